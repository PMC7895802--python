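"""Comparison against the ageing transcriptome and lifespan-effect prediction.

Gene-level resemblance: Spearman correlation of each intervention's fold
changes with the ageing signature of the same tissue, averaged to
intervention level with the usual two-stage rule. Pathway-level resemblance:
Spearman correlation of enrichment-score columns. Candidate interventions
are classified by correlating their enrichment-score profile, restricted to
the focal (shared-opposite) terms, with the mean profiles of the long- and
short-lived groups: a higher correlation with the long-lived profile calls
the candidate pro-longevity-like. Predictions can be validated against an
external evidence table with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlate import (
    DEFAULT_MIN_SHARED,
    _one_sample_t_pvalue,
    rank_sum_pvalue,
    spearman_correlation,
)
from .enrich import EnrichmentScoreMatrix
from .exceptions import ConfigError, DataError, InsufficientDataError
from .io import DatasetMetadata, DifferentialExpressionTable

logger = logging.getLogger(__name__)

CALL_PRO = "pro-longevity-like"
CALL_ANTI = "anti-longevity-like"
CALL_INDETERMINATE = "indeterminate"


@dataclass
class AgeingComparison:
    """Per-intervention gene- and pathway-level correlations with ageing."""

    table: pd.DataFrame  # columns: intervention, group, gene_level_rs, pathway_level_rs
    gene_level_stats: dict
    pathway_level_stats: dict | None
    tissue: str | None = None


@dataclass(frozen=True)
class PredictionResult:
    candidate_id: str
    rs_long: float
    rs_short: float
    rs_ageing: float | None
    call: str


@dataclass
class FisherValidation:
    table: np.ndarray  # rows: call pro/anti; cols: evidence lengthens/shortens
    odds_ratio: float
    pvalue: float
    n_known: int


def _two_stage_mean(values: Mapping[str, float], metadata: Mapping[str, DatasetMetadata]
                    ) -> dict[str, float]:
    """Average per-dataset values within study, then across studies, per intervention."""
    per_iv: dict[str, dict[str, list[float]]] = {}
    for ds, v in values.items():
        md = metadata[ds]
        per_iv.setdefault(md.intervention_id, {}).setdefault(md.study_id, []).append(v)
    return {
        iv: float(np.mean([np.mean(vs) for vs in studies.values()]))
        for iv, studies in per_iv.items()
    }


def _group_stats(values_by_group: dict[str, list[float]]) -> dict:
    long_vals = np.array(values_by_group.get("long", []), dtype=float)
    short_vals = np.array(values_by_group.get("short", []), dtype=float)
    out = {
        "mean_long": float(long_vals.mean()) if long_vals.size else float("nan"),
        "mean_short": float(short_vals.mean()) if short_vals.size else float("nan"),
        "t_p_long": _one_sample_t_pvalue(long_vals) if long_vals.size >= 2 else float("nan"),
        "t_p_short": _one_sample_t_pvalue(short_vals) if short_vals.size >= 2 else float("nan"),
    }
    if long_vals.size >= 2 and short_vals.size >= 2:
        out["wilcoxon_p"] = rank_sum_pvalue(long_vals, short_vals)
    else:
        out["wilcoxon_p"] = float("nan")
    return out


def correlate_with_ageing(
    tables: Sequence[DifferentialExpressionTable],
    metadata: Mapping[str, DatasetMetadata],
    ageing_table: DifferentialExpressionTable,
    es_matrix: EnrichmentScoreMatrix | None = None,
    ageing_scores: pd.Series | None = None,
    min_shared: int = DEFAULT_MIN_SHARED,
    ageing_tissue: str | None = None,
) -> AgeingComparison:
    """Gene- and pathway-level resemblance of each intervention to ageing.

    ``ageing_tissue``, when given, must match the tissue of every compared
    dataset (resemblance across tissues is not meaningful).
    """
    group_of = {md.intervention_id: md.lifespan_effect for md in metadata.values()}
    if ageing_tissue is not None:
        mismatched = [t.dataset_id for t in tables
                      if metadata[t.dataset_id].tissue != ageing_tissue]
        if mismatched:
            raise ConfigError(
                f"datasets from a different tissue than the ageing signature: {mismatched}"
            )
    per_dataset = {
        t.dataset_id: spearman_correlation(t, ageing_table, min_shared=min_shared)
        for t in tables
    }
    gene_level = _two_stage_mean(per_dataset, metadata)

    pathway_level: dict[str, float] = {}
    if es_matrix is not None and ageing_scores is not None:
        for iv in es_matrix.interventions:
            col = es_matrix.scores[iv]
            joint = pd.concat([col, ageing_scores], axis=1, join="inner").dropna()
            if len(joint) >= 3:
                pathway_level[iv] = float(
                    stats.spearmanr(joint.iloc[:, 0], joint.iloc[:, 1]).statistic
                )

    rows = []
    for iv in sorted(gene_level):
        rows.append({
            "intervention_id": iv,
            "group": group_of.get(iv, "?"),
            "gene_level_rs": gene_level[iv],
            "pathway_level_rs": pathway_level.get(iv, float("nan")),
        })
    table = pd.DataFrame(rows)

    by_group_gene: dict[str, list[float]] = {}
    by_group_path: dict[str, list[float]] = {}
    for row in rows:
        by_group_gene.setdefault(row["group"], []).append(row["gene_level_rs"])
        if not np.isnan(row["pathway_level_rs"]):
            by_group_path.setdefault(row["group"], []).append(row["pathway_level_rs"])
    return AgeingComparison(
        table=table,
        gene_level_stats=_group_stats(by_group_gene),
        pathway_level_stats=_group_stats(by_group_path) if pathway_level else None,
        tissue=ageing_tissue,
    )


def _profile_correlation(a: pd.Series, b: pd.Series, focal: Sequence[str]) -> float:
    joint = pd.concat([a.reindex(focal), b.reindex(focal)], axis=1).dropna()
    if len(joint) < 3:
        raise InsufficientDataError(
            f"only {len(joint)} focal terms shared between score profiles (< 3)"
        )
    return float(stats.spearmanr(joint.iloc[:, 0], joint.iloc[:, 1]).statistic)


def predict_lifespan_effect(
    candidate_scores: pd.Series,
    es_matrix: EnrichmentScoreMatrix,
    group_of: Mapping[str, str],
    focal_terms: Sequence[str],
    ageing_scores: pd.Series | None = None,
    candidate_id: str | None = None,
) -> PredictionResult:
    """Classify one candidate by its enrichment-score profile over focal terms.

    The candidate profile is correlated (Spearman) against the unweighted
    mean score profile of the long-lived and of the short-lived group; the
    larger correlation decides the call.
    """
    focal = list(focal_terms)
    if not focal:
        raise ConfigError("focal term set is empty")
    members = {g: [iv for iv in es_matrix.interventions if group_of.get(iv) == g]
               for g in ("long", "short")}
    for g, ivs in members.items():
        if not ivs:
            raise InsufficientDataError(f"no interventions in group {g!r}")
    profiles = {g: es_matrix.scores[ivs].mean(axis=1, skipna=True)
                for g, ivs in members.items()}
    rs_long = _profile_correlation(candidate_scores, profiles["long"], focal)
    rs_short = _profile_correlation(candidate_scores, profiles["short"], focal)
    rs_ageing = None
    if ageing_scores is not None:
        rs_ageing = _profile_correlation(candidate_scores, ageing_scores, focal)
    if rs_long > rs_short:
        call = CALL_PRO
    elif rs_short > rs_long:
        call = CALL_ANTI
    else:
        call = CALL_INDETERMINATE
    return PredictionResult(
        candidate_id=candidate_id or str(candidate_scores.name),
        rs_long=rs_long,
        rs_short=rs_short,
        rs_ageing=rs_ageing,
        call=call,
    )


def predict_candidates(
    candidate_matrix: EnrichmentScoreMatrix,
    es_matrix: EnrichmentScoreMatrix,
    group_of: Mapping[str, str],
    focal_terms: Sequence[str],
    ageing_scores: pd.Series | None = None,
) -> list[PredictionResult]:
    """Run :func:`predict_lifespan_effect` for each candidate column."""
    return [
        predict_lifespan_effect(
            candidate_matrix.scores[cand], es_matrix, group_of, focal_terms,
            ageing_scores=ageing_scores, candidate_id=cand,
        )
        for cand in candidate_matrix.interventions
    ]


def fisher_validation(
    predictions: Sequence[PredictionResult],
    evidence: Mapping[str, str],
) -> FisherValidation:
    """Fisher's exact test of calls against known lifespan evidence.

    ``evidence`` maps candidate ids to ``lengthens``, ``shortens`` or
    ``unknown``; only candidates with known evidence enter the 2x2 table
    (rows: pro/anti call, columns: lengthens/shortens). The two-sided p sums
    hypergeometric probabilities of tables at most as probable as the one
    observed; the sample odds ratio uses a Haldane 0.5 correction when a
    cell is empty.
    """
    table = np.zeros((2, 2), dtype=int)
    n_known = 0
    for pred in predictions:
        ev = evidence.get(pred.candidate_id, "unknown")
        if ev not in ("lengthens", "shortens") or pred.call == CALL_INDETERMINATE:
            continue
        row = 0 if pred.call == CALL_PRO else 1
        col = 0 if ev == "lengthens" else 1
        table[row, col] += 1
        n_known += 1
    if n_known == 0:
        raise InsufficientDataError("no candidate has known lifespan evidence")
    pvalue = float(stats.fisher_exact(table, alternative="two-sided")[1])
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return FisherValidation(table=table, odds_ratio=float(odds_ratio),
                            pvalue=pvalue, n_known=n_known)


def prediction_table(predictions: Sequence[PredictionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "candidate_id": [p.candidate_id for p in predictions],
            "rs_long": [p.rs_long for p in predictions],
            "rs_short": [p.rs_short for p in predictions],
            "rs_ageing": [np.nan if p.rs_ageing is None else p.rs_ageing
                          for p in predictions],
            "call": [p.call for p in predictions],
        }
    )
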