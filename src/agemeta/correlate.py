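"""Transcriptome-wide Spearman correlations between intervention signatures.

Correlations are computed between dataset-level fold-change signatures over
the genes the two datasets share, then averaged in two stages: first between
datasets from the same study and intervention pair, then across studies of
the same intervention pair. An empirical significance threshold for |r_s| is
calibrated from a panel of interventions with no known lifespan effect, whose
signatures are mutually independent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InsufficientOverlapError, MetadataError
from .io import DatasetMetadata, DifferentialExpressionTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_SHARED = 100


@dataclass
class CorrelationMatrix:
    """Intervention-level averaged Spearman correlations.

    ``matrix`` holds r_s off the diagonal and the number of contributing
    datasets on the diagonal (mirroring how compendium heatmaps annotate
    dataset counts); ``threshold`` is the empirical significance cutoff if
    one was estimated.
    """

    matrix: pd.DataFrame
    threshold: float | None = None

    @property
    def interventions(self) -> list[str]:
        return list(self.matrix.index)

    def correlation(self, a: str, b: str) -> float:
        if a == b:
            raise ValueError("diagonal holds dataset counts, not correlations")
        return float(self.matrix.loc[a, b])

    def dataset_count(self, intervention: str) -> int:
        return int(self.matrix.loc[intervention, intervention])

    def pairs(self) -> list[tuple[str, str, float]]:
        ivs = self.interventions
        return [
            (a, b, float(self.matrix.loc[a, b]))
            for a, b in itertools.combinations(ivs, 2)
        ]


@dataclass
class GroupCorrelationSummary:
    """Group-level statistics on intervention-pair correlations."""

    same_effect: list[float]
    opposite_effect: list[float]
    t_p_same: float
    t_p_opposite: float
    wilcoxon_p: float
    fraction_positive_same: float
    fraction_positive_opposite: float
    significant_same: int = 0
    significant_opposite: int = 0


def spearman_correlation(
    table_a: DifferentialExpressionTable,
    table_b: DifferentialExpressionTable,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> float:
    """Spearman rank correlation of log2FC over the shared-gene intersection."""
    a = table_a.log2fc()
    b = table_b.log2fc()
    shared = a.index.intersection(b.index)
    if len(shared) < min_shared:
        raise InsufficientOverlapError(
            f"datasets {table_a.dataset_id!r} and {table_b.dataset_id!r} share "
            f"{len(shared)} genes (< {min_shared})"
        )
    rho = stats.spearmanr(a.loc[shared].to_numpy(), b.loc[shared].to_numpy()).statistic
    return float(rho)


def pairwise_dataset_correlations(
    tables: Sequence[DifferentialExpressionTable],
    min_shared: int = DEFAULT_MIN_SHARED,
) -> pd.DataFrame:
    """Symmetric dataset x dataset Spearman matrix (diagonal 1)."""
    ids = [t.dataset_id for t in tables]
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for (i, ta), (j, tb) in itertools.combinations(enumerate(tables), 2):
        r = spearman_correlation(ta, tb, min_shared=min_shared)
        out.iat[i, j] = out.iat[j, i] = r
    return out


def average_to_interventions(
    pairwise: pd.DataFrame,
    metadata: Mapping[str, DatasetMetadata],
) -> CorrelationMatrix:
    """Collapse dataset-level correlations to intervention level in two stages.

    For each intervention pair, dataset-pair correlations are first averaged
    within each (study_a, study_b) combination, then the study-pair means are
    averaged with equal weight. Diagonal entries carry dataset counts.
    """
    for ds in pairwise.index:
        if ds not in metadata:
            raise MetadataError(f"dataset {ds!r} has no metadata")
    by_iv: dict[str, list[str]] = {}
    for ds in pairwise.index:
        by_iv.setdefault(metadata[ds].intervention_id, []).append(ds)
    interventions = sorted(by_iv)

    out = pd.DataFrame(np.nan, index=interventions, columns=interventions)
    for iv in interventions:
        out.loc[iv, iv] = len(by_iv[iv])
    for iv_a, iv_b in itertools.combinations(interventions, 2):
        study_pairs: dict[tuple[str, str], list[float]] = {}
        for ds_a in by_iv[iv_a]:
            for ds_b in by_iv[iv_b]:
                if ds_a not in pairwise.index or ds_b not in pairwise.columns:
                    raise MetadataError(f"missing correlation for pair ({ds_a}, {ds_b})")
                key = (metadata[ds_a].study_id, metadata[ds_b].study_id)
                study_pairs.setdefault(key, []).append(float(pairwise.loc[ds_a, ds_b]))
        study_means = [float(np.mean(v)) for v in study_pairs.values()]
        r = float(np.mean(study_means))
        out.loc[iv_a, iv_b] = out.loc[iv_b, iv_a] = r
    return CorrelationMatrix(matrix=out)


def correlate_datasets(
    tables: Sequence[DifferentialExpressionTable],
    metadata: Mapping[str, DatasetMetadata],
    min_shared: int = DEFAULT_MIN_SHARED,
    tissue: str | None = None,
) -> CorrelationMatrix:
    """Convenience: pairwise dataset correlations + two-stage averaging.

    If ``tissue`` is given, only datasets from that tissue are used.
    """
    if tissue is not None:
        tables = [t for t in tables if metadata[t.dataset_id].tissue == tissue]
    if len(tables) < 2:
        raise InsufficientDataError("need at least 2 datasets to correlate")
    pairwise = pairwise_dataset_correlations(tables, min_shared=min_shared)
    return average_to_interventions(pairwise, metadata)


def estimate_null_threshold(
    null_tables: Sequence[DifferentialExpressionTable],
    null_metadata: Mapping[str, DatasetMetadata],
    quantile: float = 0.95,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> float:
    """Empirical |r_s| significance cutoff from a null intervention panel.

    Returns the ``quantile`` of |r_s| over all distinct intervention pairs of
    the panel after two-stage averaging; correlations above it are treated as
    transcriptome-wide significant for the lifespan-associated interventions.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    cmat = correlate_datasets(null_tables, null_metadata, min_shared=min_shared)
    if len(cmat.interventions) < 2:
        raise InsufficientDataError("null panel must contain >= 2 interventions")
    values = np.array([abs(r) for _, _, r in cmat.pairs()])
    threshold = float(np.quantile(values, quantile))
    logger.info(
        "null threshold: %d interventions, %d pairs, q=%.3f -> |r_s| > %.4f",
        len(cmat.interventions), len(values), quantile, threshold,
    )
    return threshold


def _one_sample_t_pvalue(values: np.ndarray) -> float:
    """Two-sided one-sample t-test against mean zero, safe for degenerate input."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:
        return 1.0 if values[0] == 0.0 else 0.0
    return float(stats.ttest_1samp(values, 0.0).pvalue)


def rank_sum_pvalue(x: Sequence[float], y: Sequence[float], exact_max_n: int = 20) -> float:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null when the combined sample size is <= ``exact_max_n``, normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if len(x) + len(y) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def summarize_groups(
    cmatrix: CorrelationMatrix,
    metadata: Mapping[str, DatasetMetadata],
    threshold: float | None = None,
) -> GroupCorrelationSummary:
    """Statistics contrasting same-effect and opposite-effect intervention pairs.

    Same-effect pairs are long-long and short-short; opposite-effect pairs are
    long-short. Each list is tested against mean zero with a one-sample t-test
    and the lists are compared with an unpaired two-sided rank-sum test.
    """
    group_of: dict[str, str] = {}
    for md in metadata.values():
        group_of[md.intervention_id] = md.lifespan_effect
    same: list[float] = []
    opposite: list[float] = []
    for a, b, r in cmatrix.pairs():
        ga, gb = group_of.get(a), group_of.get(b)
        if ga not in ("long", "short") or gb not in ("long", "short"):
            continue
        (same if ga == gb else opposite).append(r)
    if len(same) < 2 or len(opposite) < 2:
        raise InsufficientDataError(
            f"need >= 2 pairs per group (got {len(same)} same, {len(opposite)} opposite)"
        )
    thr = cmatrix.threshold if threshold is None else threshold
    sig_same = sig_opp = 0
    if thr is not None:
        sig_same = int(np.sum(np.abs(same) > thr))
        sig_opp = int(np.sum(np.abs(opposite) > thr))
    return GroupCorrelationSummary(
        same_effect=same,
        opposite_effect=opposite,
        t_p_same=_one_sample_t_pvalue(np.array(same)),
        t_p_opposite=_one_sample_t_pvalue(np.array(opposite)),
        wilcoxon_p=rank_sum_pvalue(same, opposite),
        fraction_positive_same=float(np.mean(np.array(same) > 0)),
        fraction_positive_opposite=float(np.mean(np.array(opposite) > 0)),
        significant_same=sig_same,
        significant_opposite=sig_opp,
    )
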