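"""Median-rank consistency test over enrichment scores, and its downstream
summaries: the shared-opposite term partition, leading-edge hub genes, and
per-gene cross-group comparisons.

Within each intervention the terms are ranked by signed enrichment score
(rank 1 = most up-regulated). A term that is consistently regulated across a
lifespan group's interventions has an extreme median rank; the null reference
distribution draws, for each of the group's interventions, one rank uniformly
from {1..T} and takes the median, repeated a large number of times (1e6 by
default). The empirical-CDF position of the observed median among the null
medians gives the one-sided p; both tails are examined and doubled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correlate import rank_sum_pvalue
from .enrich import EnrichmentResult, EnrichmentScoreMatrix
from .exceptions import ConfigError, DataError, InsufficientDataError
from .io import DatasetMetadata

logger = logging.getLogger(__name__)

DEFAULT_N_RANDOM = 1_000_000
DEFAULT_FDR = 0.05


@dataclass(frozen=True)
class ConsistencyResult:
    term_id: str
    group: str
    median_rank: float
    pvalue: float
    qvalue: float
    direction: int
    n_interventions: int


@dataclass(frozen=True)
class HubGene:
    gene_id: str
    terms_led: frozenset[str]
    interventions_supporting: int


@dataclass
class HubGeneReport:
    group: str
    genes: list[HubGene]


def rank_terms_within_intervention(scores: pd.Series) -> pd.Series:
    """Rank terms by score within one intervention; rank 1 = largest score.

    Ties receive average ranks; missing scores are excluded from the ranking.
    """
    present = scores.dropna()
    if len(present) < 2:
        raise DataError("need >= 2 non-missing scores to rank")
    ranks = pd.Series(
        stats.rankdata(-present.to_numpy(float), method="average"),
        index=present.index,
    )
    return ranks.reindex(scores.index)


def null_median_ranks(
    n_terms: int, n_interventions: int, n_random: int, rng: np.random.Generator
) -> np.ndarray:
    """Sorted null medians of ``n_interventions`` iid uniform ranks in {1..T}."""
    draws = rng.integers(1, n_terms + 1, size=(n_random, n_interventions))
    return np.sort(np.median(draws, axis=1))


def median_rank_test(
    es: EnrichmentScoreMatrix,
    group_interventions: Sequence[str],
    group: str = "",
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    fdr_method: str = "fdr_bh",
) -> list[ConsistencyResult]:
    """Test every term for consistently extreme rank across a group.

    Terms scored in fewer than 2 of the group's interventions are excluded
    (and logged). The one-sided empirical p-values are add-one smoothed,
    doubled for two-sidedness, and BH-adjusted across the tested terms.
    """
    ivs = [iv for iv in group_interventions]
    if len(ivs) < 2:
        raise InsufficientDataError("consistency test needs >= 2 interventions")
    missing_cols = [iv for iv in ivs if iv not in es.scores.columns]
    if missing_cols:
        raise DataError(f"interventions without scores: {missing_cols}")

    sub = es.scores[ivs]
    n_terms = sub.shape[0]
    ranks = pd.DataFrame({iv: rank_terms_within_intervention(sub[iv]) for iv in ivs})

    rng = np.random.default_rng([int(seed), 17])
    null_cache: dict[int, np.ndarray] = {}

    records: list[tuple[str, float, float, int, int]] = []
    excluded = 0
    for term_id, row in ranks.iterrows():
        obs = row.dropna().to_numpy(float)
        n_iv = len(obs)
        if n_iv < 2:
            excluded += 1
            continue
        if n_iv not in null_cache:
            null_cache[n_iv] = null_median_ranks(n_terms, n_iv, n_random, rng)
        null = null_cache[n_iv]
        observed = float(np.median(obs))
        n_low = int(np.searchsorted(null, observed, side="right"))   # null <= obs
        n_high = len(null) - int(np.searchsorted(null, observed, side="left"))
        p_up = (n_low + 1) / (n_random + 1)
        p_down = (n_high + 1) / (n_random + 1)
        pvalue = min(1.0, 2.0 * min(p_up, p_down))
        direction = 1 if p_up <= p_down else -1
        records.append((term_id, observed, pvalue, direction, n_iv))
    if excluded:
        logger.info("group %s: %d term(s) scored in < 2 interventions excluded",
                    group or "?", excluded)
    if not records:
        raise InsufficientDataError("no term observed in >= 2 interventions")

    qvalues = bh_adjust([r[2] for r in records]) if fdr_method == "fdr_bh" else \
        multipletests([r[2] for r in records], method=fdr_method)[1]
    return [
        ConsistencyResult(term_id=t, group=group, median_rank=m, pvalue=p,
                          qvalue=float(q), direction=d, n_interventions=n_iv)
        for (t, m, p, d, n_iv), q in zip(records, qvalues)
    ]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DataError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def consistency_table(results: Sequence[ConsistencyResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "group": [r.group for r in results],
            "median_rank": [r.median_rank for r in results],
            "pvalue": [r.pvalue for r in results],
            "qvalue": [r.qvalue for r in results],
            "direction": [r.direction for r in results],
            "n_interventions": [r.n_interventions for r in results],
        }
    )


def shared_opposite_terms(
    results_long: Sequence[ConsistencyResult],
    results_short: Sequence[ConsistencyResult],
    fdr: float = DEFAULT_FDR,
) -> dict[str, list[str]]:
    """Partition terms by joint significance pattern across the two groups.

    Returns lists under the keys ``shared_opposite`` (significant in both
    groups, opposite directions), ``shared_same``, ``long_specific``,
    ``short_specific`` and ``neither``. Terms tested in only one group are
    treated as non-significant in the other.
    """
    long_by = {r.term_id: r for r in results_long}
    short_by = {r.term_id: r for r in results_short}
    if not set(long_by) & set(short_by):
        raise DataError("result lists share no terms; catalogues differ")
    partition: dict[str, list[str]] = {
        "shared_opposite": [], "shared_same": [],
        "long_specific": [], "short_specific": [], "neither": [],
    }
    for term_id in sorted(set(long_by) | set(short_by)):
        rl, rs = long_by.get(term_id), short_by.get(term_id)
        sig_l = rl is not None and rl.qvalue < fdr
        sig_s = rs is not None and rs.qvalue < fdr
        if sig_l and sig_s:
            key = "shared_opposite" if rl.direction != rs.direction else "shared_same"
        elif sig_l:
            key = "long_specific"
        elif sig_s:
            key = "short_specific"
        else:
            key = "neither"
        partition[key].append(term_id)
    return partition


def _intervention_leading_edges(
    dataset_results: Mapping[str, Mapping[str, EnrichmentResult]],
    metadata: Mapping[str, DatasetMetadata],
    intervention: str,
    focal_terms: Iterable[str],
) -> dict[str, frozenset[str]]:
    """Leading edge of each focal term at intervention level.

    A gene belongs to the intervention-level leading edge of a term when it
    appears in the leading edge in at least half of the intervention's
    datasets that scored the term.
    """
    datasets = [ds for ds, md in metadata.items() if md.intervention_id == intervention
                and ds in dataset_results]
    out: dict[str, frozenset[str]] = {}
    for term_id in focal_terms:
        counts: dict[str, int] = {}
        n_reporting = 0
        for ds in datasets:
            res = dataset_results[ds].get(term_id)
            if res is None:
                continue
            n_reporting += 1
            for g in res.leading_edge:
                counts[g] = counts.get(g, 0) + 1
        if n_reporting == 0:
            continue
        need = math.ceil(n_reporting / 2)
        out[term_id] = frozenset(g for g, c in counts.items() if c >= need)
    return out


def leading_edge_hubs(
    dataset_results: Mapping[str, Mapping[str, EnrichmentResult]],
    metadata: Mapping[str, DatasetMetadata],
    group_interventions: Sequence[str],
    focal_terms: Iterable[str],
    group: str = "",
) -> HubGeneReport:
    """Genes driving the enrichment of multiple processes across a group.

    A gene qualifies as a hub when, in at least half (ceil(I/2)) of the
    group's I interventions, it appears in the leading edges of two or more
    focal terms.
    """
    focal = list(focal_terms)
    if not focal:
        raise ConfigError("focal term set is empty")
    per_iv = {
        iv: _intervention_leading_edges(dataset_results, metadata, iv, focal)
        for iv in group_interventions
    }
    need_iv = math.ceil(len(group_interventions) / 2)
    support: dict[str, int] = {}
    led: dict[str, set[str]] = {}
    for iv, edges in per_iv.items():
        gene_terms: dict[str, set[str]] = {}
        for term_id, genes in edges.items():
            for g in genes:
                gene_terms.setdefault(g, set()).add(term_id)
        for g, terms in gene_terms.items():
            if len(terms) >= 2:
                support[g] = support.get(g, 0) + 1
                led.setdefault(g, set()).update(terms)
    hubs = [
        HubGene(gene_id=g, terms_led=frozenset(led[g]), interventions_supporting=c)
        for g, c in sorted(support.items())
        if c >= need_iv
    ]
    return HubGeneReport(group=group, genes=hubs)


def compare_gene_between_groups(
    normalized: pd.DataFrame,
    metadata: Mapping[str, DatasetMetadata],
    gene_id: str,
) -> tuple[float, dict[str, float]]:
    """Unpaired two-sided rank-sum test of one gene's normalised fold changes,
    long-lived vs short-lived datasets. Returns (p, group medians)."""
    if gene_id not in normalized.index:
        raise DataError(f"gene {gene_id!r} absent from the fold-change matrix")
    groups: dict[str, list[float]] = {"long": [], "short": []}
    for ds in normalized.columns:
        md = metadata.get(ds)
        if md is not None and md.lifespan_effect in groups:
            groups[md.lifespan_effect].append(float(normalized.loc[gene_id, ds]))
    if len(groups["long"]) < 2 or len(groups["short"]) < 2:
        raise InsufficientDataError("need >= 2 datasets per group")
    p = rank_sum_pvalue(groups["long"], groups["short"])
    medians = {g: float(np.median(v)) for g, v in groups.items()}
    return p, medians
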