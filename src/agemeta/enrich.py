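"""Permutation-based directional gene-set enrichment with signed scores.

Genes are ranked by ``sign(log2FC) * (-log10 p)``, so strongly up-regulated
genes sit at the top of the list and strongly down-regulated genes at the
bottom. For each gene set the classic weighted running-sum statistic is
computed over the ranked list (weight exponent 1): the sum climbs by the
normalised |metric| at member genes and falls by 1/(N - |S|) at non-members;
the enrichment statistic is the extremum of largest magnitude. Significance
comes from a gene-sampling permutation null: |S| genes are drawn uniformly
without replacement from the list, 10,000 times by default. The signed
enrichment score reported downstream is ``direction * (-log10 p)``, and the
leading edge is the set of member genes at or before (up) / at or after
(down) the extremum.

The null distribution depends only on the list's |metric| vector and on the
set size, so it is shared across equally-sized gene sets of a catalogue when
scoring one dataset.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, InsufficientDataError
from .io import DatasetMetadata, DifferentialExpressionTable, GeneSetCatalogue

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 10_000
DEFAULT_MIN_TERM_SIZE = 5
_LOG_P_FLOOR = 1e-300


@dataclass(frozen=True)
class RankedGeneList:
    """Genes sorted by the ranking metric, descending; ties broken by gene id."""

    genes: np.ndarray
    metrics: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metrics):
            raise DataError("genes and metrics must have equal length")
        if np.any(~np.isfinite(self.metrics)):
            raise DataError("non-finite ranking metrics")

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, members: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.sort(np.array([lookup[g] for g in members if g in lookup], dtype=int))


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the permutation test for one gene set in one ranked list."""

    term_id: str
    es_stat: float
    pvalue: float
    direction: int
    score: float
    leading_edge: frozenset[str]
    n_genes: int


@dataclass
class EnrichmentScoreMatrix:
    """Signed enrichment scores, terms x interventions, plus provenance.

    ``scores`` holds the two-stage-averaged intervention-level scores (NaN
    where a term was absent from every dataset of an intervention);
    ``dataset_scores`` the underlying per-dataset scores; ``dataset_results``
    the full per-dataset results including leading edges.
    """

    scores: pd.DataFrame
    dataset_scores: pd.DataFrame
    provenance: dict[str, list[str]]
    dataset_results: dict[str, dict[str, EnrichmentResult]] = field(default_factory=dict)

    @property
    def term_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def interventions(self) -> list[str]:
        return list(self.scores.columns)


def rank_genes(table: DifferentialExpressionTable) -> RankedGeneList:
    """Rank genes by sign(log2FC) * (-log10 p), descending.

    P-values are floored at 1e-300 before taking logs; a zero fold change
    yields metric 0 regardless of significance.
    """
    p = table.data["pvalue"].to_numpy(float)
    if np.any(p <= 0):
        raise DataError("p-values must be > 0")
    lfc = table.data["log2fc"].to_numpy(float)
    metric = np.sign(lfc) * (-np.log10(np.maximum(p, _LOG_P_FLOOR)))
    genes = table.data["gene_id"].to_numpy()
    order = np.lexsort((genes, -metric))
    return RankedGeneList(genes=genes[order], metrics=metric[order])


def _observed_es(abs_metrics: np.ndarray, member_mask: np.ndarray) -> tuple[float, int]:
    """Extremum of the running sum P_hit - P_miss, and its position.

    Among positions tied for the largest magnitude, the earliest wins.
    """
    n = len(abs_metrics)
    k = int(member_mask.sum())
    hit_w = np.where(member_mask, abs_metrics, 0.0)
    total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total
    p_miss = np.cumsum(~member_mask) / (n - k)
    running = p_hit - p_miss
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    mx, mn = float(running[i_max]), float(running[i_min])
    tol = 1e-12 * max(mx, -mn, 1.0)
    if mx + mn > tol:
        return mx, i_max
    if mx + mn < -tol:
        return mn, i_min
    # magnitudes tie: the extremum reached earlier in the list wins
    return (mx, i_max) if i_max <= i_min else (mn, i_min)


def _sample_positions(n: int, k: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, k) sorted positions drawn uniformly without replacement.

    Rejection sampling on with-replacement draws; for k << n few rows collide,
    and for small n the loop still terminates quickly.
    """
    pos = np.sort(rng.integers(0, n, size=(n_perm, k)), axis=1)
    bad = (np.diff(pos, axis=1) == 0).any(axis=1)
    while bad.any():
        pos[bad] = np.sort(rng.integers(0, n, size=(int(bad.sum()), k)), axis=1)
        bad = (np.diff(pos, axis=1) == 0).any(axis=1)
    return pos


def null_es_distribution(
    abs_metrics: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Permutation null of the enrichment statistic for sets of size ``k``.

    Uses the fact that between member positions the running sum falls
    monotonically, so its extrema lie immediately after (maximum) or
    immediately before (minimum) member positions; only the k member
    positions per draw need examining.
    """
    n = len(abs_metrics)
    if not (0 < k < n):
        raise DataError(f"set size {k} must lie strictly between 0 and {n}")
    pos = _sample_positions(n, k, n_perm, rng)
    w = abs_metrics[pos]
    totals = w.sum(axis=1, keepdims=True)
    h_after = np.cumsum(w, axis=1) / totals
    miss_before = (pos - np.arange(k)) / (n - k)
    after = h_after - miss_before        # value just after each member gene
    before = after - w / totals          # value just before it
    j_max = np.argmax(after, axis=1)
    j_min = np.argmin(before, axis=1)
    rows = np.arange(n_perm)
    max_es = after[rows, j_max]
    min_es = before[rows, j_min]
    # position of each extremum in the full list, for magnitude tie-breaks
    idx_max = pos[rows, j_max]
    idx_min = pos[rows, j_min] - 1
    tol = 1e-12 * np.maximum.reduce([max_es, -min_es, np.ones(n_perm)])
    tied = np.abs(max_es + min_es) <= tol
    take_max = (max_es + min_es > tol) | (tied & (idx_max <= idx_min))
    return np.where(take_max, max_es, min_es)


def _result_from_null(
    term_id: str,
    ranked: RankedGeneList,
    member_pos: np.ndarray,
    null_es: np.ndarray,
) -> EnrichmentResult:
    n = len(ranked)
    mask = np.zeros(n, dtype=bool)
    mask[member_pos] = True
    es, i_star = _observed_es(ranked.metrics_abs, mask)
    n_perm = len(null_es)
    # tolerance so a null draw of the observed subset counts as a tie even if
    # the vectorised path differs from the full scan by a rounding ulp
    tie_eps = 1e-9 * max(1.0, abs(es))
    b_up = int(np.sum(null_es >= es - tie_eps))
    b_down = int(np.sum(null_es <= es + tie_eps))
    p_up = (b_up + 1) / (n_perm + 1)
    p_down = (b_down + 1) / (n_perm + 1)
    pvalue = min(1.0, 2.0 * min(p_up, p_down))
    direction = 1 if es > 0 else (-1 if es < 0 else 1)
    if direction > 0:
        leading = ranked.genes[member_pos[member_pos <= i_star]]
    else:
        leading = ranked.genes[member_pos[member_pos >= i_star]]
    score = direction * (-np.log10(pvalue))
    return EnrichmentResult(
        term_id=term_id,
        es_stat=es,
        pvalue=pvalue,
        direction=direction,
        score=float(score),
        leading_edge=frozenset(leading),
        n_genes=len(member_pos),
    )


# cache |metrics| on the instance lazily without mutating the frozen dataclass
def _metrics_abs(self: RankedGeneList) -> np.ndarray:
    cached = self.__dict__.get("_abs")
    if cached is None:
        cached = np.abs(self.metrics)
        self.__dict__["_abs"] = cached
    return cached


RankedGeneList.metrics_abs = property(_metrics_abs)


def permutation_enrichment(
    ranked: RankedGeneList,
    term_genes: Iterable[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    term_id: str = "term",
    rng: np.random.Generator | None = None,
) -> EnrichmentResult | None:
    """Directional permutation test for one gene set.

    Returns ``None`` (with a log message) when fewer than ``min_term_size``
    member genes are present in the ranked list. A set spanning the whole
    list is degenerate: statistic 0, p-value 1.
    """
    member_pos = ranked.positions(term_genes)
    k = len(member_pos)
    if k < min_term_size:
        logger.info("term %s: only %d gene(s) in the ranked list (< %d); skipped",
                    term_id, k, min_term_size)
        return None
    if k == len(ranked):
        return EnrichmentResult(term_id, 0.0, 1.0, 1, 0.0, frozenset(), k)
    if rng is None:
        rng = np.random.default_rng(seed)
    null = null_es_distribution(ranked.metrics_abs, k, n_perm, rng)
    return _result_from_null(term_id, ranked, member_pos, null)


def enrichment_for_catalogue(
    ranked: RankedGeneList,
    catalogue: GeneSetCatalogue,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
    rng: np.random.Generator | None = None,
) -> dict[str, EnrichmentResult]:
    """Score every catalogue term against one ranked list.

    The permutation null is drawn once per distinct effective set size and
    shared across terms of that size.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = {t.term_id: ranked.positions(t.genes) for t in catalogue}
    null_cache: dict[int, np.ndarray] = {}
    results: dict[str, EnrichmentResult] = {}
    skipped = 0
    for term in catalogue:
        pos = positions[term.term_id]
        k = len(pos)
        if k < min_term_size:
            skipped += 1
            continue
        if k == len(ranked):
            results[term.term_id] = EnrichmentResult(term.term_id, 0.0, 1.0, 1, 0.0,
                                                     frozenset(), k)
            continue
        if k not in null_cache:
            null_cache[k] = null_es_distribution(ranked.metrics_abs, k, n_perm, rng)
        results[term.term_id] = _result_from_null(term.term_id, ranked, pos, null_cache[k])
    if skipped:
        logger.info("%d term(s) below min size %d skipped", skipped, min_term_size)
    return results


def _dataset_seed(base_seed: int, ranked: RankedGeneList) -> list[int]:
    # derive the permutation stream from the ranked list's content, so results
    # are independent of table order and identical data scores identically
    digest = zlib.crc32(np.ascontiguousarray(ranked.metrics).tobytes())
    digest = zlib.crc32("\x00".join(map(str, ranked.genes)).encode(), digest)
    return [int(base_seed), digest]


def score_matrix(
    tables: Sequence[DifferentialExpressionTable],
    metadata: Mapping[str, DatasetMetadata],
    catalogue: GeneSetCatalogue,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    min_term_size: int = DEFAULT_MIN_TERM_SIZE,
) -> EnrichmentScoreMatrix:
    """Signed enrichment scores per term and intervention.

    Scores are computed per dataset, then averaged within study and across
    studies of each intervention (the same two-stage rule as the
    transcriptome-wide correlations). Each dataset's permutation stream is
    derived from the base seed and the dataset id, so results do not depend
    on the order tables are supplied in.
    """
    if not tables:
        raise InsufficientDataError("no tables to score")
    term_ids = catalogue.term_ids
    dataset_results: dict[str, dict[str, EnrichmentResult]] = {}
    for table in tables:
        if table.dataset_id not in metadata:
            raise DataError(f"dataset {table.dataset_id!r} has no metadata")
        ranked = rank_genes(table)
        rng = np.random.default_rng(_dataset_seed(seed, ranked))
        results = enrichment_for_catalogue(
            ranked, catalogue, n_perm=n_perm, min_term_size=min_term_size, rng=rng
        )
        dataset_results[table.dataset_id] = results
        logger.info("dataset %s: %d/%d terms scored (n_perm=%d)",
                    table.dataset_id, len(results), len(term_ids), n_perm)

    dataset_ids = [t.dataset_id for t in tables]
    ds_scores = pd.DataFrame(np.nan, index=term_ids, columns=dataset_ids)
    for ds_id, results in dataset_results.items():
        for term_id, res in results.items():
            ds_scores.loc[term_id, ds_id] = res.score

    by_iv: dict[str, dict[str, list[str]]] = {}
    for ds_id in dataset_ids:
        md = metadata[ds_id]
        by_iv.setdefault(md.intervention_id, {}).setdefault(md.study_id, []).append(ds_id)

    interventions = sorted(by_iv)
    iv_scores = pd.DataFrame(np.nan, index=term_ids, columns=interventions)
    for iv, studies in by_iv.items():
        study_means = [
            ds_scores[ds_list].mean(axis=1, skipna=True) for ds_list in studies.values()
        ]
        iv_scores[iv] = pd.concat(study_means, axis=1).mean(axis=1, skipna=True)
    provenance = {iv: sorted(ds for dss in studies.values() for ds in dss)
                  for iv, studies in by_iv.items()}
    return EnrichmentScoreMatrix(
        scores=iv_scores,
        dataset_scores=ds_scores,
        provenance=provenance,
        dataset_results=dataset_results,
    )
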