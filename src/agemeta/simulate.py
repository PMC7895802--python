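"""Synthetic differential-expression data with planted, known ground truth.

The generator emulates the statistical structure of a cross-intervention
compendium: each lifespan group (long-lived, short-lived) carries a latent
group signature; interventions mix that signature with idiosyncratic noise at
a tunable shared weight ``w``; studies and datasets add observation noise;
planted gene sets are shifted up in one group and down in the other; a panel
of "null" interventions (no lifespan association) has fully independent
signatures; an ageing signature partially reproduces the short-lived group's
signature; and candidate interventions mix a group signature at a known
weight lambda, providing ground truth for the prediction stage.

Everything is simulated directly at the log2-fold-change level; per-gene
p-values follow a two-sided normal model with a single global standard error,
which preserves the monotone coupling between |log2FC| and significance that
the enrichment ranking metric relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .io import (
    DatasetMetadata,
    DifferentialExpressionTable,
    GeneSet,
    GeneSetCatalogue,
)

# sub-stream offsets so each operation draws from its own reproducible stream
_STREAM_CATALOGUE = 0
_STREAM_INTERVENTIONS = 1
_STREAM_AGEING = 2
_STREAM_CANDIDATES = 3

P_FLOOR = 1e-300


@dataclass(frozen=True)
class GroupDesign:
    """How many interventions / studies / datasets a lifespan group contains."""

    n_interventions: int
    n_studies_per_intervention: int = 1
    n_datasets_per_study: int = 1


@dataclass(frozen=True)
class PlantedTerm:
    """Directional shift of one gene set: +1 up, -1 down, 0 untouched."""

    direction_long: int
    direction_short: int
    shift: float

    def direction(self, group: str) -> int:
        if group == "long":
            return self.direction_long
        if group == "short":
            return self.direction_short
        return 0


def default_planted_terms(n: int = 20, shift: float = 2.5) -> dict[str, PlantedTerm]:
    """Shared-opposite planted terms: half up-in-long/down-in-short, half reversed."""
    out: dict[str, PlantedTerm] = {}
    for i in range(n):
        term_id = f"T{i + 1:04d}"
        if i < (n + 1) // 2:
            out[term_id] = PlantedTerm(+1, -1, shift)
        else:
            out[term_id] = PlantedTerm(-1, +1, shift)
    return out


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's study conditions."""

    n_genes: int = 2000
    n_terms: int = 1000
    term_size_range: tuple[int, int] = (15, 40)
    groups: dict[str, GroupDesign] = field(
        default_factory=lambda: {
            "long": GroupDesign(4, 2, 1),
            "short": GroupDesign(4, 2, 1),
            "null": GroupDesign(8, 1, 1),
        }
    )
    shared_weight: float = 0.8
    planted_terms: dict[str, PlantedTerm] = field(default_factory=default_planted_terms)
    base_sd: float = 1.0
    dataset_noise_sd: float = 0.5
    se: float = 0.5
    ageing_mix: float = 0.8
    tissue: str = "liver"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_terms < 1:
            raise ConfigError("n_genes and n_terms must be >= 1")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise ConfigError(f"bad term_size_range {self.term_size_range}")
        if hi > self.n_genes:
            raise ConfigError("term_size_range max exceeds n_genes")
        for name, g in self.groups.items():
            if name not in ("long", "short", "null"):
                raise ConfigError(f"unknown group {name!r}")
            if min(g.n_interventions, g.n_studies_per_intervention, g.n_datasets_per_study) < 1:
                raise ConfigError(f"group {name!r}: all counts must be >= 1")
        if not (0.0 <= self.shared_weight <= 1.0):
            raise ConfigError("shared_weight must lie in [0, 1]")
        if not (0.0 <= self.ageing_mix <= 1.0):
            raise ConfigError("ageing_mix must lie in [0, 1]")
        if min(self.base_sd, self.dataset_noise_sd, self.se) <= 0:
            raise ConfigError("base_sd, dataset_noise_sd and se must be > 0")
        known = {f"T{i + 1:04d}" for i in range(self.n_terms)}
        unknown = set(self.planted_terms) - known
        if unknown:
            raise ConfigError(f"planted term ids not in catalogue: {sorted(unknown)[:5]}")

    def gene_ids(self) -> np.ndarray:
        return np.array([f"G{i + 1:05d}" for i in range(self.n_genes)])


@dataclass
class SimulationTruth:
    """Ground truth the generator planted, for parameter-recovery tests."""

    group_signatures: dict[str, pd.Series]
    planted_term_directions: dict[str, PlantedTerm]
    candidate_mixes: dict[str, float] = field(default_factory=dict)
    ageing_signature: pd.Series | None = None


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def fold_change_pvalues(fold_changes: np.ndarray, se: float) -> np.ndarray:
    """Two-sided normal p-values, p = 2*Phi(-|fc|/se), floored away from zero."""
    p = 2.0 * stats.norm.sf(np.abs(fold_changes) / se)
    return np.clip(p, P_FLOOR, 1.0)


def generate_catalogue(config: SimulationConfig) -> GeneSetCatalogue:
    """Draw the gene-set catalogue.

    Planted terms receive mutually disjoint gene sets, and their genes are
    reserved: non-planted terms sample only from the remaining genes (while
    overlapping each other freely). This keeps the planted signal fully
    attributable, so sensitivity and false-discovery proportions against the
    ground truth are well defined.
    """
    config.validate()
    rng = _rng(config, _STREAM_CATALOGUE)
    genes = config.gene_ids()
    lo, hi = config.term_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_terms)
    term_ids = [f"T{i + 1:04d}" for i in range(config.n_terms)]

    planted_ids = [t for t in term_ids if t in config.planted_terms]
    planted_sizes = {t: int(sizes[term_ids.index(t)]) for t in planted_ids}
    if sum(planted_sizes.values()) > config.n_genes:
        raise ConfigError("planted term sizes exceed the gene universe; cannot stay disjoint")
    pool = rng.permutation(config.n_genes)
    offset = 0
    assignments: dict[str, frozenset[str]] = {}
    for t in planted_ids:
        k = planted_sizes[t]
        assignments[t] = frozenset(genes[pool[offset : offset + k]])
        offset += k
    free = pool[offset:]  # genes not claimed by any planted term
    if len(free) < hi:
        raise ConfigError("planted terms leave too few genes for non-planted terms")

    terms: list[GeneSet] = []
    for i, term_id in enumerate(term_ids):
        if term_id in assignments:
            members = assignments[term_id]
        else:
            members = frozenset(genes[rng.choice(free, int(sizes[i]), replace=False)])
        terms.append(GeneSet(term_id, f"synthetic gene set {term_id}", members))
    return GeneSetCatalogue(terms)


def _planted_shift(config: SimulationConfig, catalogue: GeneSetCatalogue, group: str,
                   gene_index: pd.Index) -> np.ndarray:
    shift = np.zeros(len(gene_index))
    pos = {g: i for i, g in enumerate(gene_index)}
    for term_id, planted in config.planted_terms.items():
        d = planted.direction(group)
        if d == 0 or term_id not in catalogue:
            continue
        idx = [pos[g] for g in catalogue[term_id].genes if g in pos]
        shift[idx] += d * planted.shift
    return shift


def _make_table(dataset_id: str, genes: np.ndarray, fc: np.ndarray, se: float
                ) -> DifferentialExpressionTable:
    p = fold_change_pvalues(fc, se)
    # BH within the dataset, mirroring a real DE analysis output
    from statsmodels.stats.multitest import multipletests

    padj = multipletests(p, method="fdr_bh")[1]
    df = pd.DataFrame({"gene_id": genes, "log2fc": fc, "pvalue": p, "padj": padj})
    return DifferentialExpressionTable(dataset_id=dataset_id, data=df)


def simulate_interventions(
    config: SimulationConfig, catalogue: GeneSetCatalogue
) -> tuple[list[DifferentialExpressionTable], dict[str, DatasetMetadata], SimulationTruth]:
    """Simulate the full intervention compendium.

    Group signature: s_g ~ N(0, base_sd^2) per gene, plus +/- shift on planted
    genes. Intervention: x_i = w*s_g + (1-w)*eps_i. Dataset: y_d = x_i +
    N(0, dataset_noise_sd^2). Null-group interventions use w = 0 (independent
    signatures), which is what makes them usable as a significance-threshold
    panel.
    """
    config.validate()
    rng = _rng(config, _STREAM_INTERVENTIONS)
    genes = config.gene_ids()
    gene_index = pd.Index(genes)

    tables: list[DifferentialExpressionTable] = []
    metadata: dict[str, DatasetMetadata] = {}
    signatures: dict[str, pd.Series] = {}

    for group in sorted(config.groups):
        design = config.groups[group]
        s_g = rng.normal(0.0, config.base_sd, config.n_genes)
        s_g += _planted_shift(config, catalogue, group, gene_index)
        signatures[group] = pd.Series(s_g, index=gene_index, name=group)
        w = 0.0 if group == "null" else config.shared_weight
        for i in range(design.n_interventions):
            iv_id = f"{group}_iv{i + 1:02d}"
            eps = rng.normal(0.0, config.base_sd, config.n_genes)
            x = w * s_g + (1.0 - w) * eps
            for s in range(design.n_studies_per_intervention):
                study_id = f"{iv_id}_st{s + 1}"
                for d in range(design.n_datasets_per_study):
                    ds_id = f"{study_id}_ds{d + 1}"
                    y = x + rng.normal(0.0, config.dataset_noise_sd, config.n_genes)
                    tables.append(_make_table(ds_id, genes, y, config.se))
                    metadata[ds_id] = DatasetMetadata(
                        dataset_id=ds_id,
                        study_id=study_id,
                        intervention_id=iv_id,
                        tissue=config.tissue,
                        lifespan_effect=group,
                    )
    truth = SimulationTruth(group_signatures=signatures,
                            planted_term_directions=dict(config.planted_terms))
    return tables, metadata, truth


def simulate_ageing_signature(
    config: SimulationConfig,
    truth: SimulationTruth,
    noise_sd: float | None = None,
) -> DifferentialExpressionTable:
    """Ageing signature a = rho*s_short + (1-rho)*eps, observed with dataset noise.

    ``noise_sd`` overrides the observation noise (0 gives a noise-free read of
    the latent ageing signature).
    """
    if "short" not in truth.group_signatures:
        raise ConfigError("ageing signature requires a short-lived group in the simulation")
    rng = _rng(config, _STREAM_AGEING)
    rho = config.ageing_mix
    s_short = truth.group_signatures["short"].to_numpy()
    eps = rng.normal(0.0, config.base_sd, config.n_genes)
    a = rho * s_short + (1.0 - rho) * eps
    sd = config.dataset_noise_sd if noise_sd is None else noise_sd
    y = a + (rng.normal(0.0, sd, config.n_genes) if sd > 0 else 0.0)
    truth.ageing_signature = pd.Series(a, index=truth.group_signatures["short"].index,
                                       name="ageing")
    return _make_table("ageing_ds1", config.gene_ids(), np.asarray(y, dtype=float), config.se)


def simulate_candidates(
    config: SimulationConfig,
    truth: SimulationTruth,
    lambdas: Sequence[float],
) -> tuple[list[DifferentialExpressionTable], dict[str, DatasetMetadata]]:
    """Candidate interventions mixing a group signature at weight lambda.

    lambda >= 0 mixes toward the long-lived signature, lambda < 0 toward the
    short-lived one; |lambda| <= 1. Each candidate is observed as one dataset.
    """
    for lam in lambdas:
        if abs(lam) > 1:
            raise ConfigError(f"|lambda| must be <= 1, got {lam}")
    needed = {"long", "short"}
    if not needed <= set(truth.group_signatures):
        raise ConfigError("candidates require both long and short group signatures")
    rng = _rng(config, _STREAM_CANDIDATES)
    genes = config.gene_ids()
    tables: list[DifferentialExpressionTable] = []
    metadata: dict[str, DatasetMetadata] = {}
    for j, lam in enumerate(lambdas):
        cand_id = f"cand{j + 1:03d}"
        base = truth.group_signatures["long" if lam >= 0 else "short"].to_numpy()
        eps = rng.normal(0.0, config.base_sd, config.n_genes)
        x = abs(lam) * base + (1.0 - abs(lam)) * eps
        y = x + rng.normal(0.0, config.dataset_noise_sd, config.n_genes)
        ds_id = f"{cand_id}_st1_ds1"
        tables.append(_make_table(ds_id, genes, y, config.se))
        metadata[ds_id] = DatasetMetadata(
            dataset_id=ds_id,
            study_id=f"{cand_id}_st1",
            intervention_id=cand_id,
            tissue=config.tissue,
            lifespan_effect="candidate",
        )
        truth.candidate_mixes[cand_id] = float(lam)
    return tables, metadata


def config_from_mapping(raw: Mapping) -> SimulationConfig:
    """Build a SimulationConfig from a plain mapping (parsed YAML/JSON)."""
    kwargs = dict(raw)
    if "groups" in kwargs:
        kwargs["groups"] = {
            name: GroupDesign(**spec) if isinstance(spec, Mapping) else GroupDesign(*spec)
            for name, spec in kwargs["groups"].items()
        }
    if "planted_terms" in kwargs:
        planted = kwargs["planted_terms"]
        if isinstance(planted, Mapping) and planted.get("preset") == "shared_opposite":
            kwargs["planted_terms"] = default_planted_terms(
                int(planted.get("n", 20)), float(planted.get("shift", 2.5))
            )
        else:
            kwargs["planted_terms"] = {
                term: PlantedTerm(**spec) if isinstance(spec, Mapping) else PlantedTerm(*spec)
                for term, spec in planted.items()
            }
    if "term_size_range" in kwargs:
        kwargs["term_size_range"] = tuple(kwargs["term_size_range"])
    config = SimulationConfig(**kwargs)
    config.validate()
    return config
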