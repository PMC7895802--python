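"""Reproducibility experiments: fixed protocols that measure the pipeline's
statistical behaviour on synthetic data with known ground truth.

Each experiment simulates its own inputs, runs the relevant stages and
returns summary numbers (calibration fractions, sensitivity, false-discovery
proportions, classification accuracy). They are used by the test suite and
by the repository's acceptance script; problem sizes are chosen so each
experiment completes in well under a minute on one CPU.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from . import consistency as cons
from . import correlate as corr
from . import enrich
from . import predict as pred
from . import simulate as sim

_MOD = 2**31 - 1


def _derive(seed: int, i: int) -> int:
    return int((seed * 1009 + i) % _MOD)


def _group_interventions(metadata, group):
    return sorted({m.intervention_id for m in metadata.values()
                   if m.lifespan_effect == group})


def null_threshold_experiment(
    seed: int,
    n_panels: int = 5,
    n_interventions: int = 20,
    n_genes: int = 2000,
    quantile: float = 0.95,
) -> dict:
    """Empirical |r_s| threshold from iid null panels, averaged over panels.

    With independent signatures over G shared genes the Spearman null is
    asymptotically Normal(0, 1/(G-1)), so the 0.95 quantile of |r_s| should
    approach 1.96/sqrt(G-1).
    """
    thresholds = []
    for i in range(n_panels):
        cfg = sim.SimulationConfig(
            n_genes=n_genes, n_terms=5, term_size_range=(5, 10), planted_terms={},
            groups={"null": sim.GroupDesign(n_interventions, 1, 1)},
            seed=_derive(seed, i),
        )
        cat = sim.generate_catalogue(cfg)
        tables, meta, _ = sim.simulate_interventions(cfg, cat)
        thresholds.append(corr.estimate_null_threshold(tables, meta,
                                                       quantile=quantile))
    return {
        "mean_threshold": float(np.mean(thresholds)),
        "thresholds": thresholds,
        "expected": 1.96 / np.sqrt(n_genes - 1),
        "n_pairs_per_panel": n_interventions * (n_interventions - 1) // 2,
    }


def type_one_calibration_experiment(
    seed: int,
    n_replicates: int = 10,
    n_terms: int = 200,
    n_interventions: int = 8,
    n_perm: int = 1000,
    n_random: int = 200_000,
    alpha: float = 0.05,
) -> dict:
    """Fraction of terms with consistency p below alpha on signal-free panels.

    Interventions are mutually independent (the generator's null group) and no
    term is planted, so the consistency test's null holds for every term.
    """
    fractions = []
    for i in range(n_replicates):
        cfg = sim.SimulationConfig(
            n_terms=n_terms, planted_terms={},
            groups={"null": sim.GroupDesign(n_interventions, 1, 1)},
            seed=_derive(seed, 100 + i),
        )
        cat = sim.generate_catalogue(cfg)
        tables, meta, _ = sim.simulate_interventions(cfg, cat)
        es = enrich.score_matrix(tables, meta, cat, n_perm=n_perm,
                                 seed=_derive(seed, 200 + i))
        results = cons.median_rank_test(
            es, _group_interventions(meta, "null"), group="null",
            n_random=n_random, seed=_derive(seed, 300 + i),
        )
        fractions.append(float(np.mean([r.pvalue < alpha for r in results])))
    return {"mean_fraction": float(np.mean(fractions)), "fractions": fractions,
            "n_terms": n_terms, "n_interventions": n_interventions}


def _recovery_config(seed: int) -> sim.SimulationConfig:
    cfg = sim.SimulationConfig(seed=seed)
    return replace(cfg, groups={"long": sim.GroupDesign(4, 1, 1),
                                "short": sim.GroupDesign(4, 1, 1)})


def planted_recovery_experiment(
    seed: int,
    n_replicates: int = 10,
    n_perm: int = 1000,
    n_random: int = 200_000,
    fdr: float = 0.05,
) -> dict:
    """Sensitivity and false-discovery proportion for the shared-opposite set.

    Twenty planted shared-opposite terms (shift 2.5 sd, shared weight 0.8,
    four single-dataset interventions per group); discoveries are terms the
    partition labels shared-opposite, judged against the planted truth.
    """
    tp = fp = fn = 0
    for i in range(n_replicates):
        cfg = _recovery_config(_derive(seed, 400 + i))
        cat = sim.generate_catalogue(cfg)
        tables, meta, truth = sim.simulate_interventions(cfg, cat)
        es = enrich.score_matrix(tables, meta, cat, n_perm=n_perm,
                                 seed=_derive(seed, 500 + i))
        results = {}
        for g in ("long", "short"):
            results[g] = cons.median_rank_test(
                es, _group_interventions(meta, g), group=g,
                n_random=n_random, seed=_derive(seed, 600 + i),
            )
        partition = cons.shared_opposite_terms(results["long"], results["short"],
                                               fdr=fdr)
        planted = set(truth.planted_term_directions)
        found = set(partition["shared_opposite"])
        tp += len(found & planted)
        fp += len(found - planted)
        fn += len(planted - found)
    return {
        "sensitivity": tp / (tp + fn),
        "fdr": fp / max(tp + fp, 1),
        "true_positives": tp, "false_positives": fp, "false_negatives": fn,
        "n_replicates": n_replicates,
    }


def prediction_experiment(
    seed: int,
    mixing_weight: float = 0.7,
    n_per_sign: int = 20,
    n_perm: int = 1000,
) -> dict:
    """Classification accuracy for candidates mixed at +-mixing_weight."""
    cfg = _recovery_config(_derive(seed, 700))
    cat = sim.generate_catalogue(cfg)
    tables, meta, truth = sim.simulate_interventions(cfg, cat)
    es = enrich.score_matrix(tables, meta, cat, n_perm=n_perm,
                             seed=_derive(seed, 701))
    lams: Sequence[float] = [mixing_weight] * n_per_sign + [-mixing_weight] * n_per_sign
    ctabs, cmeta = sim.simulate_candidates(cfg, truth, lams)
    ces = enrich.score_matrix(ctabs, cmeta, cat, n_perm=n_perm,
                              seed=_derive(seed, 702))
    group_of = {m.intervention_id: m.lifespan_effect for m in meta.values()}
    focal = sorted(truth.planted_term_directions)
    predictions = pred.predict_candidates(ces, es, group_of, focal)
    correct = sum(
        (truth.candidate_mixes[p.candidate_id] > 0) == (p.call == pred.CALL_PRO)
        for p in predictions
    )
    return {"accuracy": correct / len(predictions), "n_candidates": len(predictions)}


def group_correlation_experiment(seed: int) -> dict:
    """Group-level correlation summary at the generator's default conditions."""
    cfg = sim.SimulationConfig(seed=_derive(seed, 800))
    cat = sim.generate_catalogue(cfg)
    tables, meta, _ = sim.simulate_interventions(cfg, cat)
    lifespan = [t for t in tables
                if meta[t.dataset_id].lifespan_effect in ("long", "short")]
    null_tables = [t for t in tables if meta[t.dataset_id].lifespan_effect == "null"]
    threshold = corr.estimate_null_threshold(null_tables, meta)
    cmatrix = corr.correlate_datasets(lifespan, meta)
    cmatrix.threshold = threshold
    summary = corr.summarize_groups(cmatrix, meta)
    return {
        "threshold": threshold,
        "mean_rs_same": float(np.mean(summary.same_effect)),
        "mean_rs_opposite": float(np.mean(summary.opposite_effect)),
        "fraction_positive_same": summary.fraction_positive_same,
        "fraction_positive_opposite": summary.fraction_positive_opposite,
        "wilcoxon_p": summary.wilcoxon_p,
        "n_pairs_same": len(summary.same_effect),
        "n_pairs_opposite": len(summary.opposite_effect),
    }


def ageing_resemblance_experiment(seed: int) -> dict:
    """Mean gene-level correlation with the ageing signature per group."""
    cfg = sim.SimulationConfig(seed=_derive(seed, 900))
    cat = sim.generate_catalogue(cfg)
    tables, meta, truth = sim.simulate_interventions(cfg, cat)
    lifespan = [t for t in tables
                if meta[t.dataset_id].lifespan_effect in ("long", "short")]
    ageing = sim.simulate_ageing_signature(cfg, truth)
    comparison = pred.correlate_with_ageing(lifespan, meta, ageing)
    stats = comparison.gene_level_stats
    return {
        "mean_rs_long": stats["mean_long"],
        "mean_rs_short": stats["mean_short"],
        "wilcoxon_p": stats["wilcoxon_p"],
        "n_interventions": len(comparison.table),
    }
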