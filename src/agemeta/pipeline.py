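"""End-to-end pipeline: simulate -> correlate -> enrich -> consistency ->
network -> ageing comparison -> prediction, with a reproducibility manifest.

Every stochastic stage derives its stream from the single pipeline seed and
the stage name, so stages can be rerun independently yet reproducibly, and a
rerun with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import consistency as cons
from . import correlate as corr
from . import enrich, network, predict
from . import simulate as sim
from .exceptions import ConfigError
from .io import write_de_table, write_gmt, write_metadata

logger = logging.getLogger(__name__)

STAGES = ("simulate", "correlate", "enrich", "consistency", "hubs", "network",
          "ageing", "predict")


@dataclass
class PipelineConfig:
    """Parameters of a full synthetic-data run."""

    simulation: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    candidate_lambdas: list[float] = field(default_factory=lambda: [0.7, -0.7, 0.4, -0.4])
    min_shared: int = corr.DEFAULT_MIN_SHARED
    quantile: float = 0.95
    n_perm: int = enrich.DEFAULT_N_PERM
    n_random: int = cons.DEFAULT_N_RANDOM
    fdr: float = cons.DEFAULT_FDR
    oc_threshold: float = network.DEFAULT_OC_THRESHOLD
    min_cluster: int = network.DEFAULT_MIN_CLUSTER
    min_term_size: int = enrich.DEFAULT_MIN_TERM_SIZE
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        if not (0.0 < self.quantile < 1.0):
            raise ConfigError("quantile must lie in (0, 1)")
        if not (0.0 < self.fdr < 1.0):
            raise ConfigError("fdr must lie in (0, 1)")
        for v, name in ((self.n_perm, "n_perm"), (self.n_random, "n_random"),
                        (self.min_shared, "min_shared"), (self.min_cluster, "min_cluster"),
                        (self.min_term_size, "min_term_size")):
            if v < 1:
                raise ConfigError(f"{name} must be >= 1")

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed by stage-name hashing."""
        h = zlib.crc32(stage.encode("utf-8"))
        return int((self.seed * 1_000_003 + h) % (2**31 - 1))


def config_from_file(path) -> PipelineConfig:
    """Load a pipeline configuration from YAML (or JSON, a YAML subset)."""
    import yaml

    with open(str(path), encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return config_from_mapping(raw)


def config_from_mapping(raw: Mapping) -> PipelineConfig:
    kwargs = dict(raw)
    if "simulation" in kwargs:
        kwargs["simulation"] = sim.config_from_mapping(kwargs["simulation"])
    config = PipelineConfig(**kwargs)
    config.validate()
    return config


def _config_digest(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not serialisable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n",
                    encoding="utf-8")


def _tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages, writing every artefact under ``outdir``.

    Partial outputs are retained on stage failure; the failing stage is named
    in the raised error. Returns the run directory.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_sha256": _config_digest(config),
        "seed": config.seed,
        "stages": {},
        "version": _package_version(),
    }
    stage = "setup"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim_dir = out / "simulate"
        (sim_dir / "de").mkdir(parents=True, exist_ok=True)
        scfg = config.simulation
        catalogue = sim.generate_catalogue(scfg)
        tables, metadata, truth = sim.simulate_interventions(scfg, catalogue)
        ageing_table = sim.simulate_ageing_signature(scfg, truth)
        cand_tables, cand_metadata = sim.simulate_candidates(
            scfg, truth, config.candidate_lambdas
        )
        all_meta = {**metadata, **cand_metadata}
        for t in tables + cand_tables + [ageing_table]:
            write_de_table(t, sim_dir / "de" / f"{t.dataset_id}.tsv")
        write_metadata(all_meta, sim_dir / "metadata.tsv")
        write_gmt(catalogue, sim_dir / "catalogue.gmt")
        _write_json(
            {
                "planted_terms": {t: asdict(p) for t, p in
                                  truth.planted_term_directions.items()},
                "candidate_mixes": truth.candidate_mixes,
            },
            sim_dir / "truth.json",
        )
        logger.info("simulate: %d datasets, %d candidates, %d terms, %d genes",
                    len(tables), len(cand_tables), scfg.n_terms, scfg.n_genes)
        manifest["stages"]["simulate"] = {
            "datasets": len(tables), "candidates": len(cand_tables),
            "terms": scfg.n_terms, "genes": scfg.n_genes,
        }

        # --- correlate ----------------------------------------------------
        stage = "correlate"
        corr_dir = out / "correlate"
        corr_dir.mkdir(exist_ok=True)
        lifespan_tables = [t for t in tables
                           if metadata[t.dataset_id].lifespan_effect in ("long", "short")]
        null_tables = [t for t in tables
                       if metadata[t.dataset_id].lifespan_effect == "null"]
        threshold = corr.estimate_null_threshold(
            null_tables, metadata, quantile=config.quantile, min_shared=config.min_shared
        )
        cmatrix = corr.correlate_datasets(lifespan_tables, metadata,
                                          min_shared=config.min_shared)
        cmatrix.threshold = threshold
        summary = corr.summarize_groups(cmatrix, metadata)
        _tsv(cmatrix.matrix, corr_dir / "matrix.tsv")
        _write_json(
            {
                "threshold": threshold,
                "quantile": config.quantile,
                "t_p_same": summary.t_p_same,
                "t_p_opposite": summary.t_p_opposite,
                "wilcoxon_p": summary.wilcoxon_p,
                "fraction_positive_same": summary.fraction_positive_same,
                "fraction_positive_opposite": summary.fraction_positive_opposite,
                "significant_same": summary.significant_same,
                "significant_opposite": summary.significant_opposite,
                "n_pairs_same": len(summary.same_effect),
                "n_pairs_opposite": len(summary.opposite_effect),
            },
            corr_dir / "summary.json",
        )
        logger.info("correlate: %d interventions, threshold |r_s| > %.4f",
                    len(cmatrix.interventions), threshold)
        manifest["stages"]["correlate"] = {
            "interventions": len(cmatrix.interventions), "threshold": threshold,
        }

        # --- enrich -------------------------------------------------------
        stage = "enrich"
        enr_dir = out / "enrich"
        enr_dir.mkdir(exist_ok=True)
        es = enrich.score_matrix(
            lifespan_tables, metadata, catalogue,
            n_perm=config.n_perm, seed=config.stage_seed("enrich"),
            min_term_size=config.min_term_size,
        )
        ageing_meta = {
            ageing_table.dataset_id: type(next(iter(metadata.values())))(
                dataset_id=ageing_table.dataset_id, study_id="ageing_st1",
                intervention_id="ageing", tissue=scfg.tissue, lifespan_effect="ageing",
            )
        }
        ageing_es = enrich.score_matrix(
            [ageing_table], ageing_meta, catalogue,
            n_perm=config.n_perm, seed=config.stage_seed("enrich"),
            min_term_size=config.min_term_size,
        )
        cand_es = enrich.score_matrix(
            cand_tables, cand_metadata, catalogue,
            n_perm=config.n_perm, seed=config.stage_seed("enrich"),
            min_term_size=config.min_term_size,
        )
        _tsv(es.scores, enr_dir / "scores.tsv")
        _tsv(ageing_es.scores, enr_dir / "ageing_scores.tsv")
        _tsv(cand_es.scores, enr_dir / "candidate_scores.tsv")
        logger.info("enrich: %d terms x %d interventions (n_perm=%d)",
                    len(es.term_ids), len(es.interventions), config.n_perm)
        manifest["stages"]["enrich"] = {
            "terms": len(es.term_ids), "interventions": len(es.interventions),
            "n_perm": config.n_perm,
        }

        # --- consistency ----------------------------------------------------
        stage = "consistency"
        con_dir = out / "consistency"
        con_dir.mkdir(exist_ok=True)
        group_ivs = {
            g: sorted({md.intervention_id for md in metadata.values()
                       if md.lifespan_effect == g})
            for g in ("long", "short")
        }
        results = {}
        for g in ("long", "short"):
            results[g] = cons.median_rank_test(
                es, group_ivs[g], group=g, n_random=config.n_random,
                seed=config.stage_seed(f"consistency-{g}"),
            )
            _tsv(cons.consistency_table(results[g]), con_dir / f"{g}.tsv", index=False)
        partition = cons.shared_opposite_terms(results["long"], results["short"],
                                               fdr=config.fdr)
        _write_json(partition, con_dir / "partition.json")
        focal = partition["shared_opposite"]
        logger.info("consistency: %d shared-opposite terms at FDR %.2f",
                    len(focal), config.fdr)
        manifest["stages"]["consistency"] = {
            "shared_opposite": len(focal),
            "long_significant": sum(r.qvalue < config.fdr for r in results["long"]),
            "short_significant": sum(r.qvalue < config.fdr for r in results["short"]),
            "n_random": config.n_random,
        }

        # --- hubs -----------------------------------------------------------
        stage = "hubs"
        if focal:
            hub_rows = []
            for g in ("long", "short"):
                report = cons.leading_edge_hubs(
                    es.dataset_results, metadata, group_ivs[g], focal, group=g
                )
                for hub in report.genes:
                    hub_rows.append({
                        "group": g, "gene_id": hub.gene_id,
                        "n_terms_led": len(hub.terms_led),
                        "terms_led": ";".join(sorted(hub.terms_led)),
                        "interventions_supporting": hub.interventions_supporting,
                    })
            _tsv(pd.DataFrame(hub_rows,
                              columns=["group", "gene_id", "n_terms_led", "terms_led",
                                       "interventions_supporting"]),
                 out / "hubs.tsv", index=False)
            manifest["stages"]["hubs"] = {"hub_genes": len(hub_rows)}
            logger.info("hubs: %d hub gene records", len(hub_rows))

        # --- network --------------------------------------------------------
        stage = "network"
        net_dir = out / "network"
        net_dir.mkdir(exist_ok=True)
        if focal:
            net = network.build_network(
                catalogue.subset(focal),
                oc_threshold=config.oc_threshold, min_cluster=config.min_cluster,
            )
            edges = pd.DataFrame(net.edges, columns=["term_a", "term_b", "oc"])
            nodes = pd.DataFrame({
                "term_id": net.nodes,
                "component": [net.component_of(n) for n in net.nodes],
            })
        else:
            edges = pd.DataFrame(columns=["term_a", "term_b", "oc"])
            nodes = pd.DataFrame(columns=["term_id", "component"])
        _tsv(edges, net_dir / "edges.tsv", index=False)
        _tsv(nodes, net_dir / "nodes.tsv", index=False)
        manifest["stages"]["network"] = {"nodes": len(nodes), "edges": len(edges)}
        logger.info("network: %d nodes, %d edges retained", len(nodes), len(edges))

        # --- ageing comparison ----------------------------------------------
        stage = "ageing"
        age_dir = out / "ageing"
        age_dir.mkdir(exist_ok=True)
        comparison = predict.correlate_with_ageing(
            lifespan_tables, metadata, ageing_table,
            es_matrix=es, ageing_scores=ageing_es.scores["ageing"],
            min_shared=config.min_shared, ageing_tissue=scfg.tissue,
        )
        _tsv(comparison.table, age_dir / "comparison.tsv", index=False)
        _write_json(
            {"gene_level": comparison.gene_level_stats,
             "pathway_level": comparison.pathway_level_stats},
            age_dir / "stats.json",
        )
        manifest["stages"]["ageing"] = {"interventions": len(comparison.table)}
        logger.info("ageing: compared %d interventions", len(comparison.table))

        # --- predict --------------------------------------------------------
        stage = "predict"
        pred_dir = out / "predict"
        pred_dir.mkdir(exist_ok=True)
        group_of = {md.intervention_id: md.lifespan_effect for md in metadata.values()}
        focal_for_prediction = focal if len(focal) >= 3 else list(scfg.planted_terms)
        predictions = predict.predict_candidates(
            cand_es, es, group_of, focal_for_prediction,
            ageing_scores=ageing_es.scores["ageing"],
        )
        _tsv(predict.prediction_table(predictions), pred_dir / "predictions.tsv",
             index=False)
        evidence = {
            cand: ("lengthens" if lam > 0 else "shortens" if lam < 0 else "unknown")
            for cand, lam in truth.candidate_mixes.items()
        }
        _write_json({"evidence_from_truth": evidence}, pred_dir / "evidence.json")
        validation = predict.fisher_validation(predictions, evidence)
        _write_json(
            {
                "table": validation.table,
                "odds_ratio": validation.odds_ratio,
                "pvalue": validation.pvalue,
                "n_known": validation.n_known,
            },
            pred_dir / "validation.json",
        )
        correct = sum(
            1 for p in predictions
            if (evidence.get(p.candidate_id) == "lengthens" and p.call == predict.CALL_PRO)
            or (evidence.get(p.candidate_id) == "shortens" and p.call == predict.CALL_ANTI)
        )
        manifest["stages"]["predict"] = {
            "candidates": len(predictions), "correct_calls": correct,
            "fisher_p": validation.pvalue,
        }
        logger.info("predict: %d/%d candidates called correctly",
                    correct, len(predictions))
    except Exception as exc:
        from .exceptions import AgemetaError

        if isinstance(exc, AgemetaError):
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        raise AgemetaError(f"stage {stage!r} failed: {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    return out


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("agemeta")
    except Exception:
        return "unknown"
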