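import numpy as np
import pandas as pd
import pytest

import agemeta as am
from agemeta.correlate import rank_sum_pvalue
from agemeta.exceptions import InsufficientDataError, InsufficientOverlapError, MetadataError
from agemeta.simulate import GroupDesign, SimulationConfig

from .conftest import make_metadata, make_table


class TestSpearman:
    def test_identity_and_negation(self, rng):
        fc = rng.normal(size=50)
        a = make_table("a", fc)
        b = make_table("b", -fc)
        assert am.spearman_correlation(a, a, min_shared=50) == pytest.approx(1.0)
        assert am.spearman_correlation(a, b, min_shared=50) == pytest.approx(-1.0)

    def test_tie_free_closed_form(self):
        a = make_table("a", [1, 2, 3, 4])
        b = make_table("b", [1, 3, 2, 4])
        # 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 2
        assert am.spearman_correlation(a, b, min_shared=4) == pytest.approx(0.8)

    def test_insufficient_overlap_names_datasets(self):
        a = make_table("alpha", [1.0, 2.0], genes=["g1", "g2"])
        b = make_table("beta", [1.0, 2.0], genes=["g3", "g4"])
        with pytest.raises(InsufficientOverlapError, match="alpha.*beta"):
            am.spearman_correlation(a, b, min_shared=2)


class TestTwoStageAveraging:
    def test_single_dataset_interventions_pass_through(self, rng):
        tables = [make_table(f"d{i}", rng.normal(size=200)) for i in range(3)]
        meta = {f"d{i}": make_metadata(f"d{i}", f"iv{i}") for i in range(3)}
        pw = am.pairwise_dataset_correlations(tables, min_shared=100)
        cm = am.average_to_interventions(pw, meta)
        for i in range(3):
            for j in range(i + 1, 3):
                assert cm.correlation(f"iv{i}", f"iv{j}") == pytest.approx(
                    pw.loc[f"d{i}", f"d{j}"])
        assert cm.dataset_count("iv0") == 1

    def test_worked_example(self):
        # A: a1,a2 in study S1 and a3 in study S2; B: single dataset b1
        # r(a1,b1)=0.2, r(a2,b1)=0.4, r(a3,b1)=0.6
        # within-study means 0.3 and 0.6, final (0.3+0.6)/2 = 0.45
        ids = ["a1", "a2", "a3", "b1"]
        pw = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        pw.loc["a1", "b1"] = pw.loc["b1", "a1"] = 0.2
        pw.loc["a2", "b1"] = pw.loc["b1", "a2"] = 0.4
        pw.loc["a3", "b1"] = pw.loc["b1", "a3"] = 0.6
        meta = {
            "a1": make_metadata("a1", "A", study="S1"),
            "a2": make_metadata("a2", "A", study="S1"),
            "a3": make_metadata("a3", "A", study="S2"),
            "b1": make_metadata("b1", "B", study="S3"),
        }
        cm = am.average_to_interventions(pw, meta)
        assert cm.correlation("A", "B") == 0.45
        assert cm.dataset_count("A") == 3

    def test_symmetry_and_study_relabelling_invariance(self, rng):
        tables = [make_table(f"d{i}", rng.normal(size=200)) for i in range(4)]
        meta_a = {
            "d0": make_metadata("d0", "A", study="S1"),
            "d1": make_metadata("d1", "A", study="S1"),
            "d2": make_metadata("d2", "B", study="S2"),
            "d3": make_metadata("d3", "B", study="S2"),
        }
        # swap which dataset carries which label within each study
        meta_b = {
            "d1": make_metadata("d1", "A", study="S1"),
            "d0": make_metadata("d0", "A", study="S1"),
            "d3": make_metadata("d3", "B", study="S2"),
            "d2": make_metadata("d2", "B", study="S2"),
        }
        pw = am.pairwise_dataset_correlations(tables, min_shared=100)
        ca = am.average_to_interventions(pw, meta_a)
        cb = am.average_to_interventions(pw, meta_b)
        pd.testing.assert_frame_equal(ca.matrix, cb.matrix)
        assert ca.correlation("A", "B") == ca.correlation("B", "A")

    def test_missing_metadata_is_error(self, rng):
        tables = [make_table("d0", rng.normal(size=200)),
                  make_table("d1", rng.normal(size=200))]
        pw = am.pairwise_dataset_correlations(tables, min_shared=100)
        with pytest.raises(MetadataError):
            am.average_to_interventions(pw, {"d0": make_metadata("d0", "A")})


class TestNullThreshold:
    def _null_panel(self, n_iv, n_genes=300, seed=0):
        cfg = SimulationConfig(n_genes=n_genes, n_terms=5, term_size_range=(5, 10),
                               planted_terms={},
                               groups={"null": GroupDesign(n_iv, 1, 1)}, seed=seed)
        cat = am.generate_catalogue(cfg)
        return am.simulate_interventions(cfg, cat)

    def test_quantile_one_returns_maximum(self):
        tables, meta, _ = self._null_panel(6)
        thr = am.estimate_null_threshold(tables, meta, quantile=1.0)
        pw = am.pairwise_dataset_correlations(tables)
        vals = np.abs(pw.to_numpy()[np.triu_indices(len(tables), 1)])
        assert thr == pytest.approx(vals.max())

    def test_duplicate_intervention_contributes_unit_correlation(self):
        tables, meta, _ = self._null_panel(3)
        clone = make_table("clone", tables[0].data["log2fc"],
                           pvalues=tables[0].data["pvalue"],
                           genes=tables[0].data["gene_id"])
        meta = dict(meta)
        meta["clone"] = make_metadata("clone", "clone_iv", group="null")
        thr = am.estimate_null_threshold(tables + [clone], meta, quantile=1.0)
        assert thr == pytest.approx(1.0)

    def test_requires_two_interventions(self):
        tables, meta, _ = self._null_panel(1)
        with pytest.raises(InsufficientDataError):
            am.estimate_null_threshold(tables, meta)

    def test_threshold_calibration_on_large_panel(self):
        # fraction of null pairs above the q-quantile threshold is ~1-q
        tables, meta, _ = self._null_panel(21, n_genes=500, seed=3)
        thr = am.estimate_null_threshold(tables, meta, quantile=0.9)
        cm = am.correlate_datasets(tables, meta)
        frac = np.mean([abs(r) > thr for _, _, r in cm.pairs()])
        assert 0.07 <= frac <= 0.13


class TestGroupSummary:
    def _matrix(self, values):
        ivs = list(values.keys())
        names = sorted({iv for pair in ivs for iv in pair})
        m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for (a, b), r in values.items():
            m.loc[a, b] = m.loc[b, a] = r
        return am.CorrelationMatrix(matrix=m)

    def _meta(self, groups):
        return {f"{iv}_ds": make_metadata(f"{iv}_ds", iv, group=g)
                for iv, g in groups.items()}

    def test_one_sample_t_matches_closed_form(self):
        # same-effect (0.1, 0.2, 0.3): t = 0.2/(0.1/sqrt(3)), df=2
        cm = self._matrix({("L1", "L2"): 0.1, ("L1", "L3"): 0.2, ("L2", "L3"): 0.3,
                           ("L1", "S1"): 0.0, ("L2", "S1"): 0.0, ("L3", "S1"): 0.0})
        meta = self._meta({"L1": "long", "L2": "long", "L3": "long", "S1": "short"})
        summary = am.summarize_groups(cm, meta)
        assert sorted(summary.same_effect) == [0.1, 0.2, 0.3]
        assert summary.t_p_same == pytest.approx(0.0741799, abs=1e-5)

    def test_all_zero_correlations_are_degenerate_safe(self):
        cm = self._matrix({("L1", "L2"): 0.0, ("L1", "L3"): 0.0, ("L2", "L3"): 0.0,
                           ("L1", "S1"): 0.0, ("L2", "S1"): 0.0, ("L3", "S1"): 0.0})
        meta = self._meta({"L1": "long", "L2": "long", "L3": "long", "S1": "short"})
        summary = am.summarize_groups(cm, meta)
        assert summary.fraction_positive_same == 0.0
        assert summary.t_p_same == 1.0

    def test_extreme_separation_rank_sum(self):
        # exact rank-sum: C(6,3)=20 allocations, extreme split -> p = 2/20
        assert rank_sum_pvalue([1, 1, 1], [-1, -1, -1]) == pytest.approx(0.1)

    def test_threshold_flags_significant_pairs(self):
        cm = self._matrix({("L1", "L2"): 0.5, ("L1", "L3"): 0.05, ("L2", "L3"): -0.3,
                           ("L1", "S1"): 0.01, ("L2", "S1"): 0.2, ("L3", "S1"): 0.0})
        meta = self._meta({"L1": "long", "L2": "long", "L3": "long", "S1": "short"})
        summary = am.summarize_groups(cm, meta, threshold=0.15)
        assert summary.significant_same == 2
        assert summary.significant_opposite == 1

    def test_group_recovery_same_beats_opposite(self):
        # with moderate sharing and no planted shifts, same-effect pairs
        # correlate more than opposite-effect pairs in nearly every replicate
        wins = 0
        n_rep = 50
        for seed in range(n_rep):
            cfg = SimulationConfig(
                n_genes=1000, n_terms=5, term_size_range=(5, 10), planted_terms={},
                shared_weight=0.6,
                groups={"long": GroupDesign(4, 1, 1), "short": GroupDesign(4, 1, 1)},
                seed=seed,
            )
            cat = am.generate_catalogue(cfg)
            tables, meta, _ = am.simulate_interventions(cfg, cat)
            cm = am.correlate_datasets(tables, meta)
            summary = am.summarize_groups(cm, meta)
            wins += np.mean(summary.same_effect) > np.mean(summary.opposite_effect)
        assert wins / n_rep >= 0.95

    def test_averaging_stays_in_unit_interval(self, rng):
        tables = [make_table(f"d{i}", rng.normal(size=150)) for i in range(6)]
        meta = {f"d{i}": make_metadata(f"d{i}", f"iv{i % 3}", study=f"s{i % 2}")
                for i in range(6)}
        cm = am.correlate_datasets(tables, meta)
        for _, _, r in cm.pairs():
            assert -1.0 <= r <= 1.0
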