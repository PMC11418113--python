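"""Binned-control cell scoring, hybrid filtering, stage summaries."""

import numpy as np
import pandas as pd
import pytest

from ocsubtypes import (SCSimConfig, ValidationError, assign_and_filter,
                        bin_genes, control_set, generate_singlecell,
                        score_cells, stage_de, stage_proportions,
                        subtype_score)


class TestBinGenes:
    def test_divisible_case(self):
        means = pd.Series(np.arange(60.0), index=[f"g{i:02d}" for i in range(60)])
        bins = bin_genes(means, n_bins=30)
        assert bins.value_counts().eq(2).all()

    def test_remainder_to_last_bin(self):
        means = pd.Series(np.arange(61.0), index=[f"g{i:02d}" for i in range(61)])
        bins = bin_genes(means, n_bins=30)
        counts = bins.value_counts().sort_index()
        assert counts.loc[30] == 3
        assert counts.loc[:29].eq(2).all()

    def test_sorted_by_expression(self):
        means = pd.Series([5.0, 1.0, 3.0], index=["a", "b", "c"])
        bins = bin_genes(means, n_bins=3)
        assert bins["b"] < bins["c"] < bins["a"]

    def test_constant_expression_lexicographic(self):
        means = pd.Series(1.0, index=["d", "b", "a", "c"])
        bins = bin_genes(means, n_bins=2)
        assert bins["a"] == bins["b"] == 1
        assert bins["c"] == bins["d"] == 2

    def test_fewer_genes_than_bins_error(self):
        with pytest.raises(ValidationError):
            bin_genes(pd.Series([1.0, 2.0], index=["a", "b"]), n_bins=30)


class TestControlSet:
    def _bins(self):
        means = pd.Series(np.arange(90.0), index=[f"g{i:02d}" for i in range(90)])
        return bin_genes(means, n_bins=3)  # 3 bins of 30

    def test_confined_to_signature_bin(self):
        bins = self._bins()
        sig = ["g00", "g05"]  # both in bin 1
        ctrl, replaced = control_set(sig, bins, per_bin=10, seed=0)
        assert replaced is False
        assert all(bins[g] == 1 for g in ctrl)
        assert len(ctrl) == 10

    def test_per_bin_equals_bin_size_whole_bin(self):
        bins = self._bins()
        ctrl, replaced = control_set(["g00"], bins, per_bin=30, seed=1)
        assert not replaced
        assert sorted(ctrl) == sorted(bins.index[bins == 1])

    def test_replacement_flagged_for_small_bin(self):
        bins = self._bins()
        ctrl, replaced = control_set(["g00"], bins, per_bin=100, seed=2)
        assert replaced
        assert len(ctrl) == 100

    def test_seed_determinism(self):
        bins = self._bins()
        a, _ = control_set(["g00", "g40"], bins, per_bin=20, seed=5)
        b, _ = control_set(["g00", "g40"], bins, per_bin=20, seed=5)
        assert a == b

    def test_empty_signature_error(self):
        with pytest.raises(ValidationError):
            control_set([], self._bins())


class TestSubtypeScore:
    def test_zero_when_signature_equals_control_mean(self):
        cells = pd.DataFrame({"c0": [2.0, 2.0, 2.0]}, index=["s", "k1", "k2"])
        sc = subtype_score(cells, ["s"], ["k1", "k2"])
        assert sc["c0"] == 0.0

    def test_exact_shift_construction(self):
        """Signature genes shifted +1 over bin-mates with zero noise give
        SC = 1 exactly."""
        genes = [f"g{i:02d}" for i in range(60)]
        base = np.repeat(np.arange(30.0), 2)  # bin-mates share the mean
        col = base.copy()
        sig = ["g10"]  # its bin-mate g11 has the same baseline
        cells = pd.DataFrame({"c0": col}, index=genes)
        cells.loc["g10", "c0"] += 1.0
        bins = bin_genes(cells.mean(axis=1), n_bins=30)
        # control from the signature's bin; g10 and g11 now differ by 1
        ctrl = [g for g in bins.index[bins == bins["g10"]] if g != "g10"]
        sc = subtype_score(cells, sig, ctrl)
        assert sc["c0"] == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance_per_cell(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(rng.normal(size=(20, 5)),
                             index=[f"g{i}" for i in range(20)],
                             columns=[f"c{i}" for i in range(5)])
        sig, ctrl = ["g0", "g1"], ["g5", "g6", "g7"]
        base = subtype_score(cells, sig, ctrl)
        shifted = subtype_score(cells + 3.7, sig, ctrl)
        np.testing.assert_allclose(base, shifted, atol=1e-12)

    def test_disjoint_signature_error(self):
        cells = pd.DataFrame({"c0": [1.0]}, index=["g0"])
        with pytest.raises(ValidationError):
            subtype_score(cells, ["missing"], ["g0"])


class TestAssignAndFilter:
    def _scores(self, rows):
        return pd.DataFrame(rows, columns=["C1", "C2", "C3", "C4"])

    def test_hybrid_all_criteria_met(self):
        out = assign_and_filter(self._scores([[3.0, 2.0, 0.5, 0.1]]))
        assert out["hybrid"].iloc[0]

    def test_retained_when_second_small(self):
        out = assign_and_filter(self._scores([[3.0, 0.5, 0.4, 0.1]]))
        assert not out["hybrid"].iloc[0]
        assert out["assigned"].iloc[0] == "C1"

    def test_all_equal_tie_flagged_first_subtype(self):
        out = assign_and_filter(self._scores([[1.0, 1.0, 1.0, 1.0]]))
        assert out["tie"].iloc[0]
        assert out["assigned"].iloc[0] == "C1"

    def test_and_combination_requires_every_criterion(self):
        # second > 1 and second > 0.1*first, but gap to third <= 0.3
        out = assign_and_filter(self._scores([[3.0, 2.0, 1.9, 0.1]]))
        assert not out["hybrid"].iloc[0]

    def test_assignment_is_argmax(self):
        out = assign_and_filter(self._scores([[0.1, 0.9, 0.3, 0.2]]))
        assert out["assigned"].iloc[0] == "C2"


class TestStageSummaries:
    def test_single_stage_single_subtype(self):
        assig = pd.DataFrame({"assigned": ["C1", "C1"], "hybrid": [False, False]},
                             index=["c0", "c1"])
        stages = pd.Series(["primary", "primary"], index=["c0", "c1"])
        props = stage_proportions(assig, stages)
        assert props.loc["primary", "C1"] == 1.0

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        n = 300
        assig = pd.DataFrame({
            "assigned": rng.choice(["C1", "C2", "C3"], n),
            "hybrid": rng.uniform(size=n) < 0.1,
        }, index=[f"c{i}" for i in range(n)])
        stages = pd.Series(rng.choice(["primary", "relapse"], n),
                           index=assig.index)
        props = stage_proportions(assig, stages)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_planted_mixture_recovered(self):
        """A (0.2, 0.3, 0.4, 0.1) mixture at n=2000 estimated within +-0.03."""
        rng = np.random.default_rng(1)
        n = 2000
        planted = [0.2, 0.3, 0.4, 0.1]
        assig = pd.DataFrame({
            "assigned": rng.choice(["C1", "C2", "C3", "C4"], n, p=planted),
            "hybrid": [False] * n,
        }, index=[f"c{i}" for i in range(n)])
        stages = pd.Series(["primary"] * n, index=assig.index)
        props = stage_proportions(assig, stages)
        for s, p in zip(["C1", "C2", "C3", "C4"], planted):
            assert abs(props.loc["primary", s] - p) < 0.03

    def test_stage_de_identical_stages_empty(self):
        rng = np.random.default_rng(2)
        cells = pd.DataFrame(rng.normal(5, 0.2, (20, 30)),
                             index=[f"g{i}" for i in range(20)],
                             columns=[f"c{i}" for i in range(30)])
        stages = pd.Series(["primary"] * 10 + ["relapse"] * 10
                           + ["metastasis"] * 10, index=cells.columns)
        assert stage_de(cells, stages) == set()

    def test_stage_de_planted_relapse_gene(self):
        rng = np.random.default_rng(3)
        cells = pd.DataFrame(rng.normal(5, 0.2, (20, 60)),
                             index=[f"g{i}" for i in range(20)],
                             columns=[f"c{i}" for i in range(60)])
        stages = pd.Series(["primary"] * 20 + ["relapse"] * 20
                           + ["metastasis"] * 20, index=cells.columns)
        cells.loc["g0", stages == "relapse"] += 3.0
        assert "g0" in stage_de(cells, stages)

    def test_stage_de_infinite_threshold_empty(self):
        rng = np.random.default_rng(4)
        cells = pd.DataFrame(rng.normal(5, 0.2, (10, 30)),
                             index=[f"g{i}" for i in range(10)],
                             columns=[f"c{i}" for i in range(30)])
        stages = pd.Series(["primary"] * 10 + ["relapse"] * 10
                           + ["metastasis"] * 10, index=cells.columns)
        cells.loc["g0", stages == "relapse"] += 3.0
        assert stage_de(cells, stages, lfc=np.inf) == set()


class TestEndToEndScoring:
    def test_null_shift_scores_near_zero(self):
        sigs = {f"C{i+1}": [f"G{i*5+j:05d}" for j in range(5)] for i in range(4)}
        cfg = SCSimConfig(n_cells_per_type_stage=120, signature_shift=0.0,
                          noise_sd=0.5, seed=7)
        cells, table = generate_singlecell(cfg, sigs)
        mal = table.index[table["cell_type"] == "malignant_epithelial"]
        scores = score_cells(cells[mal], sigs, seed=1)
        for s in sigs:
            own = table.loc[mal, "latent_subtype"] == s
            vals = scores.loc[own.index[own], s]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean()) < 3 * se + 1e-9

    def test_assignment_accuracy_with_signal(self):
        sigs = {f"C{i+1}": [f"G{i*5+j:05d}" for j in range(5)] for i in range(4)}
        cfg = SCSimConfig(n_cells_per_type_stage=340, signature_shift=1.0,
                          noise_sd=0.5, seed=8)
        cells, table = generate_singlecell(cfg, sigs)
        mal = table.index[table["cell_type"] == "malignant_epithelial"]
        scores = score_cells(cells[mal], sigs, seed=2)
        out = assign_and_filter(scores)
        keep = out.index[~out["hybrid"]]
        acc = (out.loc[keep, "assigned"]
               == table.loc[keep, "latent_subtype"]).mean()
        assert len(mal) >= 1000
        assert acc >= 0.9
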