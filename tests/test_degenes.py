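"""Differential testing, F-scores, and signature intersection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ocsubtypes import (BulkSimConfig, ValidationError, differential_genes,
                        f_scores, generate_bulk, subtype_signatures,
                        tt_tn_sets)
from ocsubtypes.degenes import SubtypeSignature
from conftest import make_matrix


class TestDifferentialGenes:
    def test_identical_groups_empty_up_set(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 4))
        m = make_matrix(np.concatenate([vals, vals], axis=1),
                        samples=[f"s{i}" for i in range(8)])
        table, up = differential_genes(m, [f"s{i}" for i in range(4)],
                                       [f"s{i}" for i in range(4, 8)])
        assert (table["logFC"] == 0).all()
        assert up == set()

    def test_planted_gene_power(self):
        """A +2 log-unit gene at noise 0.3 and n=20/20 is detected in nearly
        every replicate."""
        rng = np.random.default_rng(1)
        hits = 0
        reps = 40
        for _ in range(reps):
            vals = rng.normal(5, 0.3, (30, 40))
            vals[0, :20] += 2.0
            m = make_matrix(vals, samples=[f"s{i}" for i in range(40)])
            _, up = differential_genes(m, [f"s{i}" for i in range(20)],
                                       [f"s{i}" for i in range(20, 40)])
            hits += "g0" in up
        assert hits / reps >= 0.95

    def test_infinite_lfc_threshold_empty(self, small_bulk):
        matrix, truth = small_bulk
        labels = truth["true_subtype"]
        a = labels.index[labels == "C1"]
        b = labels.index[labels == "C2"]
        _, up = differential_genes(matrix, a, b, lfc=np.inf)
        assert up == set()

    def test_overlapping_groups_error(self):
        m = make_matrix(np.ones((3, 6)))
        with pytest.raises(ValidationError, match="overlap"):
            differential_genes(m, ["s0", "s1", "s2"], ["s2", "s3", "s4"])

    def test_bh_is_monotone_step_up(self, small_bulk):
        """BH-adjusted p-values preserve the raw-p ordering."""
        matrix, truth = small_bulk
        labels = truth["true_subtype"]
        table, _ = differential_genes(matrix, labels.index[labels == "C1"],
                                      labels.index[labels == "C2"])
        t = table.sort_values("pvalue")
        assert (t["fdr"].diff().dropna() >= -1e-12).all()
        assert t["fdr"].between(0, 1).all()


class TestTTTNSets:
    def test_no_normals_error(self, small_bulk):
        matrix, truth = small_bulk
        with pytest.raises(ValidationError, match="normal"):
            tt_tn_sets(matrix, truth["true_subtype"], [])

    def test_planted_signature_in_tt(self):
        # effect 3 at mean purity ~0.65 puts the tumor-vs-normal logFC of a
        # planted gene ~2 SD above the threshold of 1, so near-complete
        # recovery is the analytic expectation, not a tuned outcome
        cfg = BulkSimConfig(n_cohorts=2, samples_per_cohort=60, n_genes=150,
                            n_signature_genes_per_subtype=10, effect_size=3.0,
                            noise_sd=0.3, batch_sd=0.0, seed=6)
        matrix, truth = generate_bulk(cfg)
        sets = tt_tn_sets(matrix, truth["true_subtype"],
                          list(matrix.normal_samples()))
        for s, (tt, tn) in sets.items():
            planted = set(truth["signature_genes"][s])
            assert planted <= tt
            # the TN contrast is attenuated by purity (tumors are mixtures),
            # so per-gene recovery is high but not guaranteed
            assert len(planted & tn) / len(planted) >= 0.9

    def test_identical_subtypes_exclude_shared_genes(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 0.2, (20, 26))
        vals[0, :20] += 3.0  # gene up in ALL tumors vs normals, equal across subtypes
        m = make_matrix(vals, samples=[f"s{i}" for i in range(26)])
        labels = pd.Series(["C1"] * 10 + ["C2"] * 10,
                           index=[f"s{i}" for i in range(20)])
        sets = tt_tn_sets(m, labels, [f"s{i}" for i in range(20, 26)])
        assert "g0" not in sets["C1"][0] and "g0" not in sets["C2"][0]
        assert "g0" in sets["C1"][1]  # but it is a TN gene


class TestFScores:
    @staticmethod
    def brute_force_f(groups):
        """Textbook two-loop one-way ANOVA."""
        all_vals = [v for g in groups for v in g]
        grand = sum(all_vals) / len(all_vals)
        ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
        ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
        k, n = len(groups), len(all_vals)
        return (ssb / (k - 1)) / (ssw / (n - k))

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(5, 9))
        m = make_matrix(vals, samples=[f"s{i}" for i in range(9)])
        labels = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=m.sample_ids)
        F = f_scores(m, labels)
        for gi, g in enumerate(m.genes):
            groups = [vals[gi, :3].tolist(), vals[gi, 3:6].tolist(),
                      vals[gi, 6:].tolist()]
            assert F[g] == pytest.approx(self.brute_force_f(groups), abs=1e-10)

    def test_constant_gene_zero(self):
        m = make_matrix(np.ones((2, 8)))
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=m.sample_ids)
        assert f_scores(m, labels)["g0"] == 0.0

    def test_degenerate_infinite_reported_finite(self):
        vals = np.array([[0, 0, 1, 1], [0.0, 1, 0, 1]])
        m = make_matrix(vals)
        labels = pd.Series(["a", "a", "b", "b"], index=m.sample_ids)
        F = f_scores(m, labels)
        assert np.isfinite(F["g0"])
        assert F["g0"] > F["g1"]

    def test_null_mean_matches_f_distribution(self):
        """4 groups of 3 with N(0,1): mean F over many genes ~ d2/(d2-2)."""
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(10000, 12))
        m = make_matrix(vals, samples=[f"s{i}" for i in range(12)])
        labels = pd.Series(sum(([c] * 3 for c in "abcd"), []), index=m.sample_ids)
        F = f_scores(m, labels)
        assert abs(F.mean() - 8 / 6) < 0.05

    def test_small_group_error(self):
        m = make_matrix(np.ones((2, 3)))
        labels = pd.Series(["a", "a", "b"], index=m.sample_ids)
        with pytest.raises(ValidationError):
            f_scores(m, labels)


class TestSubtypeSignatures:
    def _profiles(self, genes):
        rng = np.random.default_rng(0)
        return {s: pd.Series(rng.normal(5, 1, len(genes)), index=genes)
                for s in ("C1", "C2")}

    def test_top_ranked_gene_in_signature(self):
        genes = [f"g{i}" for i in range(20)]
        profs = self._profiles(genes)
        profs["C1"]["g0"] = 100.0  # top FC in both set-3 and set-4 rankings
        normal = pd.Series(5.0, index=genes)
        tt_tn = {"C1": ({"g0"}, {"g0"}), "C2": (set(), set())}
        sigs = subtype_signatures(tt_tn, profs, normal, top_n=5)
        assert "g0" in sigs["C1"].genes

    def test_top_n_zero_empty(self):
        genes = [f"g{i}" for i in range(10)]
        profs = self._profiles(genes)
        normal = pd.Series(5.0, index=genes)
        tt_tn = {"C1": (set(genes), set(genes)), "C2": (set(), set())}
        sigs = subtype_signatures(tt_tn, profs, normal, top_n=0)
        assert sigs["C1"].genes == []

    def test_signatures_shrink_with_top_n(self):
        genes = [f"g{i}" for i in range(30)]
        profs = self._profiles(genes)
        normal = pd.Series(5.0, index=genes)
        tt_tn = {"C1": (set(genes), set(genes)), "C2": (set(), set())}
        big = set(subtype_signatures(tt_tn, profs, normal, top_n=20)["C1"].genes)
        small = set(subtype_signatures(tt_tn, profs, normal, top_n=5)["C1"].genes)
        assert small <= big

    def test_intersection_subset_of_each_set(self):
        sig = SubtypeSignature("C1", {"a", "b"}, {"b", "c"}, {"b", "d"}, {"b"})
        assert sig.genes == ["b"]

    def test_top_n_exceeds_genes_error(self):
        genes = ["g0", "g1"]
        profs = self._profiles(genes)
        tt_tn = {"C1": (set(), set()), "C2": (set(), set())}
        with pytest.raises(ValidationError):
            subtype_signatures(tt_tn, profs, pd.Series(5.0, index=genes), top_n=5)

    def test_planted_recovery_jaccard(self):
        """Planted signature genes recovered with Jaccard >= 0.5 at effect 3
        (the purity-attenuated tumor-vs-normal gate needs effect well above
        the logFC threshold; see test_planted_signature_in_tt)."""
        cfg = BulkSimConfig(n_cohorts=2, samples_per_cohort=60, n_genes=150,
                            n_signature_genes_per_subtype=10, effect_size=3.0,
                            noise_sd=0.3, batch_sd=0.0, seed=13)
        matrix, truth = generate_bulk(cfg)
        from ocsubtypes import infer_compartments
        labels = truth["true_subtype"]
        tumors = matrix.subset_samples(matrix.tumor_samples())
        sets = tt_tn_sets(matrix, labels, list(matrix.normal_samples()))
        profs = infer_compartments(tumors, labels)
        normal_mean = matrix.values[matrix.normal_samples()].mean(axis=1)
        sigs = subtype_signatures(
            sets, {s: p.e_cancer for s, p in profs.items()}, normal_mean,
            top_n=20)
        for s in sigs:
            got = set(sigs[s].genes)
            planted = set(truth["signature_genes"][s])
            jacc = len(got & planted) / len(got | planted)
            assert jacc >= 0.5
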