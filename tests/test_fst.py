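import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radscan import (MISSING, SampleGroups, diversity_summary,
                     pairwise_fst_table, percentile_stratify, wc_fst)
from conftest import make_matrix, uniform_groups
from _oracles import enumerate_two_group_configs, wc_fst_anova_oracle


def _one_locus(groups_dosages):
    """GenotypeMatrix with one locus; groups_dosages is per-group dosage lists."""
    flat = [d for grp in groups_dosages for d in grp]
    labels = [f"g{k}" for k, grp in enumerate(groups_dosages) for _ in grp]
    return make_matrix([flat]), labels


class TestWcFst:
    def test_fixed_difference_is_exactly_one(self):
        g, labels = _one_locus([[0] * 20, [2] * 12, [2] * 11])
        res = wc_fst(g, labels)
        assert res.fst[0] == pytest.approx(1.0, abs=1e-9)

    def test_identical_group_compositions_nonpositive(self):
        g, labels = _one_locus([[0] * 7 + [1] * 7, [0] * 7 + [1] * 7])
        res = wc_fst(g, labels)
        assert res.fst[0] <= 0

    def test_matches_anova_oracle_on_all_small_two_group_configs(self):
        checked = 0
        for g1, g2 in enumerate_two_group_configs(max_n=6):
            g, labels = _one_locus([g1, g2])
            res = wc_fst(g, labels)
            *_, theta = wc_fst_anova_oracle([g1, g2])
            if np.isnan(theta):
                assert not res.defined[0]
            else:
                assert res.fst[0] == pytest.approx(theta, abs=1e-12)
            checked += 1
        assert checked > 2000

    def test_permuted_labels_give_near_zero_multilocus(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, 1000)
        d = rng.binomial(2, p[:, None], size=(1000, 60)).astype(np.int8)
        g = make_matrix(d)
        labels = rng.permutation(np.repeat(["a", "b", "c"], 20))
        assert abs(wc_fst(g, labels).multilocus_fst) < 0.005

    def test_invariant_to_relabeling_and_reordering(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(50, 12)).astype(np.int8)
        g = make_matrix(d)
        labels = np.repeat(["x", "y", "z"], 4)
        base = wc_fst(g, labels)
        relabeled = wc_fst(g, np.char.add("new_", labels))
        assert np.allclose(base.fst, relabeled.fst, equal_nan=True)
        perm = rng.permutation(12)
        reordered = wc_fst(g.take_samples(perm), labels[perm])
        assert np.allclose(base.fst, reordered.fst, equal_nan=True)
        lperm = rng.permutation(50)
        shuffled = wc_fst(g.take_loci(lperm), labels)
        assert shuffled.multilocus_fst == pytest.approx(base.multilocus_fst)

    def test_multilocus_of_repeated_locus_equals_single(self):
        g, labels = _one_locus([[0, 0, 1, 2], [2, 2, 1, 1]])
        single = wc_fst(g, labels)
        stacked = make_matrix(np.repeat(g.dosages, 5, axis=0),
                              stack_ids=list(range(5)))
        multi = wc_fst(stacked, labels)
        assert multi.multilocus_fst == pytest.approx(single.fst[0])

    def test_monomorphic_locus_flagged_undefined(self):
        g, labels = _one_locus([[0, 0, 0], [0, 0, 0]])
        res = wc_fst(g, labels)
        assert not res.defined[0] and np.isnan(res.fst[0])

    def test_group_with_one_called_individual_masked(self):
        d = [[0, 0, 2, MISSING, MISSING, 1]]
        g = make_matrix(d)
        labels = ["a", "a", "a", "b", "b", "b"]  # group b has 1 called ind
        res = wc_fst(g, labels)
        assert not res.defined[0]

    def test_fewer_than_two_groups_errors(self):
        g, _ = _one_locus([[0, 1, 2]])
        with pytest.raises(ValueError, match="two groups"):
            wc_fst(g, ["a", "a", "a"])

    @given(st.integers(0, 2 ** 24 - 1))
    @settings(max_examples=30, deadline=None)
    def test_per_locus_estimates_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        d = rng.integers(0, 3, size=(8, n)).astype(np.int8)
        labels = rng.choice(["a", "b", "c"], size=n)
        if len(set(labels)) < 2:
            labels[: n // 2] = "a"
            labels[n // 2:] = "b"
        res = wc_fst(make_matrix(d), labels)
        ok = res.defined
        assert np.all(res.fst[ok] <= 1.0 + 1e-12)
        assert np.all(res.fst[ok] >= -1.0 - 1e-12)


class TestPairwiseTable:
    def test_three_locations_give_three_pairs_per_stratum(self, small_synthetic):
        g, _, grp, _ = small_synthetic
        table = pairwise_fst_table(g, grp, axis="location")
        assert set(table.stratum) == {"all", "puella", "nigricans", "unicolor"}
        assert all((table.stratum == s).sum() == 3 for s in set(table.stratum))

    def test_identical_groups_nonpositive(self):
        d = np.tile([0, 0, 1, 1, 2, 2], (30, 1)).astype(np.int8)
        g = make_matrix(np.hstack([d, d]))
        grp = SampleGroups({s: ("sp0", "A" if j < 6 else "B")
                            for j, s in enumerate(g.samples)})
        table = pairwise_fst_table(g, grp, axis="location")
        assert (table.fst <= 1e-12).all()

    def test_bad_axis_rejected(self, small_synthetic):
        g, _, grp, _ = small_synthetic
        with pytest.raises(ValueError):
            pairwise_fst_table(g, grp, axis="depth")


class TestDiversity:
    def test_hand_computed_single_locus(self):
        g = make_matrix([[0, 1, 2]])
        grp = SampleGroups({s: ("sp", "L") for s in g.samples})
        row = diversity_summary(g, grp).iloc[0]
        assert row.Ho == pytest.approx(1 / 3)
        assert row.He == pytest.approx(0.6)  # 2n/(2n-1) * 2pq with n=3, p=1/2

    def test_monomorphic_diversity_zero(self):
        g = make_matrix([[0, 0, 0, 0]])
        grp = SampleGroups({s: ("sp", "L") for s in g.samples})
        row = diversity_summary(g, grp).iloc[0]
        assert row.Ho == 0 and row.He == 0 and np.isnan(row.Fis)

    def test_all_heterozygote_ho_is_one(self):
        g = make_matrix([[1, 1, 1, 1]])
        grp = SampleGroups({s: ("sp", "L") for s in g.samples})
        assert diversity_summary(g, grp).iloc[0].Ho == 1.0


class TestPercentileStratify:
    def _result(self, values):
        from radscan.fst import FstResult
        n = len(values)
        vals = np.asarray(values, float)
        return FstResult([f"{i}:0" for i in range(n)], ["a", "b"],
                         vals * 0, vals * 0, vals * 0, vals,
                         np.isfinite(vals), vals * 0, np.ones((n, 2)))

    def test_top_decile_of_one_to_ten(self):
        bins = percentile_stratify(self._result(range(1, 11)), (90,))
        assert bins.bins["90-100"] == ["9:0"]  # value 10 sits at row 9

    def test_bins_partition_defined_loci(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.004, 0.01, 500)
        res = self._result(vals)
        bins = percentile_stratify(res)
        all_ids = [l for lab in bins.labels for l in bins.bins[lab]]
        assert sorted(all_ids) == sorted(np.array(res.locus_ids)[res.defined])
        assert bins.edges == sorted(bins.edges)

    def test_negative_estimates_fall_in_low_bins(self):
        vals = [-0.05, -0.01, 0.0, 0.01, 0.02, 0.3, 0.5, 0.6, 0.7, 0.9]
        bins = percentile_stratify(self._result(vals), (60, 90))
        assert "0:0" in bins.bins["<60"]
        counts = bins.counts
        assert sum(counts.values()) == 10
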