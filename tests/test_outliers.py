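import numpy as np
import pytest

from radscan import (GeneratorConfig, PlantedLocus, SimConfig, calibrate_null,
                     empirical_pq, generate_dataset, pseudo_design_groups,
                     randomized_grouping_scan, repeated_outliers, run_scenario,
                     scan_comparisons, wc_fst)
from radscan.fst import FstResult
from radscan.outliers import NullEnsemble, OutlierScanResult, _het_bins


def _null_from_draws(fst, he, n_bins=1):
    fst = np.asarray(fst, float)
    he = np.asarray(he, float)
    edges, bins = _het_bins(he, n_bins) if n_bins > 1 else (np.array([]), np.zeros(len(he), int))
    by_bin = [np.sort(fst[bins == k]) for k in range(len(edges) + 1)]
    return NullEnsemble(fst, he, edges, by_bin, {"B": len(fst)})


def _fst_result(fst_vals, he_vals):
    n = len(fst_vals)
    fst = np.asarray(fst_vals, float)
    return FstResult([f"{i}:0" for i in range(n)], ["a", "b"],
                     fst * 0, fst * 0, fst * 0, fst, np.isfinite(fst),
                     np.asarray(he_vals, float), np.full((n, 2), 14.0))


class TestEmpiricalPq:
    def test_rank_formula_minimum_p(self):
        null = _null_from_draws(np.linspace(0, 0.5, 999), np.full(999, 0.3))
        obs = _fst_result([0.9], [0.3])
        res = empirical_pq(obs, null)
        assert res.p[0] == pytest.approx(1 / 1000)

    def test_all_p_one_gives_zero_outliers(self):
        null = _null_from_draws(np.full(500, 0.9), np.full(500, 0.3))
        obs = _fst_result([0.0, 0.1, 0.2], [0.3, 0.3, 0.3])
        res = empirical_pq(obs, null)
        assert np.all(res.p == 1.0) and res.n_outliers == 0

    def test_undefined_loci_not_scanned(self):
        null = _null_from_draws(np.linspace(0, 0.5, 100), np.full(100, 0.3))
        obs = _fst_result([0.4, np.nan], [0.3, 0.3])
        res = empirical_pq(obs, null)
        assert np.isnan(res.p[1]) and not res.outlier[1]
        assert res.n_considered == 1

    def test_conditional_quantiles_monotone_with_unconditional(self):
        # higher-He null classes allow higher F_st; a mid-He locus must get
        # a p-value between what the extreme classes would give it
        rng = np.random.default_rng(0)
        he = np.repeat([0.1, 0.3, 0.5], 2000)
        fst = rng.normal(0, 1e-3, 6000) + he * 0.05
        null = _null_from_draws(fst, he, n_bins=3)
        obs_val = 0.02
        ps = []
        for h in (0.1, 0.3, 0.5):
            res = empirical_pq(_fst_result([obs_val], [h]), null)
            ps.append(res.p[0])
        assert ps[0] <= ps[1] <= ps[2]


class TestCalibration:
    def test_self_check_recovers_target(self):
        null = calibrate_null(0.004, n_groups=3, sample_size=14, B=20_000,
                              seed=1, probe_loci=5000)
        assert null.meta["null_mean_fst"] == pytest.approx(0.004, rel=0.10)

    def test_het_classes_well_populated(self):
        null = calibrate_null(0.004, n_groups=3, sample_size=14, B=20_000,
                              seed=2, probe_loci=5000)
        assert null.n_bins >= 20
        assert min(len(b) for b in null.sorted_fst_by_bin) >= null.size / 40

    def test_zero_target_clamped_to_near_panmictic(self):
        null = calibrate_null(0.0, n_groups=2, sample_size=14, B=5_000,
                              seed=3, probe_loci=2000)
        assert null.meta["target_fst"] == pytest.approx(1e-6)
        assert null.meta["null_mean_fst"] < 1e-3

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError, match="range"):
            calibrate_null(0.97, n_groups=2, sample_size=14)

    def test_undefined_observed_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            calibrate_null(float("nan"), n_groups=2, sample_size=14)


@pytest.fixture(scope="module")
def structured_dataset():
    cfg = SimConfig(m=0.02, n_loci=20_000, replicates=1, n_samples_per_rep=1,
                    seed=21, max_generations=400)
    ds = run_scenario(cfg)[0]
    groups = pseudo_design_groups(ds.deme_labels, ds.genotypes.samples)
    return ds, groups


class TestScanComparisons:
    def test_nine_scans_for_three_by_three_design(self, structured_dataset):
        ds, groups = structured_dataset
        scans = scan_comparisons(ds.genotypes, groups, B=10_000, seed=5)
        assert len(scans) == 9
        assert len({s.comparison for s in scans}) == 9

    def test_null_data_yields_no_outliers(self, structured_dataset):
        ds, groups = structured_dataset
        scans = scan_comparisons(ds.genotypes, groups, B=20_000, seed=5)
        total = sum(s.n_outliers for s in scans)
        considered = sum(s.n_considered for s in scans)
        assert 100 * total / considered <= 0.02
        assert len(repeated_outliers(scans).repeated) == 0

    def test_missing_location_skipped_with_warning(self, small_synthetic, caplog):
        import logging
        g, _, groups, _ = small_synthetic
        keep = [j for j, s in enumerate(g.samples)
                if not (groups.assignment[s] == ("puella", "panama"))]
        gsub = g.take_samples(np.array(keep))
        with caplog.at_level(logging.WARNING):
            scans = scan_comparisons(gsub, groups, B=5_000, seed=6)
        assert len(scans) == 7  # both puella pairs involving panama drop
        assert any("skipped" in r.message for r in caplog.records)

    def test_planted_divergent_loci_recovered(self):
        # discoverability needs the empirical-p floor 1/(B_class+1) to sit
        # below q * rank / m, hence the full-size null ensemble here
        planted = tuple(PlantedLocus("location_divergent", 0.6) for _ in range(3))
        cfg = GeneratorConfig(n_stacks=2000, seed=31, planted=planted)
        g, _, groups, truth = generate_dataset(cfg)
        scans = scan_comparisons(g, groups, B=200_000, seed=7)
        flagged = set().union(*(s.outlier_ids for s in scans))
        assert set(truth.ids_of_kind("location_divergent")) <= flagged

    def test_global_mode_one_scan_per_species(self, structured_dataset):
        ds, groups = structured_dataset
        scans = scan_comparisons(ds.genotypes, groups, mode="global_per_species",
                                 B=10_000, seed=8)
        assert len(scans) == 3
        assert all(s.comparison.endswith(":global") for s in scans)

    def test_null_pvalues_super_uniform(self, structured_dataset):
        ds, groups = structured_dataset
        scans = scan_comparisons(ds.genotypes, groups, B=20_000, seed=5)
        p = np.concatenate([s.p[np.isfinite(s.p)] for s in scans])
        grid = np.linspace(0.01, 0.99, 50)
        ecdf = np.searchsorted(np.sort(p), grid, side="right") / len(p)
        assert np.max(ecdf - grid) < 0.02  # P(p <= x) <= x up to noise


def _scan_stub(comparison, species, outliers, considered):
    n = len(considered)
    p = np.full(n, 0.5)
    out = np.array([l in outliers for l in considered])
    return OutlierScanResult(comparison, list(considered), np.zeros(n), np.zeros(n),
                             p, p, out, 0.2, {"species": species, "pair": ("A", "B")})


class TestRepeatedOutliers:
    def test_shared_locus_is_triple_repeat(self):
        scans = [_scan_stub(f"sp{i}:A-B", f"sp{i}", {"7:0"}, ["7:0", f"{i}:1"])
                 for i in range(3)]
        rep = repeated_outliers(scans)
        assert rep.repeated == {"7:0"}
        assert rep.triple_repeated == {"7:0"}
        assert rep.same_pair_repeated == {"7:0"}

    def test_disjoint_sets_give_no_repeats(self):
        scans = [_scan_stub(f"sp{i}:A-B", f"sp{i}", {f"{i}:0"}, [f"{i}:0"])
                 for i in range(3)]
        rep = repeated_outliers(scans)
        assert rep.repeated == set() and rep.triple_repeated == set()

    def test_shared_consideration_ratio(self):
        # sp0 flags 2 loci: one considered by sp1, one private to sp0
        scans = [
            _scan_stub("sp0:A-B", "sp0", {"1:0", "2:0"}, ["1:0", "2:0"]),
            _scan_stub("sp1:A-B", "sp1", set(), ["1:0", "3:0"]),
        ]
        rep = repeated_outliers(scans)
        assert rep.shared_consideration_ratio == pytest.approx(0.5)


class TestRandomizedGrouping:
    def test_same_seed_same_grouping_and_near_zero_fst(self, small_synthetic):
        g, _, _, _ = small_synthetic
        res1, rep1 = randomized_grouping_scan(g, seed=4, B=10_000)
        res2, rep2 = randomized_grouping_scan(g, seed=4, B=10_000)
        assert res1.multilocus_fst == res2.multilocus_fst
        assert abs(res1.multilocus_fst) < 0.002
        assert len(rep1.repeated) == 0

    def test_too_few_individuals_rejected(self):
        from conftest import make_matrix
        g = make_matrix(np.zeros((3, 10), dtype=np.int8))
        with pytest.raises(ValueError, match="too few"):
            randomized_grouping_scan(g)
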