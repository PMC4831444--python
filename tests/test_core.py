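import numpy as np
import pytest

from radscan import (MISSING, CoverageMatrix, GenotypeMatrix, LocusAnnotation,
                     SampleGroups, filter_heterozygosity,
                     filter_individuals_by_missingness, filter_loci_by_coverage,
                     filter_rare_alleles, match_coverage,
                     select_first_snp_per_stack)
from conftest import make_matrix, uniform_groups


class TestGenotypeMatrix:
    def test_rejects_out_of_range_dosage(self):
        with pytest.raises(ValueError, match="dosages"):
            make_matrix([[0, 3]])

    def test_rejects_duplicate_locus_ids(self):
        with pytest.raises(ValueError, match="unique"):
            make_matrix([[0, 1], [1, 2]], stack_ids=[5, 5], offsets=[0, 0])

    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError, match="differ"):
            LocusAnnotation(1, 0, "A", "A")

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="match"):
            GenotypeMatrix(np.zeros((2, 3), dtype=np.int8),
                           [LocusAnnotation(0), LocusAnnotation(1)], ["a", "b"])


def _coverage_fixture(counts_at_depth, min_depth=10):
    """One single-SNP stack; per location, `counts_at_depth[k]` individuals
    at depth >= min_depth (rest at min_depth - 1)."""
    per_loc = max(counts_at_depth) + 5
    n = 3 * per_loc
    g = make_matrix([[0] * n])
    depth = np.full((1, n), min_depth - 1, dtype=np.int32)
    assignment = {}
    for j, s in enumerate(g.samples):
        loc = j // per_loc
        assignment[s] = ("sp0", f"loc{loc}")
        if j % per_loc < counts_at_depth[loc]:
            depth[0, j] = min_depth
    return g, CoverageMatrix(depth), SampleGroups(assignment)


class TestCoverageFilter:
    def test_two_of_three_locations_qualify(self):
        g, c, grp = _coverage_fixture((16, 3, 20))
        out = filter_loci_by_coverage(g, c, grp, min_depth=10, min_inds=15, min_groups=2)
        assert out.n_loci == 1

    def test_one_location_qualifying_is_removed(self):
        g, c, grp = _coverage_fixture((16, 3, 3))
        out = filter_loci_by_coverage(g, c, grp, min_depth=10, min_inds=15, min_groups=2)
        assert out.n_loci == 0

    def test_threshold_is_inclusive(self):
        g, c, grp = _coverage_fixture((20, 20, 20))
        c_low = CoverageMatrix(np.full_like(c.depth, 9))
        assert filter_loci_by_coverage(g, c_low, grp, 10, 15, 2).n_loci == 0
        c_eq = CoverageMatrix(np.full_like(c.depth, 10))
        assert filter_loci_by_coverage(g, c_eq, grp, 10, 15, 2).n_loci == 1

    def test_stack_passes_or_fails_as_a_unit(self):
        # stack 7 has two SNPs with depths 20 and 2: mean 11 passes at 10x
        g = make_matrix([[0] * 40, [0] * 40], stack_ids=[7, 7], offsets=[0, 1])
        depth = np.vstack([np.full(40, 20), np.full(40, 2)]).astype(np.int32)
        grp = uniform_groups(g.samples, n_locations=2)
        out = filter_loci_by_coverage(g, CoverageMatrix(depth), grp,
                                      min_depth=10, min_inds=5, min_groups=2)
        assert out.n_loci == 2  # both SNPs of the stack retained together

    def test_unknown_sample_metadata_errors(self):
        g, c, _ = _coverage_fixture((16, 3, 20))
        with pytest.raises(KeyError):
            filter_loci_by_coverage(g, c, SampleGroups({}), 10, 15, 2)


class TestRareAlleleFilter:
    def test_single_carrier_per_location_removed(self):
        # 6 samples over 3 locations (round-robin); het in one sample/location
        d = [[1, 0, 1, 0, 1, 0]]  # carriers at columns 0,2,4 -> one per location
        g = make_matrix(d, samples=[f"s{j}" for j in range(6)])
        grp = uniform_groups(g.samples, n_locations=3)
        assert filter_rare_alleles(g, grp).n_loci == 0

    def test_two_carriers_in_one_location_retained(self):
        d = [[1, 1, 0, 0, 0, 0]]
        g = make_matrix(d)
        grp = SampleGroups({s: ("sp0", "locA" if j < 2 else "locB")
                            for j, s in enumerate(g.samples)})
        assert filter_rare_alleles(g, grp).n_loci == 1

    def test_monomorphic_locus_retained(self):
        g = make_matrix([[0, 0, 0, 0, 0, 0], [2, 2, 2, 2, 2, 2]])
        grp = uniform_groups(g.samples, n_locations=3)
        assert filter_rare_alleles(g, grp).n_loci == 2

    def test_minor_allele_is_the_globally_rarer_one(self):
        # alt is the major allele here; ref (minor) carried by one individual
        d = [[2, 2, 2, 2, 2, 1]]
        g = make_matrix(d)
        grp = SampleGroups({s: ("sp0", "locA") for s in g.samples})
        assert filter_rare_alleles(g, grp).n_loci == 0


class TestHeterozygosityFilter:
    def test_excess_heterozygosity_removed(self):
        d = [[1] * 8 + [0, 2]]  # 8/10 heterozygotes
        assert filter_heterozygosity(make_matrix(d), 0.5).n_loci == 0

    def test_boundary_not_exceeded_is_kept(self):
        d = [[1] * 5 + [0] * 5]  # exactly 0.5
        assert filter_heterozygosity(make_matrix(d), 0.5).n_loci == 1

    def test_all_missing_locus_dropped(self):
        d = [[MISSING] * 4, [1, 0, 0, 0]]
        out = filter_heterozygosity(make_matrix(d), 0.5)
        assert out.n_loci == 1 and out.loci[0].stack_id == 1


class TestFirstSnpPerStack:
    def test_smallest_offset_kept(self):
        g = make_matrix([[0, 1], [1, 2]], stack_ids=[3, 3], offsets=[63, 12])
        out = select_first_snp_per_stack(g)
        assert out.n_loci == 1 and out.loci[0].snp_offset == 12

    def test_single_snp_stack_unchanged(self):
        g = make_matrix([[0, 1]], stack_ids=[9])
        out = select_first_snp_per_stack(g)
        assert out.locus_ids == g.locus_ids

    def test_output_stacks_unique(self, small_synthetic):
        g = select_first_snp_per_stack(small_synthetic[0])
        assert len(set(g.stack_ids)) == g.n_loci


class TestIndividualMissingness:
    def test_above_threshold_dropped_boundary_kept(self):
        d = np.zeros((20, 3), dtype=np.int8)
        d[:5, 0] = MISSING   # 25%
        d[:4, 1] = MISSING   # exactly 20%
        g = make_matrix(d)
        out = filter_individuals_by_missingness(g, 0.2)
        assert out.samples == ["s1", "s2"]

    def test_max_one_is_identity(self, small_synthetic):
        g = small_synthetic[0]
        assert filter_individuals_by_missingness(g, 1.0).samples == g.samples


@pytest.mark.parametrize("filt", [
    lambda g, grp: filter_rare_alleles(g, grp),
    lambda g, grp: filter_heterozygosity(g, 0.5),
    lambda g, grp: select_first_snp_per_stack(g),
    lambda g, grp: filter_individuals_by_missingness(g, 0.1),
])
def test_filters_are_idempotent(small_synthetic, filt):
    g, cov, grp, _ = small_synthetic
    once = filt(g, grp)
    twice = filt(once, grp)
    assert once.locus_ids == twice.locus_ids
    assert once.samples == twice.samples
    assert np.array_equal(once.dosages, twice.dosages)


def test_coverage_filter_idempotent(small_synthetic):
    g, cov, grp, _ = small_synthetic
    once = filter_loci_by_coverage(g, cov, grp, 10, 5, 2)
    cov1 = match_coverage(cov, g, once)
    twice = filter_loci_by_coverage(once, cov1, grp, 10, 5, 2)
    assert once.locus_ids == twice.locus_ids


def test_match_coverage_preserves_missing_invariant(small_synthetic):
    g, cov, grp, _ = small_synthetic
    sub = filter_heterozygosity(filter_rare_alleles(g, grp), 0.5)
    cov_sub = match_coverage(cov, g, sub)
    cov_sub.validate_against(sub)
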