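import numpy as np
import pytest

from radscan import (CoverageMatrix, GenotypeMatrix, GeneratorConfig,
                     LocusAnnotation, SampleGroups, generate_dataset)


def make_matrix(dosages, stack_ids=None, samples=None, offsets=None):
    """Build a small GenotypeMatrix from a nested list (loci x samples)."""
    d = np.asarray(dosages, dtype=np.int8)
    L, N = d.shape
    stack_ids = stack_ids if stack_ids is not None else list(range(L))
    offsets = offsets if offsets is not None else [0] * L
    loci = [LocusAnnotation(int(s), int(o)) for s, o in zip(stack_ids, offsets)]
    samples = samples if samples is not None else [f"s{j}" for j in range(N)]
    return GenotypeMatrix(d, loci, samples)


def uniform_groups(samples, n_locations=3, n_species=1):
    """Assign samples round-robin to a species x location grid."""
    assignment = {}
    for k, s in enumerate(samples):
        cell = k % (n_locations * n_species)
        assignment[s] = (f"sp{cell // n_locations}", f"loc{cell % n_locations}")
    return SampleGroups(assignment)


@pytest.fixture(scope="session")
def small_synthetic():
    """Default-structure synthetic dataset at reduced stack count."""
    cfg = GeneratorConfig(n_stacks=1500, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def unstructured_synthetic():
    cfg = GeneratorConfig(n_stacks=1500, seed=43, f_loc=0.0, f_sp=0.0)
    return generate_dataset(cfg)
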