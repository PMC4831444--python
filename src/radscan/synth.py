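"""Synthetic RAD-genotype generator with hierarchical divergence structure.

Emulates the study design the pipeline targets: 3 sympatric species x 3
locations with 14 diploids per cell (126 individuals), ~30,000 stacks
carrying ~1.8 SNPs each (max 3), shallow background divergence (multilocus
F_st ~ 0.004 along both axes), negative-binomial read depth with mean ~31x,
and depth-driven plus random missingness.  Divergence is built with a
Balding-Nichols hierarchy: per SNP, location frequencies are drawn around
the ancestral frequency with parameter F_loc, then species frequencies
within each location with F_sp.  SNPs within a stack share their ancestral
frequency (plus a small jitter), reproducing the within-stack redundancy
that the one-SNP-per-stack filter must resolve.

Planted loci (divergent outliers, a fixed difference, linked blocks)
overwrite the neutral frequencies and are recorded in a truth table for
recovery tests.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import MISSING, CoverageMatrix, GenotypeMatrix, LocusAnnotation, SampleGroups

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedLocus:
    """Ground-truth description of one planted signal."""

    kind: str                    #: location_divergent | species_divergent | fixed_difference | linked_block
    target: float                #: target F_st (divergent kinds) or r^2 (blocks)
    affected: tuple[str, ...] = ()  #: labels involved (e.g. the fixed location)
    size: int = 1                #: loci in a linked block

    def __post_init__(self) -> None:
        kinds = ("location_divergent", "species_divergent", "fixed_difference", "linked_block")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")


@dataclass
class GeneratorConfig:
    species: tuple[str, ...] = ("puella", "nigricans", "unicolor")
    locations: tuple[str, ...] = ("belize", "honduras", "panama")
    n_per_cell: int = 14
    n_stacks: int = 30_000
    #: SNPs per stack: P(1)=0.45, P(2)=0.30, P(3)=0.25 -> mean 1.8, max 3
    snps_per_stack_probs: tuple[float, ...] = (0.45, 0.30, 0.25)
    f_loc: float = 0.004            #: Balding-Nichols divergence among locations
    f_sp: float = 0.004             #: ... among species within a location
    beta_a: float = 0.8             #: ancestral-frequency law Beta(a, b)
    beta_b: float = 0.8
    freq_bounds: tuple[float, float] = (0.02, 0.98)
    stack_jitter: float = 0.03      #: sd of within-stack frequency jitter
    depth_mean: float = 31.0        #: negative-binomial mean per stack x individual
    depth_shape: float = 8.0        #: NB dispersion (smaller = more overdispersed)
    depth_min_call: int = 10        #: below this, the genotype is uncalled
    mcar_rate: float = 0.02         #: additional missing-completely-at-random rate
    planted: tuple[PlantedLocus, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.f_loc < 1 and 0 <= self.f_sp < 1):
            raise ValueError("divergence parameters must be in [0, 1)")
        if self.n_per_cell < 2:
            raise ValueError("need >= 2 individuals per cell")
        if abs(sum(self.snps_per_stack_probs) - 1) > 1e-9:
            raise ValueError("snps_per_stack_probs must sum to 1")


@dataclass
class SyntheticTruth:
    """Realised planted loci: plan entry -> emitted locus ids."""

    planted: list[tuple[PlantedLocus, list[str]]]

    def ids_of_kind(self, kind: str) -> list[str]:
        return [lid for pl, ids in self.planted for lid in ids if pl.kind == kind]

    @property
    def all_ids(self) -> set:
        return {lid for _, ids in self.planted for lid in ids}


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float, size: int) -> np.ndarray:
    """Draw `size` daughter frequencies per ancestral p (columns) under the
    Balding-Nichols beta model; F = 0 degenerates to identical copies."""
    if f <= 0:
        return np.tile(p, (size, 1))
    lam = (1 - f) / f
    a = np.clip(p * lam, 1e-6, None)
    b = np.clip((1 - p) * lam, 1e-6, None)
    return rng.beta(a, b, size=(size, len(p)))


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[GenotypeMatrix, CoverageMatrix, SampleGroups, SyntheticTruth]:
    """Generate one synthetic dataset (genotypes, depths, metadata, truth)."""
    rng = np.random.default_rng(cfg.seed)
    n_sp, n_loc = len(cfg.species), len(cfg.locations)
    n_cells = n_sp * n_loc
    n_ind = n_cells * cfg.n_per_cell

    # ---- stacks and loci ---------------------------------------------------
    snps_per_stack = rng.choice(
        np.arange(1, len(cfg.snps_per_stack_probs) + 1),
        size=cfg.n_stacks, p=cfg.snps_per_stack_probs,
    )
    stack_of_snp = np.repeat(np.arange(cfg.n_stacks), snps_per_stack)
    offsets = np.concatenate([np.arange(c) for c in snps_per_stack])
    L = len(stack_of_snp)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, L)
    alt_idx = (ref_idx + rng.integers(1, 4, L)) % 4  # always != ref
    loci = [
        LocusAnnotation(int(s), int(o), r, a)
        for s, o, r, a in zip(stack_of_snp, offsets, bases[ref_idx], bases[alt_idx])
    ]

    # ---- hierarchical frequencies ------------------------------------------
    lo, hi = cfg.freq_bounds
    p_stack = np.clip(rng.beta(cfg.beta_a, cfg.beta_b, cfg.n_stacks), lo, hi)
    p_anc = np.clip(
        p_stack[stack_of_snp] + rng.normal(0, cfg.stack_jitter, L), lo, hi
    )
    # Crossed Balding-Nichols effects: a location deviation shared by all
    # species and a species deviation shared by all locations.  Sharing the
    # species effect across locations is what makes the species axis carry
    # its full F_sp as a main effect (sympatric species are "the same
    # species" everywhere); a literal location-then-species hierarchy would
    # dilute the species-axis F_st to F_sp / n_locations and inflate the
    # location axis by the same amount.
    p_loc = np.clip(_balding_nichols(rng, p_anc, cfg.f_loc, n_loc), 0.0, 1.0)  # (n_loc, L)
    p_sp = np.clip(_balding_nichols(rng, p_anc, cfg.f_sp, n_sp), 0.0, 1.0)     # (n_sp, L)
    cell_freq = np.empty((n_cells, L))
    for i in range(n_sp):
        for j in range(n_loc):
            cell_freq[i * n_loc + j] = np.clip(p_loc[j] + p_sp[i] - p_anc, 0.0, 1.0)

    # ---- planting ----------------------------------------------------------
    truth_entries: list[tuple[PlantedLocus, list[str]]] = []
    blocks: list[tuple[PlantedLocus, np.ndarray]] = []
    # plantable loci: one per stack (first SNP) far from already-used rows
    candidate_rows = np.flatnonzero(offsets == 0)
    rng.shuffle(candidate_rows)
    cursor = 0
    for pl in cfg.planted:
        take = pl.size if pl.kind == "linked_block" else 1
        if pl.kind == "linked_block" and pl.size < 2:
            warnings.warn("linked block of size < 2 is a no-op", stacklevel=2)
            truth_entries.append((pl, []))
            continue
        rows = candidate_rows[cursor:cursor + take]
        cursor += take
        ids = [loci[r].locus_id for r in rows]
        if pl.kind == "fixed_difference":
            focal = pl.affected[0] if pl.affected else cfg.locations[0]
            j = cfg.locations.index(focal)
            for i in range(n_sp):
                for jj in range(n_loc):
                    cell_freq[i * n_loc + jj, rows] = 0.0 if jj == j else 1.0
        elif pl.kind in ("location_divergent", "species_divergent"):
            delta = np.sqrt(1.5 * pl.target * 0.25)  # var{+d,-d,0}=2d^2/3 = F * pq
            pattern = np.array([0.5 + delta, 0.5 - delta, 0.5])
            for i in range(n_sp):
                for jj in range(n_loc):
                    k = jj if pl.kind == "location_divergent" else i
                    cell_freq[i * n_loc + jj, rows] = pattern[k % 3]
        else:  # linked_block: generated at the genotype stage
            blocks.append((pl, rows))
        truth_entries.append((pl, ids))

    # ---- genotypes (HWE within cells) --------------------------------------
    dosages = np.empty((L, n_ind), dtype=np.int8)
    samples: list[str] = []
    assignment: dict[str, tuple[str, str]] = {}
    for c in range(n_cells):
        sp, locn = cfg.species[c // n_loc], cfg.locations[c % n_loc]
        colslice = slice(c * cfg.n_per_cell, (c + 1) * cfg.n_per_cell)
        dosages[:, colslice] = rng.binomial(
            2, np.repeat(cell_freq[c][:, None], cfg.n_per_cell, axis=1)
        )
        for k in range(cfg.n_per_cell):
            name = f"{sp}_{locn}_{k:02d}"
            samples.append(name)
            assignment[name] = (sp, locn)

    # linked blocks: two latent haplotypes per individual, per-locus allele
    # copied from the haplotype with a flip probability tuned to the target r^2
    for pl, rows in blocks:
        e = (1 - pl.target ** 0.25) / 2.0
        hap = rng.random((2, n_ind)) < 0.5
        for r in rows:
            flips = rng.random((2, n_ind)) < e
            dosages[r] = (hap ^ flips).sum(axis=0)

    # ---- depth and missingness ----------------------------------------------
    nb_p = cfg.depth_shape / (cfg.depth_shape + cfg.depth_mean)
    stack_depth = rng.negative_binomial(cfg.depth_shape, nb_p, size=(cfg.n_stacks, n_ind))
    depth = stack_depth[stack_of_snp].astype(np.int32)
    missing = depth < cfg.depth_min_call
    missing |= rng.random((L, n_ind)) < cfg.mcar_rate
    dosages[missing] = MISSING
    depth = np.where(missing, 0, depth)

    g = GenotypeMatrix(dosages, loci, samples)
    cov = CoverageMatrix(depth)
    cov.validate_against(g)
    groups = SampleGroups(assignment)
    logger.info("generated %d SNPs in %d stacks x %d individuals (%.2f SNP/stack), "
                "missingness %.1f%%", L, cfg.n_stacks, n_ind, L / cfg.n_stacks,
                100 * missing.mean())
    return g, cov, groups, SyntheticTruth(truth_entries)


def plant_linked_block(cfg: GeneratorConfig, size: int, r2: float) -> GeneratorConfig:
    """Return a config with an added block of ``size`` loci whose realised
    median pairwise r^2 approaches ``r2`` (latent shared haplotype with
    per-locus copy errors).  ``size`` 1 is a no-op (warned)."""
    if size < 2:
        warnings.warn("linked block of size < 2 has no pairwise LD; no-op", stacklevel=2)
        return cfg
    if not (0 < r2 <= 1):
        raise ValueError("target r^2 must be in (0, 1]")
    return replace(cfg, planted=(*cfg.planted, PlantedLocus("linked_block", r2, size=size)))
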