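"""Genotype/depth data model and the SNP / individual filtering rules.

The exchange object throughout the package is :class:`GenotypeMatrix`: a
loci x individuals matrix of diploid alternate-allele dosages (0, 1, 2) with
an explicit ``MISSING`` sentinel (never conflated with dosage 0).  RAD loci
are organised in *stacks* (de novo assembled read piles); a stack may carry
several SNPs, identified by their 0-based offset within the stack.

Filters mirror the standard RAD-seq quality rules for this kind of study:
per-stack coverage thresholds, removal of rare alleles and of loci with
excess heterozygosity, one SNP per stack, and per-individual missingness
limits.  All filters are pure functions returning new matrices and are
idempotent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype.  Distinct from dosage 0 (hom-ref).
MISSING: int = -1

VALID_AXES = ("location", "species", "species_location")


@dataclass(frozen=True)
class LocusAnnotation:
    """Identity of one SNP: its stack, offset within the stack, and alleles."""

    stack_id: int
    snp_offset: int = 0
    ref: str = "A"
    alt: str = "C"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles must differ (stack {self.stack_id})")

    @property
    def locus_id(self) -> str:
        return f"{self.stack_id}:{self.snp_offset}"


@dataclass
class GenotypeMatrix:
    """Loci x individuals alt-allele dosage matrix with a missing-data mask.

    Parameters
    ----------
    dosages
        ``(n_loci, n_samples)`` integer array with entries in ``{0, 1, 2}``
        or :data:`MISSING`.
    loci
        One :class:`LocusAnnotation` per row; ``(stack_id, snp_offset)``
        pairs must be unique.
    samples
        Ordered sample identifiers, one per column.
    """

    dosages: np.ndarray
    loci: list[LocusAnnotation]
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (loci x samples)")
        if self.dosages.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.loci)} loci x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or MISSING")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus identifiers (stack_id, snp_offset) must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_loci(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    @property
    def stack_ids(self) -> np.ndarray:
        return np.array([l.stack_id for l in self.loci])

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the genotype is uncalled."""
        return self.dosages == MISSING

    # -- subsetting --------------------------------------------------------
    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[index],
            [self.loci[i] for i in index],
            list(self.samples),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            list(self.loci),
            [self.samples[i] for i in index],
        )


@dataclass
class CoverageMatrix:
    """Per-genotype read depth aligned to a :class:`GenotypeMatrix`."""

    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int32)
        if (self.depth < 0).any():
            raise ValueError("read depths must be non-negative")

    def validate_against(self, g: GenotypeMatrix) -> None:
        if self.depth.shape != g.dosages.shape:
            raise ValueError("coverage shape does not match genotype matrix")
        if (self.depth[g.missing] != 0).any():
            raise ValueError("depth must be 0 wherever the genotype is missing")

    def take_loci(self, index: np.ndarray) -> "CoverageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CoverageMatrix(self.depth[index])

    def take_samples(self, index: np.ndarray) -> "CoverageMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CoverageMatrix(self.depth[:, index])


@dataclass
class SampleGroups:
    """Two-factor sample metadata: sample -> (species, location).

    The 3 species x 3 locations design of the study is a convention only;
    labels are opaque strings and any factorial layout is accepted.
    """

    assignment: Mapping[str, tuple[str, str]]

    def require_cover(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.assignment]
        if missing:
            raise KeyError(f"samples without metadata assignment: {missing[:5]}")

    def labels(self, samples: Sequence[str], by: str = "location") -> np.ndarray:
        """Group label per sample along an axis in ``{species, location, species_location}``."""
        if by not in VALID_AXES:
            raise ValueError(f"axis must be one of {VALID_AXES}, got {by!r}")
        self.require_cover(samples)
        out = []
        for s in samples:
            sp, loc = self.assignment[s]
            out.append({"species": sp, "location": loc, "species_location": f"{sp}|{loc}"}[by])
        return np.array(out)

    def units(self, samples: Sequence[str], by: str = "location") -> list[str]:
        return sorted(set(self.labels(samples, by)))

    def species_levels(self) -> list[str]:
        return sorted({sp for sp, _ in self.assignment.values()})

    def location_levels(self) -> list[str]:
        return sorted({loc for _, loc in self.assignment.values()})


# ---------------------------------------------------------------------------
# locus-level summaries used by several filters


def _allele_counts(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies, called individuals) per locus."""
    called = d != MISSING
    alt = np.where(called, d, 0).sum(axis=1)
    return alt, called.sum(axis=1)


def observed_heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Fraction of heterozygotes among non-missing calls, NaN if all missing."""
    called = ~g.missing
    n = called.sum(axis=1)
    het = (g.dosages == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, het / np.maximum(n, 1), np.nan)


# ---------------------------------------------------------------------------
# filters


def filter_loci_by_coverage(
    g: GenotypeMatrix,
    c: CoverageMatrix,
    groups: SampleGroups,
    min_depth: int = 10,
    min_inds: int = 15,
    min_groups: int = 2,
    group_by: str = "location",
) -> GenotypeMatrix:
    """Retain stacks with depth >= ``min_depth`` in >= ``min_inds`` individuals
    per grouping unit, in >= ``min_groups`` units.

    Filtering acts at the *stack* level: a stack passes or fails as a unit,
    judged on its mean depth across its SNPs (coverage in RAD data is a
    property of the read pile, not of individual SNPs within it).
    """
    if min_depth <= 0 or min_inds <= 0 or min_groups <= 0:
        raise ValueError("coverage-filter thresholds must be positive")
    c.validate_against(g)
    labels = groups.labels(g.samples, by=group_by)
    units = np.unique(labels)
    if len(units) < min_groups:
        raise ValueError(
            f"only {len(units)} grouping unit(s) in metadata, need >= {min_groups}"
        )

    stack_ids = g.stack_ids
    uniq, inverse = np.unique(stack_ids, return_inverse=True)
    # mean depth per stack x individual
    sums = np.zeros((len(uniq), g.n_samples))
    counts = np.zeros(len(uniq))
    np.add.at(sums, inverse, c.depth.astype(float))
    np.add.at(counts, inverse, 1.0)
    stack_depth = sums / counts[:, None]

    deep = stack_depth >= min_depth
    qualifying = np.zeros(len(uniq), dtype=int)
    for u in units:
        cols = labels == u
        qualifying += deep[:, cols].sum(axis=1) >= min_inds
    keep_stack = qualifying >= min_groups
    keep = keep_stack[inverse]
    logger.info(
        "coverage filter (>=%dx in >=%d inds in >=%d %s units): kept %d/%d stacks, %d/%d SNPs",
        min_depth, min_inds, min_groups, group_by,
        int(keep_stack.sum()), len(uniq), int(keep.sum()), g.n_loci,
    )
    return g.take_loci(keep)


def filter_rare_alleles(
    g: GenotypeMatrix, groups: SampleGroups, group_by: str = "location"
) -> GenotypeMatrix:
    """Drop loci whose minor allele is carried by <= 1 individual in *every*
    grouping unit.  Monomorphic loci have no minor allele and are retained
    (they are handled downstream by the estimators)."""
    labels = groups.labels(g.samples, by=group_by)
    alt, n = _allele_counts(g.dosages)
    # global minor allele: alt if alt copies <= ref copies else ref
    minor_is_alt = alt <= (2 * n - alt)
    d = g.dosages
    carries_minor = np.where(
        minor_is_alt[:, None], (d == 1) | (d == 2), (d == 1) | (d == 0)
    )
    carries_minor &= d != MISSING
    max_carriers = np.zeros(g.n_loci, dtype=int)
    for u in np.unique(labels):
        cols = labels == u
        np.maximum(max_carriers, carries_minor[:, cols].sum(axis=1), out=max_carriers)
    monomorphic = (alt == 0) | (alt == 2 * n)
    keep = monomorphic | (max_carriers > 1)
    logger.info("rare-allele filter: removed %d/%d loci", int((~keep).sum()), g.n_loci)
    return g.take_loci(keep)


def filter_heterozygosity(g: GenotypeMatrix, max_het: float = 0.5) -> GenotypeMatrix:
    """Drop loci with observed heterozygote fraction strictly above ``max_het``.

    Loci with no called genotypes have undefined heterozygosity and are
    dropped with a warning.
    """
    het = observed_heterozygosity(g)
    all_missing = np.isnan(het)
    if all_missing.any():
        logger.warning(
            "%d loci have no called genotypes; dropped (heterozygosity undefined)",
            int(all_missing.sum()),
        )
    keep = ~all_missing & (het <= max_het)
    logger.info("heterozygosity filter (<= %.2f): removed %d/%d loci",
                max_het, int((~keep).sum()), g.n_loci)
    return g.take_loci(keep)


def select_first_snp_per_stack(g: GenotypeMatrix) -> GenotypeMatrix:
    """Keep exactly one SNP per stack: the one with the smallest offset."""
    best: dict[int, int] = {}
    for i, loc in enumerate(g.loci):
        j = best.get(loc.stack_id)
        if j is None or loc.snp_offset < g.loci[j].snp_offset:
            best[loc.stack_id] = i
    keep = np.sort(np.fromiter(best.values(), dtype=int))
    return g.take_loci(keep)


def filter_individuals_by_missingness(
    g: GenotypeMatrix, max_missing: float = 0.2
) -> GenotypeMatrix:
    """Drop individuals whose missing-genotype fraction strictly exceeds
    ``max_missing``; loci are untouched."""
    frac = g.missing.mean(axis=0) if g.n_loci else np.zeros(g.n_samples)
    keep = frac <= max_missing
    dropped = [s for s, k in zip(g.samples, keep) if not k]
    if dropped:
        logger.info("missingness filter (> %.0f%%): dropped %d individuals: %s",
                    100 * max_missing, len(dropped), dropped[:10])
    return g.take_samples(keep)


def match_coverage(
    c: CoverageMatrix, before: GenotypeMatrix, after: GenotypeMatrix
) -> CoverageMatrix:
    """Subset a coverage matrix to follow a locus/sample filter applied to
    its genotype matrix."""
    row_of = {lid: i for i, lid in enumerate(before.locus_ids)}
    col_of = {s: j for j, s in enumerate(before.samples)}
    rows = np.array([row_of[lid] for lid in after.locus_ids], dtype=int)
    cols = np.array([col_of[s] for s in after.samples], dtype=int)
    return CoverageMatrix(c.depth[np.ix_(rows, cols)])
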