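"""Weir-Cockerham F_st engine, diversity summaries, and percentile stratification.

The estimator is the two-level ANOVA of Weir & Cockerham (1984) for diploid
biallelic data, decomposing variance into among-group (``a``),
among-individual-within-group (``b``) and within-individual (``c``)
components.  The per-locus estimate is ``a / (a + b + c)`` and may be
(slightly) negative by construction; negative values are preserved
everywhere.  Multilocus estimates combine components as a ratio of sums
(never a mean of per-locus ratios), the convention of standard population
genetics software.

Missing genotypes are excluded locus-wise.  A locus is *defined* when at
least two groups contribute two or more called individuals and the total
variance ``a + b + c`` is non-zero; undefined loci are flagged and excluded
from multilocus sums.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, SampleGroups

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    """Per-locus ANOVA variance components and F_st estimates."""

    locus_ids: list[str]
    group_labels: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    fst: np.ndarray          #: per-locus a/(a+b+c); NaN where undefined
    defined: np.ndarray      #: bool; False for undefined loci
    pooled_he: np.ndarray    #: 2 p̄(1-p̄) at the weighted pooled frequency
    n_per_group: np.ndarray  #: (loci, groups) usable sample sizes

    @property
    def multilocus_fst(self) -> float:
        """Ratio-of-sums multilocus estimate over defined loci."""
        d = self.defined
        denom = (self.a + self.b + self.c)[d].sum()
        if denom == 0:
            return float("nan")
        return float(self.a[d].sum() / denom)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    @property
    def mean_usable_n(self) -> float:
        """Mean (over defined loci) of the total usable sample size."""
        if not self.defined.any():
            return float("nan")
        return float(self.n_per_group[self.defined].sum(axis=1).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus_ids,
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "fst": self.fst,
                "defined": self.defined,
                "he": self.pooled_he,
            }
        )


def _group_stats(dosages: np.ndarray, grouping: np.ndarray):
    """Per-group called counts, allele frequencies and het fractions.

    Returns arrays of shape (loci, groups).
    """
    labels = np.unique(grouping)
    L = dosages.shape[0]
    n = np.empty((L, len(labels)))
    p = np.empty((L, len(labels)))
    h = np.empty((L, len(labels)))
    for k, lab in enumerate(labels):
        cols = grouping == lab
        d = dosages[:, cols]
        called = d != MISSING
        nk = called.sum(axis=1)
        alt = np.where(called, d, 0).sum(axis=1)
        het = ((d == 1) & called).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            n[:, k] = nk
            p[:, k] = np.where(nk > 0, alt / np.maximum(2 * nk, 1), np.nan)
            h[:, k] = np.where(nk > 0, het / np.maximum(nk, 1), np.nan)
    return labels, n, p, h


def wc_fst(g: GenotypeMatrix, grouping) -> FstResult:
    """Weir-Cockerham ANOVA F_st for an arbitrary grouping of the samples.

    Parameters
    ----------
    g
        Genotype matrix.
    grouping
        Sequence of group labels, one per sample.  At least two distinct
        labels are required overall; per-locus, groups with fewer than two
        called individuals are dropped and a locus with fewer than two
        usable groups is flagged undefined (not an error).
    """
    grouping = np.asarray(list(grouping))
    if grouping.shape[0] != g.n_samples:
        raise ValueError("grouping must provide one label per sample")
    if len(np.unique(grouping)) < 2:
        raise ValueError("need at least two groups to estimate F_st")

    labels, n, p, h = _group_stats(g.dosages, grouping)
    usable = n >= 2
    nu = np.where(usable, n, 0.0)
    pu = np.where(usable, p, 0.0)
    hu = np.where(usable, h, 0.0)
    r = usable.sum(axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        sum_n = nu.sum(axis=1)
        nbar = sum_n / r
        nc = (sum_n - (nu ** 2).sum(axis=1) / sum_n) / (r - 1)
        pbar = (nu * pu).sum(axis=1) / sum_n
        s2 = (nu * (pu - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (nu * hu).sum(axis=1) / sum_n
        pq = pbar * (1 - pbar)

        a = nbar / nc * (s2 - (pq - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (pq - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2

    ok = r >= 2
    a = np.where(ok, a, np.nan)
    b = np.where(ok, b, np.nan)
    c = np.where(ok, c, np.nan)
    denom = a + b + c
    defined = ok & np.isfinite(denom) & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(defined, a / denom, np.nan)
    # components enter multilocus sums only where defined
    a = np.where(defined, a, 0.0)
    b = np.where(defined, b, 0.0)
    c = np.where(defined, c, 0.0)
    he = np.where(ok, 2 * pq, np.nan)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.debug("wc_fst: %d/%d loci undefined (monomorphic or <2 usable groups)",
                     n_undef, g.n_loci)
    return FstResult(
        locus_ids=g.locus_ids,
        group_labels=[str(l) for l in labels],
        a=a, b=b, c=c, fst=fst, defined=defined,
        pooled_he=he, n_per_group=nu,
    )


def pairwise_fst_table(
    g: GenotypeMatrix, groups: SampleGroups, axis: str = "location"
) -> pd.DataFrame:
    """Multilocus F_st per pair of groups on one axis, per stratum of the other.

    For ``axis="location"`` one row is emitted per (species stratum,
    location pair), plus pooled "all"-stratum rows; symmetrically for
    ``axis="species"``.  Each row carries the ratio-of-sums estimate, the
    mean usable sample size and the number of defined loci.
    """
    if axis not in ("location", "species"):
        raise ValueError("axis must be 'location' or 'species'")
    other = "species" if axis == "location" else "location"
    axis_labels = groups.labels(g.samples, by=axis)
    strat_labels = groups.labels(g.samples, by=other)
    levels = sorted(set(axis_labels))
    if len(levels) < 2:
        raise ValueError(f"need >=2 levels on axis {axis!r}")

    rows = []
    for stratum in ["all", *sorted(set(strat_labels))]:
        in_stratum = np.ones(g.n_samples, bool) if stratum == "all" else strat_labels == stratum
        for g1, g2 in itertools.combinations(levels, 2):
            cols = in_stratum & np.isin(axis_labels, (g1, g2))
            present = set(axis_labels[cols])
            if len(present) < 2:
                logger.warning("stratum %s: pair (%s, %s) skipped, group absent", stratum, g1, g2)
                continue
            sub = g.take_samples(cols)
            res = wc_fst(sub, axis_labels[cols])
            rows.append(
                {
                    "stratum": stratum, "group1": g1, "group2": g2,
                    "fst": res.multilocus_fst,
                    "mean_n": res.mean_usable_n,
                    "n_loci": res.n_defined,
                }
            )
    return pd.DataFrame(rows)


def diversity_summary(
    g: GenotypeMatrix, groups: SampleGroups, by: str = "location"
) -> pd.DataFrame:
    """Observed/expected heterozygosity, per-site diversity and F_is per group.

    He uses the small-sample correction ``2n/(2n-1) * 2 p̂ q̂``.  Nucleotide
    diversity is reported over the retained (variant) sites only, where it
    coincides with unbiased He per site; with no invariant sites in a SNP
    matrix a genome-wide per-nucleotide value is not recoverable.
    F_is = 1 - Ho/He, undefined (NaN) where He = 0.
    """
    labels = groups.labels(g.samples, by=by)
    out = []
    for unit in sorted(set(labels)):
        d = g.dosages[:, labels == unit]
        called = d != MISSING
        n = called.sum(axis=1)
        ok = n >= 2
        alt = np.where(called, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n)
            ho_l = ((d == 1) & called).sum(axis=1) / n
            he_l = (2 * n) / (2 * n - 1) * 2 * p * (1 - p)
        ho = float(ho_l[ok].mean()) if ok.any() else float("nan")
        he = float(he_l[ok].mean()) if ok.any() else float("nan")
        fis = 1 - ho / he if he and he > 0 else float("nan")
        out.append(
            {"group": unit, "n_loci": int(ok.sum()), "mean_n": float(n[ok].mean()) if ok.any() else float("nan"),
             "Ho": ho, "He": he, "pi": he, "Fis": fis}
        )
    return pd.DataFrame(out)


@dataclass
class PercentileBins:
    """F_st percentile stratification: bin edges and per-bin locus ids."""

    breaks: list[float]          #: requested percentile breaks (e.g. 60,70,80,90)
    edges: list[float]           #: F_st value at each break
    labels: list[str]            #: bin labels, lowest first
    bins: dict[str, list[str]]   #: label -> locus ids

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.bins.items()}


def percentile_stratify(
    f: FstResult, breaks: tuple[float, ...] = (60, 70, 80, 90)
) -> PercentileBins:
    """Partition defined loci into half-open F_st percentile bins.

    Edges follow a rank-based rule: the edge for break ``q`` is the sorted
    F_st value at 0-based rank ``floor(q/100 * n)``, so each upper bin holds
    ~(100-q)% of loci; ties share a bin by value, so counts may deviate from
    exact percentages.  Bins are ``[lower, upper)`` with the top bin closed
    above; negative estimates fall in the lowest bins as ordinary values.
    """
    breaks = tuple(sorted(breaks))
    ids = np.asarray(f.locus_ids, dtype=object)[f.defined]
    vals = f.fst[f.defined]
    order = np.argsort(vals, kind="stable")
    svals = vals[order]
    n = len(svals)
    if n == 0:
        raise ValueError("no defined F_st values to stratify")
    edges = [float(svals[min(int(np.floor(q / 100 * n)), n - 1)]) for q in breaks]
    edges = [max(edges[: i + 1]) for i in range(len(edges))]  # enforce non-decreasing

    labels = [f"<{breaks[0]:g}"] + [
        f"{breaks[i]:g}-{breaks[i + 1]:g}" for i in range(len(breaks) - 1)
    ] + [f"{breaks[-1]:g}-100"]
    bounds = [-np.inf, *edges, np.inf]
    bins: dict[str, list[str]] = {}
    for k, lab in enumerate(labels):
        sel = (vals >= bounds[k]) & (vals < bounds[k + 1])
        bins[lab] = list(ids[sel])
    assert sum(len(v) for v in bins.values()) == n
    return PercentileBins(list(breaks), edges, labels, bins)
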