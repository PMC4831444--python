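"""Simulation-calibrated F_st outlier scans with empirical FDR control.

The decision rule mirrors the study design this package reproduces: a locus
is an outlier when its q-value is below 0.2, an expected false discovery
rate of 20% (with 0.05 as the stringent sensitivity setting).  The null
distribution is not parametric: a neutral island model is tuned so that its
stationary multilocus F_st matches the observed one under the same group
count and sample sizes, a large ensemble of null loci is drawn from it, and
per-locus empirical p-values are computed conditional on heterozygosity
(high-He loci can reach higher F_st values under drift alone, so the null
is binned into heterozygosity classes).  Benjamini-Hochberg turns the
empirical p-values into q-values.

The empirical-p granularity 1/(B_class + 1) bounds the smallest attainable
p-value; with the default ensemble size the scan yields ~0 discoveries on
structure-only data, i.e. it is conservative by construction.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .core import GenotypeMatrix, SampleGroups
from .fst import FstResult, wc_fst
from . import sim as island

logger = logging.getLogger(__name__)

FST_FLOOR = 1e-6


@dataclass
class NullEnsemble:
    """Null (F_st, He) draws from a calibrated neutral island model,
    pre-binned into heterozygosity classes."""

    fst: np.ndarray
    he: np.ndarray
    bin_edges: np.ndarray          #: ascending upper-open He cut points (len = n_bins - 1)
    sorted_fst_by_bin: list[np.ndarray]
    meta: dict

    @property
    def size(self) -> int:
        return len(self.fst)

    @property
    def n_bins(self) -> int:
        return len(self.sorted_fst_by_bin)

    def bin_of(self, he: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.bin_edges, he, side="left")


def _stationary_m(target_freq_fst: float, n_demes: int, deme_size: int,
                  c_eff: float | None = None) -> float:
    """Invert the census-after-migration stationary relation
    F = beta (F + (1-F) c), c ~ (1-1/d)/2N, for the migration rate."""
    d, two_n = n_demes, 2 * deme_size
    c = c_eff if c_eff is not None else (1 - 1 / d) / two_n
    f = target_freq_fst
    beta = f / (f + (1 - f) * c)
    alpha = 1 - np.sqrt(beta)
    return float(alpha * (d - 1) / d)


def calibrate_null(
    observed,
    n_groups: int,
    sample_size: int,
    B: int = 200_000,
    deme_size: int = 1000,
    n_het_bins: int = 20,
    seed: int = 0,
    probe_loci: int = 20_000,
) -> NullEnsemble:
    """Tune the island model to the observed multilocus F_st and draw a null
    ensemble of >= B defined locus estimates with their heterozygosities.

    Parameters
    ----------
    observed
        A multilocus F_st value or an :class:`~radscan.fst.FstResult` (its
        ratio-of-sums estimate is used); clamped below at 1e-6.
    n_groups, sample_size
        The sampling design of the comparison being calibrated: the null
        island model uses ``n_groups`` demes and draws ``sample_size``
        diploids per deme.
    """
    target = observed.multilocus_fst if isinstance(observed, FstResult) else float(observed)
    if not np.isfinite(target):
        raise ValueError("observed multilocus F_st is undefined")
    target = max(target, FST_FLOOR)
    if target >= 0.95:
        raise ValueError(
            f"target F_st {target} outside the calibratable range [1e-6, 0.95)"
        )
    d = int(n_groups)
    if d < 2:
        raise ValueError("need at least two groups")
    # ANOVA estimates ~ d/(d-1) x frequency-level Fst
    f_star = target * (d - 1) / d
    m = _stationary_m(f_star, d, deme_size)

    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCA11)))
    base = island.SimConfig(
        n_demes=d, deme_size=deme_size, m=m, n_loci=probe_loci,
        sample_size=sample_size, seed=seed, max_generations=800,
    )
    # one secant-style refinement through the stationary relation
    burn = island.quasi_stationarity_gens(base)
    probe = island.init_state(base, rng)
    for _ in range(burn):
        island.step_generation(probe, base)
    f_meas = island.frequency_fst(probe.freqs)
    if abs(f_meas - f_star) > 0.05 * f_star:
        beta0 = (1 - m * d / (d - 1)) ** 2
        c_eff = f_meas * (1 - beta0) / (beta0 * (1 - f_meas))
        m = _stationary_m(f_star, d, deme_size, c_eff=c_eff)
        base = replace(base, m=m)

    # final ensemble run (oversampled; monomorphic-in-sample draws are undefined)
    ens_cfg = replace(base, n_loci=int(B * 1.1) + 1)
    state = island.init_state(ens_cfg, rng)
    for _ in range(burn):
        island.step_generation(state, ens_cfg)

    fst_draws: list[np.ndarray] = []
    he_draws: list[np.ndarray] = []
    multilocus: list[float] = []
    total = 0
    while total < B:
        ds = island.sample_dataset(state, ens_cfg)
        res = wc_fst(ds.genotypes, ds.deme_labels)
        keep = res.defined
        fst_draws.append(res.fst[keep])
        he_draws.append(res.pooled_he[keep])
        multilocus.append(res.multilocus_fst)
        total += int(keep.sum())
        if total < B:  # decorrelate before redrawing
            for _ in range(20):
                island.step_generation(state, ens_cfg)
    fst = np.concatenate(fst_draws)
    he = np.concatenate(he_draws)

    edges, bins = _het_bins(he, n_het_bins)
    sorted_by_bin = [np.sort(fst[bins == k]) for k in range(len(edges) + 1)]
    null_multilocus = float(np.mean(multilocus))
    meta = {
        "B": int(len(fst)), "target_fst": target, "m": m,
        "n_groups": d, "sample_size": sample_size, "deme_size": deme_size,
        "seed": seed, "burn_generations": burn,
        "null_mean_fst": null_multilocus,
    }
    logger.info("null calibration: target=%.5f achieved=%.5f m=%.5f B=%d",
                target, null_multilocus, m, len(fst))
    return NullEnsemble(fst, he, edges, sorted_by_bin, meta)


def _het_bins(he: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Partition He values into ~n_bins contiguous classes of near-equal
    count.  He from small samples is heavily tied, so bins are built over
    unique values and adjacent small bins are merged (every class ends with
    >= half the nominal share)."""
    B = len(he)
    floor = B / (2 * n_bins)      # minimum class occupancy
    # first pass aims finer than n_bins so merging still leaves ~n_bins classes
    target = B / (n_bins * 1.5)
    uniq, counts = np.unique(he, return_counts=True)
    edges: list[float] = []
    acc = 0
    for v, cnt in zip(uniq[:-1], counts[:-1]):
        acc += cnt
        if acc >= target:
            edges.append(float(v))
            acc = 0
    # enforce the occupancy floor: merge any undersized class into its
    # smaller neighbor (He is heavily tied in small samples, so the greedy
    # pass above can strand slivers, e.g. the He = 0.5 tie block)
    while edges:
        occ = np.bincount(np.searchsorted(np.array(edges), he, side="left"),
                          minlength=len(edges) + 1)
        small = np.flatnonzero(occ < floor)
        if small.size == 0:
            break
        k = int(small[0])
        if k == 0:
            edges.pop(0)
        elif k == len(edges):
            edges.pop()
        else:
            edges.pop(k if occ[k + 1] <= occ[k - 1] else k - 1)
    edges_arr = np.array(edges)
    return edges_arr, np.searchsorted(edges_arr, he, side="left")


@dataclass
class OutlierScanResult:
    """Per-locus outlier calls for one comparison."""

    comparison: str
    locus_ids: list[str]
    fst: np.ndarray
    he: np.ndarray
    p: np.ndarray
    q: np.ndarray
    outlier: np.ndarray            #: bool, q < q_threshold
    q_threshold: float
    meta: dict = field(default_factory=dict)

    @property
    def n_considered(self) -> int:
        return int(np.isfinite(self.p).sum())

    @property
    def n_outliers(self) -> int:
        return int(self.outlier.sum())

    @property
    def outlier_ids(self) -> set:
        return {lid for lid, o in zip(self.locus_ids, self.outlier) if o}

    @property
    def considered_ids(self) -> set:
        return {lid for lid, fin in zip(self.locus_ids, np.isfinite(self.p)) if fin}


def empirical_pq(
    observed: FstResult,
    null: NullEnsemble,
    q_threshold: float = 0.2,
    comparison: str = "scan",
) -> OutlierScanResult:
    """Empirical per-locus p-values against the He-conditional null, with
    Benjamini-Hochberg q-values.

    p = (1 + #{null draws in the locus's He class with F_st >= observed})
        / (B_class + 1).
    """
    from statsmodels.stats.multitest import multipletests

    L = len(observed.locus_ids)
    p = np.full(L, np.nan)
    scanable = observed.defined & np.isfinite(observed.pooled_he)
    idx = np.flatnonzero(scanable)
    if idx.size:
        bins = null.bin_of(observed.pooled_he[idx])
        for k in np.unique(bins):
            null_sorted = null.sorted_fst_by_bin[k]
            sel = idx[bins == k]
            n_ge = len(null_sorted) - np.searchsorted(
                null_sorted, observed.fst[sel], side="left"
            )
            p[sel] = (1.0 + n_ge) / (len(null_sorted) + 1.0)
    q = np.full(L, np.nan)
    outlier = np.zeros(L, dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        rej, qv, *_ = multipletests(p[finite], alpha=q_threshold, method="fdr_bh")
        q[finite] = qv
        outlier[finite] = qv < q_threshold
    return OutlierScanResult(
        comparison=comparison,
        locus_ids=list(observed.locus_ids),
        fst=observed.fst, he=observed.pooled_he,
        p=p, q=q, outlier=outlier, q_threshold=q_threshold,
        meta={"B": null.size, "calibration": dict(null.meta)},
    )


class _NullCache:
    """Re-use a calibrated ensemble across comparisons with the same design
    and (rounded) target F_st."""

    def __init__(self, B: int, deme_size: int, seed: int):
        self.B, self.deme_size, self.seed = B, deme_size, seed
        self._store: dict[tuple, NullEnsemble] = {}

    def get(self, target: float, n_groups: int, sample_size: int) -> NullEnsemble:
        key = (n_groups, sample_size, round(max(target, FST_FLOOR), 3))
        if key not in self._store:
            self._store[key] = calibrate_null(
                max(key[2], FST_FLOOR), n_groups, sample_size,
                B=self.B, deme_size=self.deme_size, seed=self.seed,
            )
        return self._store[key]


def scan_comparisons(
    g: GenotypeMatrix,
    groups: SampleGroups,
    mode: str = "per_pair",
    q_threshold: float = 0.2,
    B: int = 200_000,
    deme_size: int = 1000,
    seed: int = 0,
    null_cache: _NullCache | None = None,
) -> list[OutlierScanResult]:
    """Outlier scans following the study's comparison design.

    ``per_pair``: one scan per (species, location pair) — 9 scans for the
    full 3x3 design.  ``global_per_species``: one scan per species across
    all its locations.  Pairs missing a location are skipped with a warning.
    """
    if mode not in ("per_pair", "global_per_species"):
        raise ValueError(f"unknown scan mode {mode!r}")
    cache = null_cache or _NullCache(B=B, deme_size=deme_size, seed=seed)
    species = groups.labels(g.samples, by="species")
    location = groups.labels(g.samples, by="location")
    results: list[OutlierScanResult] = []
    for sp in sorted(set(species)):
        sp_cols = species == sp
        locs = sorted(set(location[sp_cols]))
        if mode == "per_pair":
            pairs = list(itertools.combinations(sorted(set(location)), 2))
            for l1, l2 in pairs:
                cols = sp_cols & np.isin(location, (l1, l2))
                if {l1, l2} - set(location[cols]):
                    logger.warning("species %s: pair (%s, %s) skipped (location missing)",
                                   sp, l1, l2)
                    continue
                sub = g.take_samples(cols)
                res = wc_fst(sub, location[cols])
                n_samp = int(round(res.n_per_group[res.defined].mean())) if res.defined.any() else 2
                null = cache.get(res.multilocus_fst, 2, max(n_samp, 2))
                scan = empirical_pq(res, null, q_threshold, comparison=f"{sp}:{l1}-{l2}")
                scan.meta.update(species=sp, pair=(l1, l2), mode=mode)
                results.append(scan)
        else:
            if len(locs) < 2:
                logger.warning("species %s skipped: <2 locations", sp)
                continue
            cols = sp_cols
            sub = g.take_samples(cols)
            res = wc_fst(sub, location[cols])
            n_samp = int(round(res.n_per_group[res.defined].mean())) if res.defined.any() else 2
            null = cache.get(res.multilocus_fst, len(locs), max(n_samp, 2))
            scan = empirical_pq(res, null, q_threshold, comparison=f"{sp}:global")
            scan.meta.update(species=sp, pair=None, mode=mode)
            results.append(scan)
    return results


@dataclass
class RepeatedOutlierReport:
    """Cross-species intersection of outlier calls."""

    per_comparison: dict[str, set]         #: comparison label -> outlier locus ids
    per_species_outliers: dict[str, set]
    per_species_considered: dict[str, set]
    repeat_counts: dict[str, int]          #: locus -> number of species flagging it
    repeated: set                          #: flagged in >= 2 species (any pair)
    triple_repeated: set                   #: flagged in all species
    same_pair_repeated: set                #: flagged for the same location pair in >= 2 species
    shared_consideration_ratio: float

    @property
    def n_repeated(self) -> int:
        return len(self.repeated)


def repeated_outliers(scans: list[OutlierScanResult]) -> RepeatedOutlierReport:
    """Intersect outlier calls across species.

    A locus is a *repeated* outlier when flagged in >= 2 species (any
    location pair) and *triple-repeated* when flagged in every species.
    ``same_pair_repeated`` additionally requires the same location pair in
    each species (emitted separately; both matching rules are reported).
    The shared-consideration ratio is the fraction of flagged loci that were
    also considered (tested) in at least one other species's scans.
    """
    per_comp = {s.comparison: s.outlier_ids for s in scans}
    sp_out: dict[str, set] = {}
    sp_cons: dict[str, set] = {}
    pair_out: dict[tuple, dict[str, set]] = {}
    for s in scans:
        sp = s.meta.get("species", s.comparison)
        sp_out.setdefault(sp, set()).update(s.outlier_ids)
        sp_cons.setdefault(sp, set()).update(s.considered_ids)
        pair = s.meta.get("pair")
        if pair is not None:
            pair_out.setdefault(tuple(pair), {}).setdefault(sp, set()).update(s.outlier_ids)

    counts: dict[str, int] = {}
    for sp, ids in sp_out.items():
        for lid in ids:
            counts[lid] = counts.get(lid, 0) + 1
    n_species = len(sp_out)
    repeated = {l for l, c in counts.items() if c >= 2}
    triple = {l for l, c in counts.items() if c >= max(n_species, 3)}

    same_pair: set = set()
    for pair, by_sp in pair_out.items():
        c: dict[str, int] = {}
        for ids in by_sp.values():
            for lid in ids:
                c[lid] = c.get(lid, 0) + 1
        same_pair |= {l for l, k in c.items() if k >= 2}

    flagged_total = 0
    shared = 0
    for sp, ids in sp_out.items():
        others = set().union(*(v for k, v in sp_cons.items() if k != sp)) if n_species > 1 else set()
        for lid in ids:
            flagged_total += 1
            if lid in others:
                shared += 1
    ratio = shared / flagged_total if flagged_total else float("nan")

    return RepeatedOutlierReport(
        per_comparison=per_comp,
        per_species_outliers=sp_out,
        per_species_considered=sp_cons,
        repeat_counts=counts,
        repeated=repeated,
        triple_repeated=triple,
        same_pair_repeated=same_pair,
        shared_consideration_ratio=ratio,
    )


def randomized_grouping_scan(
    g: GenotypeMatrix,
    n_species: int = 3,
    n_locations: int = 3,
    seed: int = 0,
    q_threshold: float = 0.2,
    B: int = 200_000,
    null_cache: _NullCache | None = None,
) -> tuple[FstResult, RepeatedOutlierReport]:
    """Permute individuals uniformly into a random species x location design
    of equal cell sizes and rerun the full F_st + scan + repeat pipeline.

    Permuting labels destroys any real structure, so the global F_st is ~0
    and no repeated outliers are expected.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_cells = n_species * n_locations
    per_cell = g.n_samples // n_cells
    if per_cell < 2:
        raise ValueError("too few individuals for the requested design")
    used = per_cell * n_cells
    if used < g.n_samples:
        logger.warning("randomization uses %d of %d individuals (equal cells)",
                       used, g.n_samples)
    perm = rng.permutation(g.n_samples)[:used]
    gsub = g.take_samples(perm)
    assignment = {}
    for k, name in enumerate(gsub.samples):
        cell = k // per_cell
        assignment[name] = (f"rsp{cell // n_locations}", f"rloc{cell % n_locations}")
    rgroups = SampleGroups(assignment)

    global_fst = wc_fst(gsub, rgroups.labels(gsub.samples, by="location"))
    scans = scan_comparisons(
        gsub, rgroups, mode="per_pair", q_threshold=q_threshold, B=B,
        seed=seed, null_cache=null_cache,
    )
    return global_fst, repeated_outliers(scans)
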