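"""Linkage-disequilibrium network analysis.

Loci are vertices; edges connect pairs whose LD (squared composite genotype
correlation r^2 — phase is unknown in RAD genotypes, so the Burrows-type
unphased surrogate is used) exceeds a threshold.  As the threshold descends
on a fixed grid, connected components merge; the merger order forms a tree
whose branches are clusters.  At each merge the statistic

    lambda = n_focal * (median within-cluster r^2 before merge
                        - median within-cluster r^2 after merge)

measures how much a focal cluster's internal cohesion is diluted by the
merge.  Merges whose lambda exceeds median(lambda) + phi * MAD(lambda) and
whose focal cluster carries at least |E|min edges at the merge threshold
are *outlier clusters*; outlier clusters with no outlier nested inside are
*single-outlier clusters* (SOCs) — the unit of interest, typically driven
either by admixture LD (group-differentiating loci) or by physical linkage
(e.g. an inversion).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeMatrix, SampleGroups
from .fst import wc_fst

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric pairwise r^2 among loci (NaN where undefined)."""

    r2: np.ndarray
    locus_ids: list[str]

    def __post_init__(self) -> None:
        k = len(self.locus_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 matrix shape does not match locus count")


def ld_r2_matrix(
    g: GenotypeMatrix, min_shared_frac: float = 0.8, soft_cap: int = 12_000
) -> LDMatrix:
    """Squared Pearson correlation of dosage vectors over pairwise-complete
    individuals.

    Input should already be LD-network-ready (no rare alleles, observed
    heterozygosity <= 0.5, one SNP per stack, bounded missingness).  Pairs
    sharing fewer than ``min_shared_frac`` of individuals (or < 3) are set
    to NaN.  Locus counts above ``soft_cap`` are refused: the dense matrix
    grows quadratically and becomes impractical well before 100k loci.
    """
    if g.n_loci > soft_cap:
        raise ValueError(
            f"{g.n_loci} loci exceed the LD-matrix soft cap ({soft_cap}); "
            "pre-filter or raise soft_cap explicitly"
        )
    X = g.dosages.astype(float)
    ok = (g.dosages != MISSING).astype(float)
    X = X * ok  # missing -> 0, masked out of all sums below

    n = ok @ ok.T
    sx = X @ ok.T
    sxx = (X * X) @ ok.T
    sxy = X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var = n * sxx - sx ** 2
        denom = var * var.T
        r2 = np.where(denom > 0, cov ** 2 / denom, np.nan)
    min_n = max(3, int(np.ceil(min_shared_frac * g.n_samples)))
    r2[n < min_n] = np.nan
    np.fill_diagonal(r2, 1.0)
    r2 = np.clip(r2, 0.0, 1.0)
    return LDMatrix(r2, g.locus_ids)


@dataclass
class MergeEvent:
    """One merger of two clusters at a grid threshold."""

    threshold: float
    cluster_id: int                      #: id of the merged (new) cluster
    constituent_ids: tuple[int, int]     #: ids of the two merging clusters
    members: np.ndarray                  #: locus indices of the merged cluster
    constituent_members: tuple[np.ndarray, np.ndarray]
    edge_counts: tuple[int, int]         #: internal edges of each constituent at this threshold
    lambdas: tuple[float, float]         #: lambda per focal constituent (NaN for singletons)
    outlier_flags: list[bool] = field(default_factory=lambda: [False, False])


@dataclass
class LDClusterTree:
    """Threshold-descending single-linkage merger tree with lambda statistics."""

    locus_ids: list[str]
    events: list[MergeEvent]
    grid_step: float
    #: cluster id -> parent cluster id (set when a cluster merges away)
    parent: dict[int, int] = field(default_factory=dict)
    #: outlier cluster ids after lambda_outliers
    outlier_clusters: set = field(default_factory=set)
    soc_clusters: set = field(default_factory=set)
    #: cluster id -> (members, merge threshold, edge count, lambda)
    cluster_info: dict[int, dict] = field(default_factory=dict)

    def members_of(self, cluster_id: int) -> list[str]:
        return [self.locus_ids[i] for i in self.cluster_info[cluster_id]["members"]]

    def socs(self) -> list[dict]:
        out = []
        for cid in sorted(self.soc_clusters):
            info = self.cluster_info[cid]
            out.append({"cluster_id": cid, "loci": self.members_of(cid), **info})
        return out


def _median_r2(r2: np.ndarray, members: np.ndarray, rng: np.random.Generator | None = None,
               max_pairs: int = 2_000_000) -> float:
    k = len(members)
    if k < 2:
        return float("nan")
    if k * (k - 1) // 2 > max_pairs and rng is not None:
        a = rng.choice(members, size=2048)
        b = rng.choice(members, size=2048)
        sel = a != b
        vals = r2[a[sel], b[sel]]
    else:
        sub = r2[np.ix_(members, members)]
        vals = sub[np.triu_indices(k, 1)]
    vals = vals[np.isfinite(vals)]
    return float(np.median(vals)) if len(vals) else float("nan")


def build_ld_tree(ld: LDMatrix, grid_step: float = 0.01) -> LDClusterTree:
    """Single-linkage merger tree over a descending r^2 threshold grid.

    Edges (pairs with r^2 >= threshold) are added as the threshold steps
    down from 1.0 by ``grid_step``; clusters are connected components, and
    every union of two components is recorded as a merge event with member
    sets, per-constituent internal edge counts at the merge threshold, and
    the lambda statistic (NaN when the focal constituent is a singleton,
    which has no internal median).
    """
    k = len(ld.locus_ids)
    r2 = ld.r2
    iu, ju = np.triu_indices(k, 1)
    vals = r2[iu, ju]
    finite = np.isfinite(vals) & (vals > 0)
    iu, ju, vals = iu[finite], ju[finite], vals[finite]
    order = np.argsort(-vals)
    iu, ju, vals = iu[order], ju[order], vals[order]
    # snap each edge to the first grid threshold at or below its r^2
    grid_idx = np.floor(np.round(vals / grid_step, 9)).astype(int)
    thresholds = grid_idx * grid_step

    parent_arr = np.arange(k)
    members: dict[int, list[int]] = {i: [i] for i in range(k)}
    internal_edges: dict[int, int] = {i: 0 for i in range(k)}
    medians: dict[int, float] = {i: float("nan") for i in range(k)}
    next_id = k
    events: list[MergeEvent] = []
    tree_parent: dict[int, int] = {}
    rng = np.random.default_rng(0)

    def find(x: int) -> int:
        while parent_arr[x] != x:
            parent_arr[x] = parent_arr[parent_arr[x]]
            x = parent_arr[x]
        return x

    cluster_of: dict[int, int] = {i: i for i in range(k)}  # DSU root -> cluster id

    for e in range(len(vals)):
        ra, rb = find(iu[e]), find(ju[e])
        thr = float(np.round(thresholds[e], 9))
        if ra == rb:
            internal_edges[cluster_of[ra]] += 1
            continue
        ca, cb = cluster_of[ra], cluster_of[rb]
        ma, mb = members[ca], members[cb]
        merged = ma + mb
        cid = next_id
        next_id += 1
        med_after = _median_r2(r2, np.asarray(merged), rng)
        lam_a = len(ma) * (medians[ca] - med_after) if len(ma) >= 2 else float("nan")
        lam_b = len(mb) * (medians[cb] - med_after) if len(mb) >= 2 else float("nan")
        ev = MergeEvent(
            threshold=thr,
            cluster_id=cid,
            constituent_ids=(ca, cb),
            members=np.asarray(merged),
            constituent_members=(np.asarray(ma), np.asarray(mb)),
            edge_counts=(internal_edges[ca], internal_edges[cb]),
            lambdas=(lam_a, lam_b),
        )
        events.append(ev)
        tree_parent[ca] = cid
        tree_parent[cb] = cid
        parent_arr[rb] = ra
        cluster_of[ra] = cid
        members[cid] = merged
        internal_edges[cid] = internal_edges[ca] + internal_edges[cb] + 1
        medians[cid] = med_after
        del members[ca], members[cb]

    tree = LDClusterTree(list(ld.locus_ids), events, grid_step, parent=tree_parent)
    for ev in events:
        for side in (0, 1):
            cid = ev.constituent_ids[side]
            tree.cluster_info[cid] = {
                "members": ev.constituent_members[side],
                "size": len(ev.constituent_members[side]),
                "merge_threshold": ev.threshold,
                "edges": ev.edge_counts[side],
                "lambda": ev.lambdas[side],
            }
    return tree


def _descendants(tree: LDClusterTree, cid: int) -> set:
    children: dict[int, list[int]] = {}
    for child, par in tree.parent.items():
        children.setdefault(par, []).append(child)
    out: set = set()
    stack = list(children.get(cid, []))
    while stack:
        c = stack.pop()
        out.add(c)
        stack.extend(children.get(c, []))
    return out


def lambda_outliers(tree: LDClusterTree, phi: float = 4.0, e_min: int = 16) -> LDClusterTree:
    """Flag outlier clusters (lambda > median + phi*MAD, >= e_min internal
    edges at the merge threshold) and SOCs (outliers with no nested
    outlier).  Flags are written onto the tree and returned."""
    lams = np.array([l for ev in tree.events for l in ev.lambdas if np.isfinite(l)])
    tree.outlier_clusters = set()
    tree.soc_clusters = set()
    if len(lams) == 0:
        return tree
    med = float(np.median(lams))
    mad = float(np.median(np.abs(lams - med)))
    cut = med + phi * mad
    for ev in tree.events:
        for side in (0, 1):
            lam = ev.lambdas[side]
            if np.isfinite(lam) and lam > cut and ev.edge_counts[side] >= e_min:
                ev.outlier_flags[side] = True
                tree.outlier_clusters.add(ev.constituent_ids[side])
    for cid in tree.outlier_clusters:
        if not (_descendants(tree, cid) & tree.outlier_clusters):
            tree.soc_clusters.add(cid)
    logger.info("lambda outliers: %d outlier clusters, %d SOCs (phi=%g, |E|min=%d, cut=%.3f)",
                len(tree.outlier_clusters), len(tree.soc_clusters), phi, e_min, cut)
    return tree


def soc_divergence(
    g: GenotypeMatrix,
    groups: SampleGroups,
    soc: list[str],
    by: str = "species_location",
    ld: LDMatrix | None = None,
) -> dict:
    """Divergence summary for one SOC's locus set: multilocus W&C F_st
    across sample groups, median within-SOC r^2, and a centroid-separation
    score (between-group over mean within-group variance of the top
    dosage principal components).

    A SOC of group-differentiating loci shows elevated F_st and moderate
    r^2 (admixture LD); a physically linked but group-neutral SOC shows
    F_st ~ 0 with high median r^2.
    """
    if not soc:
        raise ValueError("empty SOC locus set")
    pos = {lid: i for i, lid in enumerate(g.locus_ids)}
    try:
        rows = np.array([pos[l] for l in soc])
    except KeyError as e:
        raise KeyError(f"SOC locus not in genotype matrix: {e}") from e
    sub = g.take_loci(rows)
    labels = groups.labels(g.samples, by=by)
    res = wc_fst(sub, labels)

    if ld is None:
        ld = ld_r2_matrix(sub, min_shared_frac=0.0)
        med_r2 = _median_r2(ld.r2, np.arange(sub.n_loci))
    else:
        lpos = {lid: i for i, lid in enumerate(ld.locus_ids)}
        med_r2 = _median_r2(ld.r2, np.array([lpos[l] for l in soc]))

    X = sub.dosages.T.astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), np.where(np.isnan(mu), 0.0, mu)[None, :], X)
    X -= X.mean(axis=0)
    from sklearn.decomposition import PCA

    ncomp = int(min(5, X.shape[0] - 1, X.shape[1]))
    pcs = PCA(n_components=ncomp, random_state=0).fit_transform(X)
    centroids = np.stack([pcs[labels == u].mean(axis=0) for u in sorted(set(labels))])
    within = np.mean([pcs[labels == u].var(axis=0).sum() for u in sorted(set(labels))])
    between = centroids.var(axis=0).sum()
    sep = float(between / within) if within > 0 else float("inf")

    return {
        "n_loci": len(soc),
        "fst": res.multilocus_fst,
        "median_r2": med_r2,
        "centroid_separation": sep,
    }
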