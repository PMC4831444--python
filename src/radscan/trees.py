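"""Distance-based trees and PCA clustering over genotype matrices.

These are deliberately lightweight, model-free views of the same structure
the divergence scans quantify: an allele-sharing distance among individuals,
neighbor-joining trees with locus-bootstrap support, and a PCA + k-means
clustering with silhouette-based selection of the number of clusters.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def allele_sharing_distance(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise individual distance 1 - (mean proportion of shared alleles).

    For two diploid dosages x, y at a locus the shared-allele proportion is
    ``1 - |x - y| / 2``; it is averaged over loci called in both individuals.
    Identical individuals are at distance 0, opposite homozygotes at 1.
    """
    D = g.dosages.astype(float)
    D[g.dosages == MISSING] = np.nan
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(D - D[:, [i]])          # (L, n)
        with np.errstate(invalid="ignore"):
            d = np.nanmean(diff / 2.0, axis=0)
        if np.isnan(d).any():
            bad = [g.samples[j] for j in np.flatnonzero(np.isnan(d)) if j != i]
            raise ValueError(f"no shared called loci between {g.samples[i]} and {bad[:3]}")
        out[i] = d
        out[i, i] = 0.0
    return (out + out.T) / 2.0


@dataclass
class DistanceTree:
    """A rooted-for-serialization NJ tree with bootstrap supports.

    ``newick`` stores branch lengths and internal-node support values
    (0-100, written as internal node labels).
    """

    newick: str
    leaf_names: list[str]
    supports: dict[frozenset, float]  #: bipartition (leaf set not containing leaf 0) -> support %

    def __str__(self) -> str:  # pragma: no cover
        return self.newick


def _skbio_nj(dm_array: np.ndarray, names: list[str]):
    from skbio import DistanceMatrix
    from skbio.tree import nj

    return nj(DistanceMatrix(dm_array, names))


def _clamp_negative_branches(tree) -> None:
    """Clamp negative branch lengths to 0, absorbing the deficit into a
    sibling edge (standard NJ post-processing)."""
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            sibs = [s for s in node.siblings() if s.length is not None]
            if sibs:
                sibs[0].length += node.length
                if sibs[0].length < 0:
                    sibs[0].length = 0.0
            node.length = 0.0


def _bipartitions(tree, leaves: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalised as the side that does
    not contain the reference (first) leaf."""
    ref = leaves[0]
    full = set(leaves)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        if 1 < len(side) < len(leaves) - 1:
            parts.add(frozenset(side))
    return parts


def nj_tree(
    d: np.ndarray,
    leaf_names: list[str],
    bootstrap: int = 0,
    g: GenotypeMatrix | None = None,
    seed: int | None = None,
) -> DistanceTree:
    """Neighbor-joining tree from a distance matrix, with optional
    locus-resampling bootstrap.

    Bootstrap replicates resample loci of ``g`` with replacement, rebuild the
    allele-sharing distance and the NJ tree, and score each internal edge of
    the point-estimate tree by the percentage of replicates containing its
    bipartition.
    """
    d = np.asarray(d, float)
    if d.shape[0] < 3:
        raise ValueError("neighbor-joining needs at least 3 leaves")
    if bootstrap and g is None:
        raise ValueError("bootstrap requires the genotype matrix")

    tree = _skbio_nj(d, leaf_names)
    _clamp_negative_branches(tree)

    supports: dict[frozenset, float] = {}
    if bootstrap:
        rng = np.random.default_rng(seed)
        target = _bipartitions(tree, leaf_names)
        hits = {p: 0 for p in target}
        for _ in range(bootstrap):
            idx = rng.integers(0, g.n_loci, size=g.n_loci)
            try:
                dist = allele_sharing_distance_resampled(g, idx)
            except ValueError:
                continue
            rtree = _skbio_nj(dist, leaf_names)
            rparts = _bipartitions(rtree, leaf_names)
            for p in target & rparts:
                hits[p] += 1
        supports = {p: 100.0 * h / bootstrap for p, h in hits.items()}
        _annotate_supports(tree, leaf_names, supports)

    return DistanceTree(str(tree).strip(), list(leaf_names), supports)


def allele_sharing_distance_resampled(g: GenotypeMatrix, idx: np.ndarray) -> np.ndarray:
    """Allele-sharing distance over a with-replacement locus resample.

    Repeated indices are honoured with multiplicity (this is what makes it a
    true bootstrap), implemented via per-locus weights.
    """
    weights = np.bincount(idx, minlength=g.n_loci).astype(float)
    D = g.dosages.astype(float)
    D[g.dosages == MISSING] = np.nan
    n = g.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(D - D[:, [i]]) / 2.0
        ok = ~np.isnan(diff)
        w = weights[:, None] * ok
        denom = w.sum(axis=0)
        if (denom == 0).any():
            raise ValueError("a pair shares no resampled loci")
        out[i] = np.nansum(np.where(ok, diff, 0.0) * weights[:, None], axis=0) / denom
        out[i, i] = 0.0
    return (out + out.T) / 2.0


def _annotate_supports(tree, leaves: list[str], supports: dict[frozenset, float]) -> None:
    ref = leaves[0]
    full = set(leaves)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = full - side
        key = frozenset(side)
        if key in supports:
            node.name = f"{supports[key]:.0f}"


@dataclass
class ClusterResult:
    k: int
    assignment: np.ndarray          #: cluster index per individual
    scores: dict[int, float]        #: candidate k -> mean silhouette (k>=2)
    sample_names: list[str]


def pca_cluster(
    g: GenotypeMatrix,
    k_max: int = 6,
    seed: int = 0,
    n_components: int = 10,
    silhouette_min: float = 0.25,
) -> ClusterResult:
    """Mean-imputed genotype PCA followed by k-means with silhouette-based
    selection of k.

    k = 1 is selected when no k >= 2 reaches ``silhouette_min`` (a panmictic
    dataset produces no meaningful partition).  Deterministic given ``seed``.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    if g.n_samples < 2:
        raise ValueError("clustering needs at least 2 individuals")
    X = g.dosages.T.astype(float)
    miss = X == MISSING
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean[None, :], X)
    X -= X.mean(axis=0)

    ncomp = int(min(n_components, g.n_samples - 1, g.n_loci))
    pcs = PCA(n_components=ncomp, random_state=seed).fit_transform(X)

    scores: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in range(2, min(k_max, g.n_samples - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pcs)
        assignments[k] = km.labels_
        scores[k] = float(silhouette_score(pcs, km.labels_)) if len(set(km.labels_)) > 1 else -1.0

    if scores and max(scores.values()) >= silhouette_min:
        best = max(scores, key=scores.get)
        return ClusterResult(best, assignments[best], scores, list(g.samples))
    return ClusterResult(1, np.zeros(g.n_samples, dtype=int), scores, list(g.samples))
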