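"""Population structure: IBS distances, neighbor-joining and PCA.

The distance between two samples is the allele-sharing (1 - IBS) dosage
distance: the mean over co-called sites of |dosage_a - dosage_b| / 2,
which lies in [0, 1].  Trees are built with the Saitou-Nei
neighbor-joining algorithm under the Studier-Keppler Q criterion and
returned as (unrooted, trifurcating-root) scikit-bio ``TreeNode`` objects.
PCA follows the smartpca convention: centre dosage columns and scale by
1/sqrt(p(1-p)) with p estimated as half the column mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .genotypes import MISSING, GenotypeTable


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        self.matrix = m


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray          # (n_samples, n_components)
    variance_explained: np.ndarray   # percentages, sum to 100
    n_variants_used: int


def ibs_distance(table: GenotypeTable) -> DistanceMatrix:
    """Pairwise 1-IBS dosage distance over sites called in both samples."""
    if table.n_samples < 2 or table.n_variants < 1:
        raise ValueError("need >= 2 samples and >= 1 variant")
    g = table.genotypes.astype(float)
    called = table.genotypes != MISSING
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(
                    f"samples {table.samples[i]} and {table.samples[j]} "
                    "share no co-called sites"
                )
            d[i, j] = d[j, i] = np.abs(g[i, both] - g[j, both]).mean() / 2.0
    return DistanceMatrix(labels=list(table.samples), matrix=d)


# ----------------------------------------------------------------------
# Neighbor joining
# ----------------------------------------------------------------------

def neighbor_joining(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei agglomeration with the Studier-Keppler Q criterion.

    Deterministic: ties in Q are broken by the lexicographically smallest
    pair of cluster representative labels (the smallest leaf label in each
    cluster).  Negative branch lengths are clamped to zero with the
    deficit shifted to the sibling edge.  The result is unrooted, emitted
    with a trifurcating root.
    """
    n0 = len(dist.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    d = dist.matrix.copy()
    nodes = [TreeNode(name=lbl) for lbl in dist.labels]
    reps = list(dist.labels)  # representative (min) leaf label per cluster

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - r[i] - r[j]
                pair = tuple(sorted((reps[i], reps[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        # PHYLIP-style handling of negative estimates
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final three-point join: root is the trifurcating internal node
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    a.length, b.length, c.length = float(la), float(lb), float(lc)
    root = TreeNode()
    root.extend([a, b, c])
    return root


def write_newick(tree: TreeNode, path) -> None:
    """Write standard Newick with branch lengths (labels quoted as needed)."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_phylip_distances(dist: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format, for interoperability."""
    with open(path, "w") as fh:
        fh.write(f"{len(dist.labels)}\n")
        for lbl, row in zip(dist.labels, dist.matrix):
            cells = " ".join(f"{x:.6f}" for x in row)
            fh.write(f"{lbl:<10s} {cells}\n")


def is_monophyletic(tree: TreeNode, labels: set[str]) -> bool:
    """True when *labels* form a clade in some rooting of *tree*.

    For an unrooted tree this holds when either the labels or their
    complement are the tip set of one subtree hanging off an edge.
    """
    all_tips = {t.name for t in tree.tips()}
    target = set(labels)
    complement = all_tips - target
    for node in tree.non_tips(include_self=False):
        tips = {t.name for t in node.tips()}
        if tips == target or tips == complement:
            return True
    # a clade can also hang directly off the trifurcating root
    for child in tree.children:
        tips = {child.name} if child.is_tip() else \
            {t.name for t in child.tips()}
        if tips == target or tips == complement:
            return True
    return False


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def pca(table: GenotypeTable, n_components: int | None = None) -> PcaResult:
    """Genotype PCA with smartpca-style column scaling.

    Missing dosages are imputed with the column mean before scaling.
    Monomorphic columns are dropped.  Variance-explained percentages are
    computed over all components of the sample covariance and sum to 100.
    The sign of each component is fixed so that its largest-magnitude
    sample loading is positive.
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    g = table.genotypes.astype(float)
    g[table.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1) & (np.nanstd(g, axis=0) > 0)
    if poly.sum() < 2:
        raise ValueError("fewer than 2 polymorphic variants")
    x = (g[:, poly] - col_mean[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    m = poly.sum()
    cov = x @ x.T / m
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        col = eigvec[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            eigvec[:, k] = -col
    total = eigval.sum()
    var_pct = 100.0 * eigval / total if total > 0 else eigval
    coords = eigvec * np.sqrt(eigval)
    k = n_components or len(eigval)
    return PcaResult(
        samples=list(table.samples),
        coordinates=coords[:, :k],
        variance_explained=var_pct,
        n_variants_used=int(m),
    )
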