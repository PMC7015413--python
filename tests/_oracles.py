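"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, whole-CDS translation, exhaustive enumeration) and shares no code
with the package's fast paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from Bio.Seq import Seq
from skbio import TreeNode


def brute_hp(n_maj, n_min) -> float:
    """Pooled heterozygosity by explicit summation."""
    s_maj = 0.0
    s_min = 0.0
    for a, b in zip(n_maj, n_min):
        s_maj += float(a)
        s_min += float(b)
    if s_maj + s_min == 0:
        return float("nan")
    return 2.0 * s_maj * s_min / (s_maj + s_min) ** 2


def brute_hudson_fst(p1, n1, p2, n2) -> float:
    """Hudson ratio-of-sums by explicit per-site loop."""
    num = 0.0
    den = 0.0
    for a, na, b, nb in zip(p1, n1, p2, n2):
        if na < 2 or nb < 2:
            continue
        d = a * (1 - b) + b * (1 - a)
        if d <= 0:
            continue
        num += (a - b) ** 2 - a * (1 - a) / (na - 1) - b * (1 - b) / (nb - 1)
        den += d
    if den == 0:
        return float("nan")
    return num / den


def brute_effect(model, scaffold_seq: str, pos: int, alt: str) -> str:
    """Effect by translating the full mutant CDS and diffing the protein."""
    mutant = scaffold_seq[:pos - 1] + alt + scaffold_seq[pos:]
    ref_cds = model.cds_sequence(scaffold_seq)
    alt_cds = model.cds_sequence(mutant)
    ref_aa = str(Seq(ref_cds).translate())
    alt_aa = str(Seq(alt_cds).translate())
    assert len(ref_aa) == len(alt_aa)
    diffs = [(a, b) for a, b in zip(ref_aa, alt_aa) if a != b]
    if not diffs:
        return "synonymous"
    assert len(diffs) == 1
    a, b = diffs[0]
    if a != "*" and b == "*":
        return "stopgain"
    if a == "*" and b != "*":
        return "stoploss"
    return "nonsynonymous"


def brute_specific_sites(genotypes: np.ndarray, focal_rows, other_rows,
                         min_individuals: int = 2,
                         strict_missing: bool = False) -> set[int]:
    """Private-SNP rule evaluated site by site in pure python."""
    hits = set()
    n_sites = genotypes.shape[1]
    for j in range(n_sites):
        carriers = sum(1 for i in focal_rows if genotypes[i, j] > 0)
        if carriers < min_individuals:
            continue
        ok = True
        for i in other_rows:
            g = genotypes[i, j]
            if g > 0:
                ok = False
                break
            if strict_missing and g < 0:
                ok = False
                break
        if ok:
            hits.add(j)
    return hits


def brute_hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct combinatorial summation."""
    total = comb(N, n)
    s = 0
    for x in range(k, min(K, n) + 1):
        s += comb(K, x) * comb(N - K, n - x)
    return s / total


def brute_hypergeom_enumerate(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every C(N, n) draw (N <= 12)."""
    members = set(range(K))  # first K items carry the term
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for d in draw if d in members) >= k:
            hits += 1
    return hits / total


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random unrooted binary tree with uniform(0.1, 1) branch lengths.

    Built by sequential edge splitting starting from a 3-leaf star, so the
    root is trifurcating and every internal node has degree 3.
    """
    def leaf(i):
        t = TreeNode(name=f"L{i}")
        t.length = float(rng.uniform(0.1, 1.0))
        return t

    root = TreeNode()
    root.extend([leaf(0), leaf(1), leaf(2)])
    edges = list(root.children)
    for i in range(3, n_leaves):
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        mid = TreeNode()
        mid.length = float(rng.uniform(0.1, 1.0))
        parent.remove(target)
        target.parent = None
        new_leaf = leaf(i)
        mid.extend([target, new_leaf])
        parent.append(mid)
        edges.extend([mid, new_leaf])
    return root


def tip_distance_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    dm = tree.tip_tip_distances()
    return dm.filter(labels).data.copy()
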