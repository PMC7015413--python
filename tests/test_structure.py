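"""IBS distances, neighbor joining, Newick round-trips and PCA."""

import numpy as np
import pytest

import _oracles
from conftest import make_table
from popsweep.simulate import SimulationConfig, simulate_cohort
from popsweep.structure import (DistanceMatrix, ibs_distance,
                                is_monophyletic, neighbor_joining, pca,
                                read_newick, write_newick)

WORKED_LABELS = ["A", "B", "C", "D"]
WORKED_MATRIX = np.array([
    [0, 3, 5, 6],
    [3, 0, 6, 7],
    [5, 6, 0, 7],
    [6, 7, 7, 0],
], dtype=float)


def test_ibs_distance_examples():
    g = np.array([[0, 1, 2], [0, 1, 2], [2, 2, 2], [2, 1, 0]], dtype=np.int8)
    t = make_table(g)
    d = ibs_distance(t)
    assert d.matrix[0, 1] == 0.0                       # identical samples
    i, j = 0, 3
    assert d.matrix[i, j] == pytest.approx(2 / 3)      # (1+0+1)/3
    g2 = np.array([[0, 0], [2, 2]], dtype=np.int8)
    assert ibs_distance(make_table(g2)).matrix[0, 1] == 1.0


def test_ibs_invariant_to_site_permutation_and_relabeling():
    rng = np.random.default_rng(3)
    g = rng.integers(0, 3, size=(6, 200)).astype(np.int8)
    t = make_table(g)
    perm = rng.permutation(200)
    t2 = make_table(g[:, perm])
    assert np.allclose(ibs_distance(t).matrix, ibs_distance(t2).matrix)


def test_nj_worked_four_taxon_example():
    """Additive distances 3,5,6,6,7,7 give topology AB|CD with terminal
    branch lengths 1,2,3,4 and internal edge 1."""
    tree = neighbor_joining(DistanceMatrix(WORKED_LABELS, WORKED_MATRIX))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
    internals = [n.length for n in tree.non_tips()]
    assert internals == pytest.approx([1.0])
    assert is_monophyletic(tree, {"A", "B"})
    got = _oracles.tip_distance_matrix(tree, WORKED_LABELS)
    assert np.allclose(got, WORKED_MATRIX, atol=1e-9)


def test_nj_three_taxa_three_point_formulas():
    m = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
    tree = neighbor_joining(DistanceMatrix(["X", "Y", "Z"], m))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["X"] == pytest.approx((2 + 3 - 5) / 2)
    assert lengths["Y"] == pytest.approx((2 + 5 - 3) / 2)
    assert lengths["Z"] == pytest.approx((3 + 5 - 2) / 2)
    assert len(tree.children) == 3


def test_nj_equidistant_ties_resolved_deterministically():
    m = np.ones((4, 4)) - np.eye(4)
    tree = neighbor_joining(DistanceMatrix(list("ABCD"), m))
    assert sorted(t.name for t in tree.tips()) == list("ABCD")
    internal = [n.length for n in tree.non_tips()]
    assert internal == pytest.approx([0.0], abs=1e-12)
    again = neighbor_joining(DistanceMatrix(list("ABCD"), m))
    assert tree.compare_rfd(again) == 0


def test_nj_invalid_matrices_rejected():
    bad = np.array([[0, 1], [2, 0]], dtype=float)
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], bad)
    with pytest.raises(ValueError, match=">= 3 taxa"):
        neighbor_joining(DistanceMatrix(["a", "b"],
                                        np.array([[0, 1], [1, 0.]])))


def test_nj_recovers_random_additive_trees():
    """Topology (RF=0) and path lengths (<= 1e-9) recovered from additive
    matrices of 100 random binary trees with 5-12 leaves."""
    rng = np.random.default_rng(41)
    for rep in range(100):
        n = int(rng.integers(5, 13))
        true = _oracles.random_binary_tree(rng, n)
        labels = sorted(t.name for t in true.tips())
        dm = _oracles.tip_distance_matrix(true, labels)
        est = neighbor_joining(DistanceMatrix(labels, dm))
        assert est.compare_rfd(true) == 0
        got = _oracles.tip_distance_matrix(est, labels)
        assert np.max(np.abs(got - dm)) <= 1e-9


def test_nj_agrees_with_skbio_reference():
    """Independent cross-check against scikit-bio's NJ on random noisy
    (non-additive) matrices: same topology."""
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(53)
    for rep in range(10):
        n = 7
        base = _oracles.random_binary_tree(rng, n)
        labels = sorted(t.name for t in base.tips())
        m = _oracles.tip_distance_matrix(base, labels)
        noise = rng.uniform(0, 0.01, size=m.shape)
        m = m + (noise + noise.T)
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        ours = neighbor_joining(DistanceMatrix(labels, m))
        theirs = skbio_nj(SkbioDM(m, ids=labels))
        assert ours.compare_rfd(theirs) == 0


def test_newick_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    tree = _oracles.random_binary_tree(rng, 9)
    labels = sorted(t.name for t in tree.tips())
    p = tmp_path / "t.nwk"
    write_newick(tree, p)
    text = p.read_text()
    assert text.strip().endswith(";") and text.count(";") == 1
    back = read_newick(p)
    assert sorted(t.name for t in back.tips()) == labels
    assert len(back.children) == 3  # trifurcating root: unrooted tree
    a = _oracles.tip_distance_matrix(tree, labels)
    b = _oracles.tip_distance_matrix(back, labels)
    assert np.max(np.abs(a - b)) <= 1e-9


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

def test_pca_duplicated_sample_identical_coordinates():
    rng = np.random.default_rng(13)
    g = rng.integers(0, 3, size=(6, 300)).astype(np.int8)
    g[5] = g[0]
    res = pca(make_table(g))
    # compare components carrying real variance; the null-space columns
    # are numerical noise at machine precision
    real = res.variance_explained > 1e-6
    assert np.allclose(res.coordinates[0, real], res.coordinates[5, real],
                       atol=1e-9)


def test_pca_variance_explained_sums_to_100(small_cohort):
    table, _ = small_cohort
    res = pca(table)
    assert res.variance_explained.sum() == pytest.approx(100.0, abs=1e-6)
    assert res.n_variants_used > 0


def test_pca_rejects_degenerate_input():
    g = np.zeros((4, 5), dtype=np.int8)
    with pytest.raises(ValueError, match="polymorphic"):
        pca(make_table(g))


def test_pca_separates_diverged_populations():
    """Two strongly diverged populations separate on PC1 with no overlap
    in >= 9/10 seeds."""
    wins = 0
    for seed in range(10):
        cfg = SimulationConfig(
            n_scaffolds=1, scaffold_length_bp=250_000,
            n_variants_per_scaffold=1_000, populations=("P1", "P2"),
            drift_divergence={"P1": 0.3, "P2": 0.3}, shared_branch_f=0.01,
            private_allele_rate=0.0, indel_rate=0.0, seed=seed)
        table, _ = simulate_cohort(cfg)
        res = pca(table)
        pc1 = res.coordinates[:, 0]
        a, b = pc1[:3], pc1[3:]
        wins += (a.max() < b.min()) or (b.max() < a.min())
    assert wins >= 9


def test_muscovy_pair_clade_and_pca_adjacency(small_cohort):
    """On the default five-population design the Muscovy-like pair's six
    samples form a clade and their PCA centroids are mutually nearest."""
    table, _ = small_cohort
    from popsweep.variants import maf_filter
    t, _ = maf_filter(table, 0.1)
    tree = neighbor_joining(ibs_distance(t))
    pair_samples = {s for s, p in zip(t.samples, t.populations)
                    if p in ("JJ", "FF")}
    assert is_monophyletic(tree, pair_samples)
    res = pca(t)
    cent = {}
    for p in t.population_names:
        rows = t.sample_indices(p)
        cent[p] = res.coordinates[rows, :2].mean(axis=0)
    def dist(a, b):
        return float(np.linalg.norm(cent[a] - cent[b]))
    others = [p for p in t.population_names if p not in ("JJ", "FF")]
    assert all(dist("JJ", "FF") < dist("JJ", o) for o in others)
    assert all(dist("JJ", "FF") < dist("FF", o) for o in others)
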