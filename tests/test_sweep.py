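"""Windowing, Hp/Fst statistics, Z-transform, outlier calling, merging."""

import numpy as np
import pandas as pd
import pytest

import _oracles
from popsweep.genes import GeneModel
from popsweep.simulate import SimulationConfig, SweepSpec, simulate_cohort
from popsweep.sweep import (ScanConfig, make_windows, merge_regions,
                            overlap_genes, scan_windows, select_outliers,
                            window_fst, window_hp, z_transform)


@pytest.mark.parametrize("length,n_windows", [
    (150_000, 0),    # boundary scaffold excluded (strictly > 150 kb)
    (150_001, 2),    # starts 1 and 50,001
    (250_000, 4),    # starts 1, 50,001, 100,001, 150,001
    (1_000_000, 19),
])
def test_make_windows_enumeration(length, n_windows):
    w = make_windows({"s": length}, ScanConfig())
    assert len(w) == n_windows
    if n_windows:
        assert w["start"].iloc[0] == 1
        assert (w["end"] - w["start"] + 1 == 100_000).all()


def test_window_hp_limits_and_worked_value():
    assert window_hp(np.array([10, 8]), np.array([0, 0])) == 0.0
    assert window_hp(np.array([5, 5]), np.array([5, 5])) == 0.5
    assert window_hp(np.array([10]), np.array([2])) == pytest.approx(
        2 * 10 * 2 / 144)
    assert np.isnan(window_hp(np.array([]), np.array([])))


def test_window_fst_limits_and_worked_value():
    six = np.array([6.0])
    assert window_fst(np.array([1.0]), six, np.array([0.0]), six) == 1.0
    assert window_fst(np.array([1.0]), six, np.array([0.5]), six) == \
        pytest.approx(0.4)
    # identical populations: near zero (negative allowed, unbiased)
    rng = np.random.default_rng(2)
    p = rng.uniform(0.1, 0.9, 500)
    n = np.full(500, 6.0)
    assert abs(window_fst(p, n, p, n)) < 0.5  # exactly equal freqs
    assert window_fst(p, n, p, n) < 0


def test_hp_and_fst_agree_with_brute_force_oracles():
    """Exact agreement with loop-based oracles on 100 random fixtures of
    up to 1,000 SNPs each."""
    rng = np.random.default_rng(67)
    for rep in range(100):
        n = int(rng.integers(1, 1001))
        n1 = rng.integers(2, 7, n).astype(float)
        n2 = rng.integers(2, 7, n).astype(float)
        a1 = rng.integers(0, 7, n)
        maj = np.maximum(a1, rng.integers(0, 7, n))
        mn = np.minimum(a1, rng.integers(0, 7, n))
        p1 = rng.uniform(0, 1, n)
        p2 = rng.uniform(0, 1, n)
        assert window_hp(maj, mn) == pytest.approx(
            _oracles.brute_hp(maj, mn), abs=1e-12)
        got = window_fst(p1, n1, p2, n2)
        want = _oracles.brute_hudson_fst(p1, n1, p2, n2)
        assert got == pytest.approx(want, abs=1e-9)


def test_z_transform_contract():
    assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])
    rng = np.random.default_rng(9)
    x = rng.normal(3, 7, 500)
    z = z_transform(x)
    assert abs(z.mean()) < 1e-12
    assert abs(z.std(ddof=1) - 1) < 1e-12
    with pytest.raises(ValueError):
        z_transform([2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        z_transform([1.0])


def _windows_frame(zhp, zfst):
    n = len(zhp)
    return pd.DataFrame({
        "scaffold": ["s"] * n,
        "start": np.arange(n) * 50_000 + 1,
        "end": np.arange(n) * 50_000 + 100_000,
        "n_snps": 50,
        "hp": 0.2, "fst": 0.1,
        "zhp": zhp, "zfst": zfst,
    })


def test_select_outliers_anti_aligned_fixture():
    """100 windows, exactly 5 jointly extreme (high ZFst, low ZHp):
    exactly those 5 are selected."""
    rng = np.random.default_rng(71)
    zfst = rng.normal(0, 1, 95)
    zhp = rng.normal(0, 1, 95)
    zfst = np.concatenate([zfst, 10 + np.arange(5.0)])
    zhp = np.concatenate([zhp, -10 - np.arange(5.0)])
    w = _windows_frame(zhp, zfst)
    out = select_outliers(w, ScanConfig())
    assert sorted(out.index) == [0, 1, 2, 3, 4]
    assert set(out["start"]) == set(w["start"].iloc[95:])


def test_outlier_count_bounded_by_nearest_rank():
    rng = np.random.default_rng(73)
    for rep in range(20):
        n = int(rng.integers(40, 400))
        zf = rng.normal(0, 1, n)
        zh = rng.normal(0, 1, n)
        w = _windows_frame(zh, zf)
        out = select_outliers(w, ScanConfig())
        thr_n = int(np.ceil(0.05 * n))
        zf_thr = np.sort(zf)[int(np.ceil(0.95 * n)) - 1]
        zh_thr = np.sort(zh)[thr_n - 1]
        ties = int((zf == zf_thr).sum() + (zh == zh_thr).sum())
        assert len(out) <= thr_n + 1 + ties
        # brute-force re-evaluation of the conjunction
        brute = {i for i in range(n) if zf[i] >= zf_thr and zh[i] <= zh_thr}
        assert set(w.index[w["start"].isin(out["start"])]) == brute


def test_select_outliers_needs_enough_windows():
    w = _windows_frame(np.arange(10.0), np.arange(10.0))
    with pytest.raises(ValueError, match="retained windows"):
        select_outliers(w, ScanConfig())


def test_merge_regions_rules():
    w = pd.DataFrame({
        "scaffold": ["s1", "s1", "s1", "s2"],
        "start": [1, 50_001, 100_001, 1],
        "end": [100_000, 150_000, 200_000, 100_000],
    })
    regions = merge_regions(w)
    assert len(regions) == 2
    assert (regions[0].scaffold, regions[0].start, regions[0].end,
            regions[0].n_windows) == ("s1", 1, 200_000, 3)
    assert regions[1].scaffold == "s2"
    # disjoint windows on one scaffold stay separate
    w2 = pd.DataFrame({"scaffold": ["s1", "s1"],
                       "start": [1, 200_001], "end": [100_000, 300_000]})
    assert len(merge_regions(w2)) == 2


def test_overlap_genes_boundary_rules():
    regions = merge_regions(pd.DataFrame(
        {"scaffold": ["s"], "start": [1000], "end": [2000]}))
    inside = GeneModel("g_in", "s", "+", 1200, 1400, exons=[(1200, 1400)],
                       biotype="ncRNA")
    edge = GeneModel("g_edge", "s", "+", 2000, 2500, exons=[(2000, 2500)],
                     biotype="ncRNA")
    outside = GeneModel("g_out", "s", "+", 2001, 2500, exons=[(2001, 2500)],
                        biotype="ncRNA")
    regions, genes = overlap_genes(regions, [inside, edge, outside])
    assert regions[0].genes == ["g_edge", "g_in"]
    assert genes == ["g_edge", "g_in"]


def test_scan_invariant_to_scaffold_order(small_cohort):
    table, _ = small_cohort
    w1 = scan_windows(table, "JJ", "YD",
                      ScanConfig(min_snps_per_window=5))
    # reverse the variant order across scaffolds
    order = np.argsort(-np.arange(table.n_variants))
    t2 = table.subset_variants(order)
    t2.variants = t2.variants.sort_values(["scaffold", "pos"],
                                          ascending=[False, True])
    w2 = scan_windows(table.subset_variants(order[::-1]), "JJ", "YD",
                      ScanConfig(min_snps_per_window=5))
    pd.testing.assert_frame_equal(w1, w2)


def test_planted_sweep_recovered():
    """A planted full-intensity sweep interval intersects a reported
    sweep region on a two-population cohort."""
    sim = SimulationConfig(
        n_scaffolds=3, scaffold_length_bp=600_000,
        n_variants_per_scaffold=1_800, populations=("JJ", "YD"),
        drift_divergence={"JJ": 0.05, "YD": 0.08},
        private_allele_rate=0.0, indel_rate=0.0, seed=19,
        sweep_specs=[SweepSpec("scaffold_2", 200_001, 350_000, "JJ", 1.0)])
    table, truth = simulate_cohort(sim)
    cfg = ScanConfig()
    w = scan_windows(table, "JJ", "YD", cfg)
    assert len(w) >= 20
    out = select_outliers(w, cfg)
    regions = merge_regions(out)
    sw = truth.planted_sweeps[0]
    hit = any(r.scaffold == sw["scaffold"] and r.start <= sw["end"]
              and r.end >= sw["start"] for r in regions)
    assert hit
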