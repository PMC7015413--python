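"""Windowed ZHp/ZFst selective-sweep scan.

Sliding 100 kb windows (50 kb step) over scaffolds longer than 150 kb;
per-window pooled heterozygosity Hp of the focal population and Hudson
Fst between focal and contrast; genome-wide Z-transformation of both;
joint outlier calling (ZFst in the top 5% AND ZHp in the bottom 5%,
nearest-rank percentiles); merging of outlier windows into maximal
regions; and gene overlap.

Hp for a window is ``2 * sum(nMAJ) * sum(nMIN) / (sum(nMAJ) + sum(nMIN))^2``
with major/minor allele counts summed over the window's SNPs.  Low Hp
plus high Fst marks a swept, differentiated window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genes import GeneModel
from .genotypes import GenotypeTable, SiteAlleleCounts, allele_counts


@dataclass
class ScanConfig:
    """Window-scan parameters (defaults as used genome-wide in the study
    design this pipeline follows: 100 kb windows, 50 kb step, scaffolds
    > 150 kb, windows with > 20 SNPs, joint top-5% outliers)."""

    window_size: int = 100_000
    step: int = 50_000
    min_scaffold_length: int = 150_000
    min_snps_per_window: int = 20   # exclusive: windows need > this many
    outlier_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if min(self.window_size, self.step, self.min_scaffold_length) <= 0:
            raise ValueError("sizes must be positive")
        if not 0.0 < self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in (0,1)")


@dataclass
class SweepRegion:
    scaffold: str
    start: int
    end: int
    n_windows: int
    genes: list[str] = field(default_factory=list)


def make_windows(scaffold_lengths: dict[str, int], config: ScanConfig
                 ) -> pd.DataFrame:
    """Enumerate sliding windows, 1-based inclusive.

    Scaffolds are used only when strictly longer than
    ``min_scaffold_length``; windows that would extend past the scaffold
    end are dropped so that every window has the full nominal length.
    """
    rows = []
    for scaf in sorted(scaffold_lengths):
        length = scaffold_lengths[scaf]
        if length <= config.min_scaffold_length:
            continue
        start = 1
        while start + config.window_size - 1 <= length:
            rows.append((scaf, start, start + config.window_size - 1))
            start += config.step
    return pd.DataFrame(rows, columns=["scaffold", "start", "end"])


def window_hp(n_maj: np.ndarray, n_min: np.ndarray) -> float:
    """Pooled heterozygosity of one window from its per-SNP allele counts.

    Returns NaN for an empty window (no SNPs), which excludes it later.
    """
    s_maj = float(np.sum(n_maj))
    s_min = float(np.sum(n_min))
    tot = s_maj + s_min
    if tot == 0:
        return float("nan")
    return 2.0 * s_maj * s_min / (tot * tot)


def hudson_fst_components(p1: np.ndarray, n1: np.ndarray,
                          p2: np.ndarray, n2: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1).  Sites need >= 2 called chromosomes in both
    populations; callers must mask accordingly.
    """
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def window_fst(p1: np.ndarray, n1: np.ndarray,
               p2: np.ndarray, n2: np.ndarray) -> float:
    """Hudson Fst for one window as the ratio of sums over its SNPs.

    Sites with fewer than 2 called chromosomes in either population or a
    zero denominator are skipped; a window with no usable site returns
    NaN (excluded later).
    """
    ok = (n1 >= 2) & (n2 >= 2)
    num, den = hudson_fst_components(p1[ok], n1[ok], p2[ok], n2[ok])
    use = den > 0
    if not np.any(use):
        return float("nan")
    return float(num[use].sum() / den[use].sum())


def z_transform(values: np.ndarray) -> np.ndarray:
    """Z-scores with the sample standard deviation (n-1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise ValueError("need >= 2 finite values to Z-transform")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation: Z-transform undefined")
    return (x - x.mean()) / sd


def _nearest_rank(sorted_values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: value at position ceil(q*N) of the sorted
    sample (1-based)."""
    n = len(sorted_values)
    rank = max(1, int(np.ceil(q * n)))
    return float(sorted_values[rank - 1])


def scan_windows(table: GenotypeTable, focal: str, contrast: str,
                 config: ScanConfig | None = None,
                 counts: SiteAlleleCounts | None = None) -> pd.DataFrame:
    """Per-window SNP count, Hp (focal), Hudson Fst (focal vs contrast),
    ZHp and ZFst.

    Only SNPs enter the statistics.  Windows with ``n_snps`` at or below
    the configured minimum, or with an undefined statistic, are dropped
    before the genome-wide Z-transformation.
    """
    config = config or ScanConfig()
    snp_idx = np.flatnonzero(table.snp_mask())
    sub = table.subset_variants(snp_idx)
    if counts is None:
        counts = allele_counts(sub)
    fi = counts.pop_index(focal)
    ci = counts.pop_index(contrast)
    n_maj, n_min = counts.n_maj[fi], counts.n_min[fi]
    p1 = counts.alt_freq(focal)
    p2 = counts.alt_freq(contrast)
    nc1 = counts.called[fi].astype(float)
    nc2 = counts.called[ci].astype(float)

    windows = make_windows(table.scaffold_lengths, config)
    scafs = sub.variants["scaffold"].to_numpy()
    poss = sub.variants["pos"].to_numpy()
    rows = []
    for scaf, group in windows.groupby("scaffold", sort=True):
        on = scafs == scaf
        pos_s = poss[on]
        order = np.argsort(pos_s)
        pos_s = pos_s[order]
        site_idx = np.flatnonzero(on)[order]
        for w in group.itertuples(index=False):
            lo = np.searchsorted(pos_s, w.start, side="left")
            hi = np.searchsorted(pos_s, w.end, side="right")
            sites = site_idx[lo:hi]
            n_snps = len(sites)
            hp = window_hp(n_maj[sites], n_min[sites])
            fst = window_fst(p1[sites], nc1[sites], p2[sites], nc2[sites])
            rows.append((scaf, w.start, w.end, n_snps, hp, fst))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_snps",
                                     "hp", "fst"])
    retained = df[(df["n_snps"] > config.min_snps_per_window)
                  & np.isfinite(df["hp"]) & np.isfinite(df["fst"])].copy()
    retained = retained.reset_index(drop=True)
    if len(retained) >= 2:
        retained["zhp"] = z_transform(retained["hp"].to_numpy())
        retained["zfst"] = z_transform(retained["fst"].to_numpy())
    else:
        retained["zhp"] = np.nan
        retained["zfst"] = np.nan
    return retained


def select_outliers(windows: pd.DataFrame, config: ScanConfig | None = None
                    ) -> pd.DataFrame:
    """Joint outliers: ZFst at/above its (1-f) nearest-rank percentile AND
    ZHp at/below its f percentile.  Ties at either threshold are included.
    """
    config = config or ScanConfig()
    if len(windows) < 20:
        raise ValueError(
            f"only {len(windows)} retained windows; outlier thresholds "
            "would be meaningless"
        )
    f = config.outlier_fraction
    zf = np.sort(windows["zfst"].to_numpy())
    zh = np.sort(windows["zhp"].to_numpy())
    zf_thr = _nearest_rank(zf, 1.0 - f)
    zh_thr = _nearest_rank(zh, f)
    sel = (windows["zfst"] >= zf_thr) & (windows["zhp"] <= zh_thr)
    return windows[sel].reset_index(drop=True)


def merge_regions(outliers: pd.DataFrame) -> list[SweepRegion]:
    """Merge overlapping or book-ended (<= 1 bp gap) outlier windows on
    one scaffold into maximal regions."""
    regions: list[SweepRegion] = []
    if not len(outliers):
        return regions
    df = outliers.sort_values(["scaffold", "start"])
    cur = None
    for w in df.itertuples(index=False):
        if (cur is not None and w.scaffold == cur.scaffold
                and w.start <= cur.end + 2):
            cur.end = max(cur.end, w.end)
            cur.n_windows += 1
        else:
            if cur is not None:
                regions.append(cur)
            cur = SweepRegion(scaffold=w.scaffold, start=int(w.start),
                              end=int(w.end), n_windows=1)
    regions.append(cur)
    return regions


def overlap_genes(regions: list[SweepRegion], models: list[GeneModel]
                  ) -> tuple[list[SweepRegion], list[str]]:
    """Attach genes whose transcript span intersects a region by >= 1 bp.

    Returns the regions (gene lists filled in, sorted) and the
    deduplicated global gene list.
    """
    trees: dict[str, IntervalTree] = {}
    for m in models:
        trees.setdefault(m.scaffold, IntervalTree()).addi(
            m.start, m.end + 1, m.gene_id)
    all_genes: set[str] = set()
    for region in regions:
        tree = trees.get(region.scaffold)
        if tree is None:
            region.genes = []
            continue
        hits = sorted(iv.data for iv in tree.overlap(region.start,
                                                     region.end + 1))
        region.genes = hits
        all_genes.update(hits)
    return regions, sorted(all_genes)


def run_scan(table: GenotypeTable, focal: str, contrast: str,
             models: list[GeneModel], config: ScanConfig | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame, list[SweepRegion],
                        list[str]]:
    """Full scan: windows -> outliers -> merged regions -> gene overlap."""
    config = config or ScanConfig()
    windows = scan_windows(table, focal, contrast, config)
    outliers = select_outliers(windows, config)
    regions = merge_regions(outliers)
    regions, genes = overlap_genes(regions, models)
    return windows, outliers, regions, genes


def write_windows_tsv(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_regions_bed(regions: list[SweepRegion], path) -> None:
    """BED (0-based half-open) of merged sweep regions with gene lists."""
    with open(path, "w") as fh:
        for r in regions:
            genes = ",".join(r.genes) if r.genes else "."
            fh.write(f"{r.scaffold}\t{r.start - 1}\t{r.end}\t{genes}\n")
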