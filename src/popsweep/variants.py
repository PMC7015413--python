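"""VCF input and the study's variant filters.

Reads a multi-sample VCF (GT and DP FORMAT fields) into a
:class:`~popsweep.genotypes.GenotypeTable` and applies the per-site
filters used throughout the pipeline: the site-depth filter (total DP
across samples outside [low, high] discarded), the minor-allele-frequency
filter (MAF <= threshold removed), and per-breed merged call sets.

Multi-allelic records are dropped entirely rather than split: sites with
more than two alleles are removed from every downstream analysis.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .genotypes import INDEL, MISSING, SNP, GenotypeTable

log = logging.getLogger(__name__)

#: maximum indel length (bp) retained, matching the calling pipeline's range
MAX_INDEL_LEN = 50


def read_population_map(path) -> dict[str, str]:
    """Read a two-column sample<TAB>population file into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"sample {dup!r} listed twice in population map")
    return dict(zip(df["sample"], df["population"]))


def _classify_alleles(ref: str, alt: str) -> str | None:
    """SNP, indel (length difference 1-50 bp) or None (dropped)."""
    if len(ref) == 1 and len(alt) == 1:
        return SNP
    diff = abs(len(ref) - len(alt))
    if 1 <= diff <= MAX_INDEL_LEN:
        return INDEL
    return None


def read_vcf(vcf_path, population_map_path) -> GenotypeTable:
    """Load a multi-sample VCF into a genotype table.

    Record order is preserved.  Multi-allelic records are dropped, as are
    records that are neither a SNP nor a 1-50 bp indel.  Missing genotypes
    ("./.") become the missing dosage code.  Scaffold lengths are taken
    from the ``##contig`` header lines; a used scaffold without a declared
    length is an error.

    Raises
    ------
    ValueError
        If a VCF sample is absent from the population map, or a used
        scaffold has no contig length in the header.
    """
    pop_map = read_population_map(population_map_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pop_map]
    if missing_samples:
        raise ValueError(
            f"samples {missing_samples} present in VCF but absent from "
            f"population map {population_map_path}"
        )
    populations = [pop_map[s] for s in samples]

    lengths: dict[str, int] = {}
    try:
        lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig lines
        lengths = {}

    rows = []
    gts = []
    dps = []
    no_dp = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # multi-allelic: dropped
        vclass = _classify_alleles(rec.REF, rec.ALT[0])
        if vclass is None:
            continue
        if rec.CHROM not in lengths:
            raise ValueError(
                f"VCF header declares no contig length for scaffold "
                f"{rec.CHROM!r} (record at {rec.CHROM}:{rec.POS})"
            )
        # gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = rec.gt_types.astype(np.int8)
        if g.max(initial=0) > 3 or g.min(initial=0) < 0:
            raise ValueError(f"malformed GT at {rec.CHROM}:{rec.POS}")
        g[g == 3] = MISSING
        dp = rec.format("DP")
        if dp is None:
            no_dp += 1
            dp_row = np.full(len(samples), -1, dtype=np.int32)
        else:
            dp_row = dp.reshape(-1).astype(np.int32)
            dp_row[dp_row < 0] = -1
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0], vclass))
        gts.append(g)
        dps.append(dp_row)
    if no_dp:
        log.warning("%d records lacked a DP field; retained with DP=-1", no_dp)

    variants = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "vclass"])
    genotypes = (np.vstack(gts).T if gts
                 else np.empty((len(samples), 0), dtype=np.int8))
    depths = (np.vstack(dps).T if dps
              else np.empty((len(samples), 0), dtype=np.int32))
    used = set(variants["scaffold"].unique()) if len(variants) else set()
    return GenotypeTable(
        samples=samples,
        populations=populations,
        variants=variants,
        genotypes=genotypes,
        depths=depths,
        scaffold_lengths={k: v for k, v in lengths.items()} or
                         {s: 0 for s in used},
    )


def filter_depth(table: GenotypeTable, low: int = 4, high: int = 500
                 ) -> tuple[GenotypeTable, int]:
    """Discard sites with ultra-low or ultra-high total coverage.

    A site is removed when the summed DP over all samples is < *low* or
    > *high* (boundaries themselves are retained).  Sites where no sample
    has a DP value are retained with a warning.

    Returns the filtered table and the number of sites removed.
    """
    if table.depths is None:
        warnings.warn("table has no DP values; depth filter is a no-op")
        return table, 0
    dp = table.depths
    has_dp = dp >= 0
    site_dp = np.where(has_dp, dp, 0).sum(axis=0)
    any_dp = has_dp.any(axis=0)
    keep = (site_dp >= low) & (site_dp <= high)
    n_missing_dp = int((~any_dp).sum())
    if n_missing_dp:
        log.warning("%d sites lack DP entirely; retained", n_missing_dp)
        keep |= ~any_dp
    removed = int((~keep).sum())
    return table.subset_variants(keep), removed


def maf_filter(table: GenotypeTable, threshold: float = 0.1
               ) -> tuple[GenotypeTable, int]:
    """Remove sites whose minor-allele frequency is <= *threshold*.

    MAF is computed over the called chromosomes of all samples pooled
    (missing genotypes contribute nothing).  The boundary is inclusive:
    MAF exactly equal to *threshold* is removed, so monomorphic sites
    (MAF 0) always are.
    """
    g = table.genotypes
    called = g != MISSING
    n_chrom = 2 * called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, alt / np.maximum(n_chrom, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = maf > threshold
    removed = int((~keep).sum())
    return table.subset_variants(keep), removed


def population_union(table: GenotypeTable, population: str) -> set[int]:
    """Variant indices carried by at least one individual of *population*.

    This is the per-breed merged call set: a variant belongs to a breed's
    set when any of its individuals carries >= 1 alternate allele.  Missing
    genotypes are not evidence of the allele.
    """
    idx = table.sample_indices(population)  # raises KeyError if unknown
    g = table.genotypes[idx, :]
    carrier = (g > 0).any(axis=0)
    return set(np.flatnonzero(carrier).tolist())


def write_filter_report(path, stage_counts: dict[str, int]) -> None:
    """Write a small TSV accounting of sites removed per filter stage."""
    with open(path, "w") as fh:
        fh.write("stage\tsites_removed\n")
        for stage, n in stage_counts.items():
            fh.write(f"{stage}\t{n}\n")
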