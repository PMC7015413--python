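# popsweep

Post-variant-calling population genomics for small multi-breed
resequencing cohorts: variant filtering and annotation, breed-private SNP
discovery, population structure (neighbor-joining tree and genotype PCA),
windowed ZHp/ZFst selective-sweep scans, and gene-set over-representation
— validated end-to-end on a synthetic multi-population cohort with
planted sweeps and private alleles.

## Who this is for

Groups analysing a handful of pooled-by-breed diploid genomes (a few
individuals per population, scaffold-level reference) who want the
classic domestication-scan workflow as tested, reusable code: start from
a multi-sample VCF, end with candidate selection regions, the genes they
contain, and enrichment tables.

## The statistics at the core

For each 100 kb window (step 50 kb) on scaffolds longer than 150 kb,
using only windows with more than 20 SNPs:

* **Pooled heterozygosity** of the focal population,

  `Hp = 2 ΣnMAJ ΣnMIN / (ΣnMAJ + ΣnMIN)²`,

  where `nMAJ`/`nMIN` are the major/minor allele counts at each in-window
  SNP, summed over the window. `Hp ∈ [0, 0.5]`; swept regions are low.
* **Hudson's Fst** between focal and contrast populations, combined over
  the window as a ratio of sums: per site
  `N = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)` and
  `D = p₁(1−p₂) + p₂(1−p₁)`, window `Fst = ΣN / ΣD`.
* Both are **Z-transformed genome-wide**; windows with ZFst in the top 5%
  *and* ZHp in the bottom 5% (nearest-rank percentiles, ties included)
  are called selection regions, merged when overlapping, and intersected
  with gene models.

Around the scan: site-depth filtering (total DP < 4 or > 500 discarded),
MAF ≤ 0.1 removal before structure analyses, ANNOVAR-style region
categories with codon-level effect calls (synonymous / nonsynonymous /
stop-gain / stop-loss), a private-SNP rule (allele in ≥ 2 of 3 focal
individuals and in no other individual), IBS-distance neighbor joining,
smartpca-style PCA, and one-sided hypergeometric enrichment with
Benjamini–Hochberg q-values.

## Worked example

Run the default synthetic study — five populations (a Muscovy-like pair
JJ/FF sharing a recent branch, a mallard-like YD, plus HD and BD), three
diploid individuals each, 5 scaffolds × 1 Mb, 3,000 variants per
scaffold, one planted full-intensity sweep for JJ on
scaffold_1:400,001–550,000:

```bash
popsweep run-all --seed 1 --out out/
```

The manifest printed at the end (seed 1) includes:

```
"variants_read": 15000,        # biallelic SNPs+indels loaded from the VCF
"removed_by_depth": 0,         # no site outside total DP [4, 500]
"specific_snps": 80,           # JJ-private SNPs (>= 2 of 3 carriers)
"removed_by_maf": 3301,        # MAF <= 0.1 sites dropped before structure
"windows_retained_JJ_vs_YD": 95,
"outlier_windows_JJ_vs_YD": 4, # joint low-ZHp / high-ZFst windows
"sweep_regions_JJ_vs_YD": 1,   # merged region scaffold_1:350,001-600,000
"sweep_genes_JJ_vs_YD": 15,    # genes overlapping that region
```

The single JJ-vs-YD region contains the planted sweep interval; the
NJ tree in `out/nj_tree.nwk` groups the six JJ/FF samples as a clade.
Stage outputs land in `out/`: the simulated file set (`sim/cohort.vcf`,
`sim/genes.gff3`, `sim/genome.fa`, population and term maps, truth
record), `annotations.tsv` + `region_summary.tsv`, `specific_snps.tsv`,
`nj_tree.nwk`, `pca_coordinates.tsv`, per-contrast `windows_*.tsv` /
`regions_*.bed` / `sweep_genes_*.txt`, enrichment tables and
`manifest.json`. Each stage is also a subcommand (`popsweep simulate`,
`filter`, `annotate`, `specific`, `structure`, `sweep`, `enrich`) so
stages compose through files; `popsweep run-all --config my.yaml` takes a
YAML config (`popsweep init-config` writes the default) that can instead
point at real inputs (VCF, GFF3, FASTA, sample→population map, gene→term
maps).

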