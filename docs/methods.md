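# Methods

This note records the models, defaults and numerical conventions behind
popsweep, and what the synthetic validation does and does not establish.

## Cohort model (synthetic data)

The generator emulates a five-population resequencing design with three
diploid individuals per population on sub-chromosomal scaffolds.

* **Ancestral frequencies.** Each variant's ancestral alternate-allele
  frequency is uniform on (0.05, 0.95), keeping sites segregating and
  informative.
* **Drift.** Each population branch applies a Balding–Nichols draw,
  `p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`, around its parent frequency. The
  first two populations (the Muscovy-like pair, default labels JJ and
  FF) first share a draw on a common branch (`shared_branch_f`, default
  0.15) and then drift independently (F = 0.05 each); the remaining
  populations drift directly from the ancestor (YD 0.08, HD 0.15,
  BD 0.18). These F values are free design parameters, not estimates of
  any real breed: they were chosen once to yield clear but imperfect
  population separation — a Muscovy pair that clusters, a mallard-like
  population at intermediate distance — at 15 samples.
* **Genotypes.** Binomial(2, p_pop) per individual; optional uniform
  missingness (`missing_rate`, default 0).
* **Sweeps.** A planted sweep pushes the focal population's frequency at
  every in-interval site toward the nearer boundary:
  `q' = q + intensity·(target − q)` with `target = 1 if q ≥ 0.5 else 0`.
  Intensity 1 fixes every site, so focal heterozygosity inside the
  interval is exactly zero and divergence from any contrast population
  rises; intermediate intensities interpolate monotonically.
* **Private alleles.** A configurable fraction of sites (default 0.02)
  is made private: the alternate frequency is zeroed in every population
  except the owner (rotating over populations), and after genotype
  drawing at least two owner individuals are forced to carry the allele
  so the discovery rule (≥ 2 carriers) can in principle recover every
  planted site. Private sites are never placed inside sweep intervals.
* **Depth.** Per-sample DP is Poisson(`mean_depth`, default 12). An
  optional `depth_outlier_rate` plants sites whose total depth exceeds
  500 or falls below 4 to exercise the depth filter.
* **Genome and genes.** Scaffolds (≥ 200 kb) carry uniform random
  sequence with non-overlapping three-exon protein-coding genes (and a
  fraction of two-exon ncRNAs, default 0.1) tiled at 8–25 kb gaps on
  both strands. Each CDS is ATG + 60–150 non-stop codons + one stop,
  embedded into the scaffold sequence so that VCF REF alleles, the
  emitted FASTA and effect classification are mutually consistent.
  GO-term and pathway maps assign 0–4 / 0–2 labels per gene from small
  pools.
* **Determinism.** All randomness flows from one seed through named
  `numpy` generator substreams (genome, cohort, term maps); two runs
  with one seed produce byte-identical files.

What the generator does **not** emulate: linkage disequilibrium beyond
drift (sites are exchangeable given frequencies), recombination maps,
sequencing error or read-level artefacts, indel realignment ambiguity,
or realistic gene density (genes cover only a few percent of the
synthetic scaffolds, so region-category proportions differ from a real
annotation where intronic variants dominate). Passing tests therefore
demonstrate the correctness of the statistical machinery under the
assumed sampling model, not calibration on real genomes.

## Analysis conventions

* **Variants.** Multi-allelic records are dropped entirely; indels are
  1–50 bp; coordinates are 1-based VCF positions (indels anchored at the
  VCF anchor base). Missing genotypes are never evidence of an allele.
* **Depth filter.** Operates on the per-site total DP across samples,
  bounds inclusive-keep (total < 4 or > 500 removed); sites with no DP
  at all are retained with a warning. The bounds are parameters, as is
  the choice of operand.
* **MAF filter.** Minor-allele frequency over all called chromosomes
  pooled; the removal boundary is inclusive (MAF ≤ 0.1 goes), applied
  before the structure analyses only.
* **Allele counts.** Major/minor assignment is per population per site;
  exact ties assign the major count to the reference allele, keeping
  results reference-stable and deterministic.
* **Region categories.** ANNOVAR-style precedence: splicing > exonic >
  UTR5 > UTR3 > intronic > upstream/downstream > intergenic, with ncRNA
  transcripts yielding ncRNA_exonic / ncRNA_intronic. The splice window
  is the canonical 2 bp of intron adjacent to a junction (exonic
  positions are never splicing). The flank is 1 kb from the transcript
  span (configurable); hits on both flanks give "upstream;downstream".
  Between genes at equal precedence the alphabetically first gene id is
  reported. Indels receive region categories but no effect calls.
* **Effect calls.** The reference codon is built from the spliced CDS
  honouring strand and frame; the alternate base is complemented on the
  minus strand; both codons are translated with the standard genetic
  code. Stop-gain/stop-loss take precedence over the amino-acid
  comparison. A VCF REF base that contradicts the supplied FASTA is an
  error, not a silent skip.
* **Private-SNP rule.** ≥ `min_individuals` (default 2) focal carriers,
  zygosity-agnostic, and zero carriers elsewhere. Missing non-focal
  genotypes are treated as "allele not observed"; `strict_missing`
  instead requires every non-focal genotype to be a called homozygous
  reference.
* **Distances and trees.** Sample distance is allele-sharing (1 − IBS):
  mean |dosage difference|/2 over co-called sites, in [0, 1]. Neighbor
  joining uses the Studier–Keppler Q criterion; Q ties are broken by the
  lexicographically smallest pair of cluster representative labels;
  negative branch-length estimates are clamped to zero with the deficit
  moved to the sibling edge; the tree is left unrooted and written with
  a trifurcating root.
* **PCA.** Dosage columns are mean-imputed for missing calls, centred,
  and scaled by 1/sqrt(p(1−p)) with p = column mean / 2 (the simple
  moment estimate rather than a posterior; exactly testable and
  indistinguishable at these sample sizes). Monomorphic columns are
  dropped. Variance-explained percentages are taken over all eigenvalues
  (clipped at zero) and sum to 100; each component's sign is fixed by
  making its largest-magnitude sample loading positive.
* **Scan.** Windows are dropped (not truncated) at scaffold ends so
  every window has the full nominal length, keeping the per-window
  variance of Hp and Fst homogeneous — the genome-wide Z-transformation
  assumes comparable windows. Scaffolds must be strictly longer than
  150 kb; windows need strictly more than 20 SNPs; only SNPs enter Hp
  and Fst. Z-scores use the sample SD (n−1). Percentile thresholds are
  nearest-rank over the retained windows (computed after the SNP-count
  filter), with ties included on both sides; outlier calling requires at
  least 20 retained windows. Merging joins overlapping or book-ended
  (≤ 1 bp gap) outlier windows; a gene is attached to a region on ≥ 1 bp
  of transcript-span overlap.
* **Enrichment.** One-sided hypergeometric upper tail per term; the
  background is restricted to annotated genes, and unannotated query
  genes are dropped with a logged count. Term maps are flat — no
  ontology graph traversal. q-values are Benjamini–Hochberg. The default
  significance filter is p < 0.05 (configurable to q).
* **Pipeline.** `run_all` writes the simulated inputs, reads them back
  through the same readers used for real data (so every file format is
  exercised on every run), then runs filter → annotate → private SNPs →
  structure → one scan per configured contrast (defaults JJ–YD and
  JJ–BD) → enrichment. In `run_all` an empty gene list for one
  enrichment target logs a warning and skips that table rather than
  aborting the whole run — a small default cohort can legitimately yield
  no specific-nonsynonymous genes; the `enrich` subcommand, by contrast,
  exits non-zero on an empty list. The manifest hashes the
  analysis-relevant configuration (output paths excluded) so reruns are
  comparable.

## Problem sizes used in validation

The test suite and the acceptance script use compact study designs —
2–5 scaffolds of 0.25–1 Mb, 800–3,000 variants per scaffold, 10–20 seeds
per stochastic property — chosen so the full validation completes in a
few minutes while leaving every window comfortably above the > 20-SNP
threshold and every scan with ≥ 20 retained windows. Stochastic
properties (sweep recovery, clade recovery, PC1 separation) are asserted
at ≥ 90% of seeds, mirroring the fact that they are statistical, not
deterministic, guarantees.

## Known limitations

* Hp is computed from genotype-derived allele counts (two chromosomes
  per called individual), not from pooled read counts as in pooled-
  sequencing designs; with three individuals per population Hp is
  noisy, which the windowed aggregation and Z-scoring absorb.
* With 15 samples the Hudson Fst per window can be negative; this is
  expected of an unbiased estimator near zero differentiation.
* The NJ implementation is O(n⁴) in leaf count with pure-python pair
  selection; fine for cohort-scale trees (tens of samples), not for
  thousands of taxa.
* Effect calls are transcript-naive: one transcript per gene, no
  isoform-resolved reports, no frameshift annotation for indels.
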