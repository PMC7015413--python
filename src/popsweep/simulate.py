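"""Synthetic multi-population cohort generator.

Emulates a resequencing study of five duck populations (a Muscovy-like
pair that shares a recent branch, a mallard-like ancestor proxy, and two
further domesticated breeds) with three diploid individuals each.  Drift
is modelled per population branch with Balding-Nichols Beta distributions
around a shared ancestral allele frequency; selective sweeps are planted
by pushing the focal population's allele frequency toward fixation, and
population-private alleles are planted by restricting the alternate
allele to one population.

Everything is deterministic given the seed: genome sequence, gene models,
variant positions, genotypes and depths all flow from named substreams of
one :func:`numpy.random.default_rng` seed sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genes import NCRNA, PROTEIN_CODING, GeneModel, write_fasta, write_gff3
from .genotypes import GenotypeTable

STOP_CODONS = ("TAA", "TAG", "TGA")
BASES = np.frombuffer(b"ACGT", dtype="S1")

# rng substream tags (second word of the seed sequence)
_GENOME_STREAM = 1
_COHORT_STREAM = 2
_TERMS_STREAM = 3


@dataclass
class SweepSpec:
    """A planted sweep: interval, focal population and intensity in (0,1]."""

    scaffold: str
    start: int
    end: int
    focal_population: str
    intensity: float = 1.0


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the five-population, three-individuals-per-population
    design with ~12x mean depth.  The first two populations play the
    Muscovy-like roles and share a recent branch (``shared_branch_f``),
    which makes their allele frequencies correlated; the third population
    plays the mallard-like ancestor proxy.
    """

    n_scaffolds: int = 5
    scaffold_length_bp: int = 1_000_000
    n_variants_per_scaffold: int = 3_000
    populations: tuple[str, ...] = ("JJ", "FF", "YD", "HD", "BD")
    n_individuals_per_population: int = 3
    drift_divergence: dict[str, float] | None = None
    shared_branch_f: float = 0.15
    sweep_specs: list[SweepSpec] | None = None
    private_allele_rate: float = 0.02
    mean_depth: float = 12.0
    depth_outlier_rate: float = 0.0
    indel_rate: float = 0.05
    missing_rate: float = 0.0
    ncrna_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("population labels must be unique")
        if self.n_scaffolds < 1 or self.n_individuals_per_population < 1:
            raise ValueError("counts must be positive")
        if self.scaffold_length_bp < 200_000:
            raise ValueError("scaffold_length_bp must be >= 200,000")
        if self.drift_divergence is None:
            defaults = [0.05, 0.05, 0.08, 0.15, 0.18]
            self.drift_divergence = {
                p: defaults[i % len(defaults)]
                for i, p in enumerate(self.populations)
            }
        for p, f in self.drift_divergence.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"drift F for {p} must be in (0,1), got {f}")
        if not 0.0 < self.shared_branch_f < 1.0:
            raise ValueError("shared_branch_f must be in (0,1)")
        if not 0.0 <= self.private_allele_rate < 1.0:
            raise ValueError("private_allele_rate must be in [0,1)")
        if self.sweep_specs is None:
            self.sweep_specs = []
        for sw in self.sweep_specs:
            if not 0.0 < sw.intensity <= 1.0:
                raise ValueError("sweep intensity must be in (0,1]")
            if sw.focal_population not in self.populations:
                raise ValueError(f"unknown sweep focal {sw.focal_population!r}")
            if sw.scaffold not in self.scaffold_names:
                raise ValueError(f"sweep scaffold {sw.scaffold!r} does not exist")
            if not (1 <= sw.start <= sw.end <= self.scaffold_length_bp):
                raise ValueError(
                    f"sweep interval {sw.start}-{sw.end} outside scaffold "
                    f"{sw.scaffold} (length {self.scaffold_length_bp})"
                )
        by_focal: dict[str, list[SweepSpec]] = {}
        for sw in self.sweep_specs:
            by_focal.setdefault(sw.focal_population, []).append(sw)
        for focal, sweeps in by_focal.items():
            per_scaf: dict[str, list[SweepSpec]] = {}
            for sw in sweeps:
                per_scaf.setdefault(sw.scaffold, []).append(sw)
            for scaf, group in per_scaf.items():
                group = sorted(group, key=lambda s: s.start)
                for a, b in zip(group, group[1:]):
                    if b.start <= a.end:
                        raise ValueError(
                            f"overlapping sweep intervals for {focal} on {scaf}"
                        )

    @property
    def scaffold_names(self) -> list[str]:
        return [f"scaffold_{i + 1}" for i in range(self.n_scaffolds)]

    @property
    def muscovy_pair(self) -> tuple[str, str]:
        return self.populations[0], self.populations[1]


@dataclass
class TruthRecord:
    """Ground truth of what the generator planted."""

    planted_sweeps: list[dict]
    planted_private_sites: list[dict]
    population_tree: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_sweeps": self.planted_sweeps,
                    "planted_private_sites": self.planted_private_sites,
                    "population_tree": self.population_tree,
                },
                fh, indent=1, sort_keys=True,
            )

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["planted_sweeps"], d["planted_private_sites"],
                   d["population_tree"])


# ----------------------------------------------------------------------
# Genome and gene models
# ----------------------------------------------------------------------

_MIN_GENE_SPAN = 4_000  # conservative upper bound on one gene's footprint


def _random_cds(rng: np.random.Generator, n_internal: int) -> str:
    """ATG + n_internal random non-stop codons + one stop codon."""
    codons = ["ATG"]
    while len(codons) < n_internal + 1:
        codon = "".join(rng.choice(["A", "C", "G", "T"], size=3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    codons.append(STOP_CODONS[rng.integers(0, 3)])
    return "".join(codons)


def _build_gene(rng: np.random.Generator, gene_id: str, scaffold: str,
                anchor: int, strand: str, biotype: str
                ) -> tuple[GeneModel, str | None]:
    """Lay out one multi-exon gene starting at genomic *anchor*.

    Returns the model and, for coding genes, the coding-strand CDS
    sequence to embed in the genome.
    """
    u5 = int(rng.integers(60, 150))
    u3 = int(rng.integers(80, 200))
    n_internal = int(rng.integers(60, 150))
    cds_len = 3 * (n_internal + 2)
    i1 = int(rng.integers(200, 500))
    i2 = int(rng.integers(200, 500))
    # split CDS across three exons
    c1 = 3 * int(rng.integers(10, n_internal // 2))
    c2 = 3 * int(rng.integers(10, n_internal // 2))
    c3 = cds_len - c1 - c2

    if biotype == NCRNA:
        e1 = int(rng.integers(150, 400))
        e2 = int(rng.integers(150, 400))
        s1, en1 = anchor, anchor + e1 - 1
        s2, en2 = en1 + i1 + 1, en1 + i1 + e2
        model = GeneModel(gene_id=gene_id, scaffold=scaffold, strand=strand,
                          start=s1, end=en2, exons=[(s1, en1), (s2, en2)],
                          biotype=NCRNA)
        return model, None

    # transcript laid out 5'->3' in genomic forward coordinates; for "-"
    # strand genes the genomic layout is mirrored (UTR3 first).
    if strand == "+":
        lens = [u5 + c1, i1, c2, i2, c3 + u3]
    else:
        lens = [u3 + c3, i1, c2, i2, c1 + u5]
    s = anchor
    blocks = []
    for L in lens:
        blocks.append((s, s + L - 1))
        s += L
    ex1, _, ex2, _, ex3 = blocks
    exons = [ex1, ex2, ex3]
    if strand == "+":
        utr5 = [(ex1[0], ex1[0] + u5 - 1)]
        cds = [(ex1[0] + u5, ex1[1]), ex2, (ex3[0], ex3[1] - u3)]
        utr3 = [(ex3[1] - u3 + 1, ex3[1])]
    else:
        utr3 = [(ex1[0], ex1[0] + u3 - 1)]
        cds = [(ex1[0] + u3, ex1[1]), ex2, (ex3[0], ex3[1] - u5)]
        utr5 = [(ex3[1] - u5 + 1, ex3[1])]
    model = GeneModel(gene_id=gene_id, scaffold=scaffold, strand=strand,
                      start=ex1[0], end=ex3[1], exons=exons, cds=cds,
                      utr5=utr5, utr3=utr3, biotype=PROTEIN_CODING)
    return model, _random_cds(rng, n_internal)


def _build_genome_and_genes(config: SimulationConfig
                            ) -> tuple[dict[str, str], list[GeneModel]]:
    """Deterministically build scaffold sequences with embedded genes."""
    rng = np.random.default_rng([config.seed, _GENOME_STREAM])
    L = config.scaffold_length_bp
    if L < _MIN_GENE_SPAN + 2_000:
        raise ValueError(
            f"scaffold length {L} too short to place one gene "
            f"(needs >= {_MIN_GENE_SPAN + 2_000} bp)"
        )
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    gene_no = 0
    for scaf in config.scaffold_names:
        seq = rng.choice(BASES, size=L)
        pos = int(rng.integers(1_000, 3_000))
        while pos + _MIN_GENE_SPAN < L - 1_000:
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = (NCRNA if rng.random() < config.ncrna_fraction
                       else PROTEIN_CODING)
            model, cds_seq = _build_gene(
                rng, f"gene{gene_no:05d}", scaf, pos, strand, biotype)
            models.append(model)
            if cds_seq is not None:
                embed = (cds_seq if strand == "+"
                         else str(Seq(cds_seq).reverse_complement()))
                k = 0
                for s, e in model.cds:
                    n = e - s + 1
                    seq[s - 1:e] = np.frombuffer(
                        embed[k:k + n].encode(), dtype="S1")
                    k += n
            pos = model.end + int(rng.integers(8_000, 25_000))
        genome[scaf] = seq.tobytes().decode()
    return genome, models


def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Scaffold sequences (genes embedded), deterministic given the seed."""
    return _build_genome_and_genes(config)[0]


def simulate_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping multi-exon gene models tiled along each scaffold."""
    return _build_genome_and_genes(config)[1]


def simulate_term_maps(config: SimulationConfig, models: list[GeneModel],
                       n_go_terms: int = 30, n_pathways: int = 12
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign 0-4 GO terms and 0-2 pathways to each gene, deterministically."""
    rng = np.random.default_rng([config.seed, _TERMS_STREAM])
    go_ids = [f"GO:{i + 1:07d}" for i in range(n_go_terms)]
    pw_ids = [f"map{i + 1:05d}" for i in range(n_pathways)]
    go_rows, pw_rows = [], []
    for m in models:
        for t in rng.choice(go_ids, size=int(rng.integers(0, 5)), replace=False):
            go_rows.append((m.gene_id, t))
        for t in rng.choice(pw_ids, size=int(rng.integers(0, 3)), replace=False):
            pw_rows.append((m.gene_id, t))
    go = pd.DataFrame(go_rows, columns=["gene", "term"])
    pw = pd.DataFrame(pw_rows, columns=["gene", "term"])
    return go, pw


# ----------------------------------------------------------------------
# Cohort
# ----------------------------------------------------------------------

def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float
                     ) -> np.ndarray:
    """Draw drifted frequencies Beta(p(1-F)/F, (1-p)(1-F)/F) around *p*."""
    if f < 1e-9:
        return p.copy()
    p = np.clip(p, 1e-6, 1.0 - 1e-6)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[GenotypeTable, TruthRecord]:
    """Draw genotypes for the whole cohort.

    Ancestral allele frequencies are uniform on (0.05, 0.95); each
    population's frequency is a Balding-Nichols draw around the ancestral
    value with its branch F.  The Muscovy-like pair first shares a
    Balding-Nichols draw on their common branch, which correlates their
    frequencies.  Genotypes are binomial(2, p_pop) per individual; planted
    sweeps push the focal population's frequency toward the nearer
    boundary by ``intensity``; planted private sites carry the alternate
    allele only in the owner population, with at least two carriers.
    """
    rng = np.random.default_rng([config.seed, _COHORT_STREAM])
    genome, _ = _build_genome_and_genes(config)
    pops = list(config.populations)
    n_ind = config.n_individuals_per_population
    samples = [f"{p}{i + 1}" for p in pops for i in range(n_ind)]
    sample_pops = [p for p in pops for _ in range(n_ind)]

    rows = []
    for scaf in config.scaffold_names:
        L = config.scaffold_length_bp
        positions = np.sort(rng.choice(
            np.arange(1, L - 60), size=config.n_variants_per_scaffold,
            replace=False))
        seq = genome[scaf]
        for pos in positions:
            ref_base = seq[pos - 1]
            if rng.random() < config.indel_rate:
                k = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # insertion
                    ins = "".join(rng.choice(["A", "C", "G", "T"], size=k))
                    ref, alt = ref_base, ref_base + ins
                else:  # deletion
                    ref, alt = seq[pos - 1:pos + k], ref_base
                vclass = "indel"
            else:
                others = [b for b in "ACGT" if b != ref_base]
                ref, alt = ref_base, others[rng.integers(0, 3)]
                vclass = "SNP"
            rows.append((scaf, int(pos), ref, alt, vclass))
    variants = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt",
                                           "vclass"])
    n_sites = len(variants)

    # --- population allele frequencies --------------------------------
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    pair = config.muscovy_pair
    p_shared = _balding_nichols(rng, p_anc, config.shared_branch_f)
    freqs = {}
    for pop in pops:
        base = p_shared if pop in pair else p_anc
        freqs[pop] = _balding_nichols(rng, base, config.drift_divergence[pop])

    # --- planted sweeps ------------------------------------------------
    scaffolds = variants["scaffold"].to_numpy()
    positions_all = variants["pos"].to_numpy()
    in_any_sweep = np.zeros(n_sites, dtype=bool)
    planted_sweeps = []
    for sw in config.sweep_specs:
        mask = ((scaffolds == sw.scaffold) & (positions_all >= sw.start)
                & (positions_all <= sw.end))
        in_any_sweep |= mask
        q = freqs[sw.focal_population][mask]
        target = np.where(q >= 0.5, 1.0, 0.0)
        freqs[sw.focal_population][mask] = q + sw.intensity * (target - q)
        planted_sweeps.append({
            "scaffold": sw.scaffold, "start": int(sw.start),
            "end": int(sw.end), "focal_population": sw.focal_population,
            "intensity": float(sw.intensity), "n_sites": int(mask.sum()),
        })

    # --- planted private alleles --------------------------------------
    candidates = np.flatnonzero(~in_any_sweep)
    n_private = int(round(config.private_allele_rate * n_sites))
    n_private = min(n_private, len(candidates))
    private_idx = np.sort(rng.choice(candidates, size=n_private,
                                     replace=False))
    owners = [pops[i % len(pops)] for i in range(n_private)]
    for j, site in enumerate(private_idx):
        for pop in pops:
            freqs[pop][site] = 0.0
        freqs[owners[j]][site] = rng.uniform(0.3, 0.8)

    # --- genotypes -----------------------------------------------------
    genotypes = np.empty((len(samples), n_sites), dtype=np.int8)
    row = 0
    for pop in pops:
        for _ in range(n_ind):
            genotypes[row] = rng.binomial(2, freqs[pop]).astype(np.int8)
            row += 1
    pop_rows = {p: [i for i, sp in enumerate(sample_pops) if sp == p]
                for p in pops}

    planted_private = []
    for j, site in enumerate(private_idx):
        owner = owners[j]
        owner_rows = pop_rows[owner]
        g = genotypes[owner_rows, site]
        carriers = int((g > 0).sum())
        if carriers < 2:  # force >= 2 carriers so the rule is recoverable
            for r in owner_rows[:2]:
                if genotypes[r, site] == 0:
                    genotypes[r, site] = 1
            carriers = int((genotypes[owner_rows, site] > 0).sum())
        planted_private.append({
            "scaffold": str(variants.at[site, "scaffold"]),
            "pos": int(variants.at[site, "pos"]),
            "site_index": int(site),
            "owner": owner,
            "n_carriers": carriers,
        })

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = -1

    # --- depths --------------------------------------------------------
    depths = rng.poisson(config.mean_depth,
                         size=genotypes.shape).astype(np.int32)
    n_out = int(round(config.depth_outlier_rate * n_sites))
    if n_out:
        out_sites = rng.choice(n_sites, size=n_out, replace=False)
        for k, site in enumerate(out_sites):
            if k % 2 == 0:  # ultra-high coverage site (total > 500)
                depths[:, site] = rng.poisson(
                    1_200.0 / len(samples), size=len(samples))
            else:  # ultra-low (total < 4)
                depths[:, site] = 0
                depths[rng.integers(0, len(samples)), site] = int(
                    rng.integers(0, 4))

    pair_str = f"({pair[0]},{pair[1]})"
    rest = ",".join(p for p in pops if p not in pair)
    tree = f"({pair_str},{rest});" if rest else f"{pair_str};"

    table = GenotypeTable(
        samples=samples, populations=sample_pops, variants=variants,
        genotypes=genotypes, depths=depths,
        scaffold_lengths={s: config.scaffold_length_bp
                          for s in config.scaffold_names},
    )
    truth = TruthRecord(planted_sweeps=planted_sweeps,
                        planted_private_sites=planted_private,
                        population_tree=tree)
    return table, truth


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(table: GenotypeTable, path) -> None:
    """Write the table as VCF 4.2 with GT:DP per sample."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popsweep-simulator\n")
        for scaf, length in table.scaffold_lengths.items():
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        gt = table.genotypes
        dp = table.depths
        for j, v in enumerate(table.variants.itertuples(index=False)):
            cells = []
            for i in range(table.n_samples):
                d = int(dp[i, j]) if dp is not None else "."
                cells.append(f"{_GT_STR[int(gt[i, j])]}:{d}")
            fh.write(f"{v.scaffold}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\t"
                     "GT:DP\t" + "\t".join(cells) + "\n")


def write_population_map(table: GenotypeTable, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(table.samples, table.populations):
            fh.write(f"{s}\t{p}\n")


def write_term_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_cohort(table: GenotypeTable, truth: TruthRecord,
                 gene_models: list[GeneModel], out_dir, *,
                 genome: dict[str, str] | None = None,
                 go_map: pd.DataFrame | None = None,
                 pathway_map: pd.DataFrame | None = None) -> dict[str, str]:
    """Write the full synthetic file set; returns a name->path map."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "gff3": os.path.join(out_dir, "genes.gff3"),
        "population_map": os.path.join(out_dir, "populations.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(table, paths["vcf"])
    write_gff3(gene_models, paths["gff3"])
    write_population_map(table, paths["population_map"])
    truth.to_json(paths["truth"])
    if genome is not None:
        paths["fasta"] = os.path.join(out_dir, "genome.fa")
        write_fasta(genome, paths["fasta"])
    if go_map is not None:
        paths["gene2go"] = os.path.join(out_dir, "gene2go.tsv")
        write_term_map(go_map, paths["gene2go"])
    if pathway_map is not None:
        paths["gene2pathway"] = os.path.join(out_dir, "gene2pathway.tsv")
        write_term_map(pathway_map, paths["gene2pathway"])
    return paths
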