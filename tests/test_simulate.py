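"""Synthetic-cohort generator: construction rules and drift statistics."""

import numpy as np
import pytest
from Bio.Seq import Seq

from popsweep.genotypes import allele_counts
from popsweep.simulate import (SimulationConfig, SweepSpec, simulate_cohort,
                               simulate_gene_models, simulate_genome,
                               write_vcf)
from popsweep.sweep import ScanConfig, scan_windows, window_hp


def test_same_seed_byte_identical_vcf(small_cfg, tmp_path):
    t1, _ = simulate_cohort(small_cfg)
    t2, _ = simulate_cohort(small_cfg)
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_vcf(t1, p1)
    write_vcf(t2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seed_differs(small_cfg, tmp_path):
    other = SimulationConfig(**{**small_cfg.__dict__, "seed": 99})
    t1, _ = simulate_cohort(small_cfg)
    t2, _ = simulate_cohort(other)
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    write_vcf(t1, p1)
    write_vcf(t2, p2)
    assert p1.read_bytes() != p2.read_bytes()


def test_full_intensity_sweep_fixes_focal_genotypes(small_cohort):
    """Intensity 1.0 forces every focal genotype in the interval to a
    homozygote, so windowed Hp over in-sweep SNPs is exactly 0."""
    table, truth = small_cohort
    sw = truth.planted_sweeps[0]
    jj = table.genotypes[table.sample_indices("JJ"), :]
    pos = table.variants["pos"].to_numpy()
    scaf = table.variants["scaffold"].to_numpy()
    in_sweep = ((scaf == sw["scaffold"]) & (pos >= sw["start"])
                & (pos <= sw["end"]))
    # private planted sites are excluded from sweep intervals by design
    assert (jj[:, in_sweep] != 1).all()
    counts = allele_counts(table)
    i = counts.pop_index("JJ")
    assert window_hp(counts.n_maj[i][in_sweep],
                     counts.n_min[i][in_sweep]) == 0.0


def test_zero_private_rate_gives_empty_truth_list():
    cfg = SimulationConfig(n_scaffolds=1, scaffold_length_bp=250_000,
                           n_variants_per_scaffold=200,
                           private_allele_rate=0.0, seed=3)
    _, truth = simulate_cohort(cfg)
    assert truth.planted_private_sites == []


def test_overlapping_sweeps_same_focal_rejected():
    with pytest.raises(ValueError, match="overlap"):
        SimulationConfig(
            n_scaffolds=1, scaffold_length_bp=250_000,
            n_variants_per_scaffold=100, seed=0,
            sweep_specs=[SweepSpec("scaffold_1", 1, 100_000, "JJ", 1.0),
                         SweepSpec("scaffold_1", 50_000, 150_000, "JJ", 0.5)])


def test_sweep_outside_scaffold_rejected():
    with pytest.raises(ValueError, match="outside scaffold"):
        SimulationConfig(
            n_scaffolds=1, scaffold_length_bp=250_000,
            n_variants_per_scaffold=100, seed=0,
            sweep_specs=[SweepSpec("scaffold_1", 200_000, 300_000, "JJ", 1.0)])


def test_gene_models_construction_rules(small_models, small_genome):
    """CDS length % 3 == 0, starts with ATG, ends with a stop, and the
    translated CDS has no internal stop codon."""
    assert len(small_models) > 1
    coding = [m for m in small_models if m.biotype == "protein_coding"]
    assert coding
    for m in coding:
        assert m.cds_length % 3 == 0
        cds = m.cds_sequence(small_genome[m.scaffold])
        assert cds.startswith("ATG")
        assert cds[-3:] in ("TAA", "TAG", "TGA")
        aa = str(Seq(cds).translate())
        assert aa.endswith("*") and "*" not in aa[:-1]


def test_genes_on_both_strands_and_nonoverlapping(small_models):
    strands = {m.strand for m in small_models}
    assert strands == {"+", "-"}
    by_scaf = {}
    for m in small_models:
        by_scaf.setdefault(m.scaffold, []).append((m.start, m.end))
    for spans in by_scaf.values():
        spans.sort()
        assert all(b[0] > a[1] for a, b in zip(spans, spans[1:]))


def test_vcf_positions_sorted_and_counted(written_cohort, small_cfg):
    lines = [l for l in open(written_cohort["vcf"]) if not l.startswith("#")]
    assert len(lines) == small_cfg.n_scaffolds * small_cfg.n_variants_per_scaffold
    last = {}
    for line in lines:
        scaf, pos = line.split("\t")[:2]
        assert int(pos) >= 1
        if scaf in last:
            assert int(pos) > last[scaf]
        last[scaf] = int(pos)


def test_no_drift_gives_near_zero_fst():
    """With F -> 0 on every branch and no sweeps, mean window Fst is 0
    within three standard errors (Hudson estimator is unbiased)."""
    cfg = SimulationConfig(n_scaffolds=1, scaffold_length_bp=1_000_000,
                           n_variants_per_scaffold=10_000,
                           populations=("P1", "P2"),
                           drift_divergence={"P1": 1e-7, "P2": 1e-7},
                           shared_branch_f=1e-7, private_allele_rate=0.0,
                           indel_rate=0.0, seed=7)
    table, _ = simulate_cohort(cfg)
    w = scan_windows(table, "P1", "P2", ScanConfig())
    fst = w["fst"].to_numpy()
    se = fst.std(ddof=1) / np.sqrt(len(fst))
    assert abs(fst.mean()) <= 3 * se


def test_heterozygosity_decreases_with_sweep_intensity():
    """Mean focal heterozygote fraction inside the sweep interval drops
    monotonically as intensity goes 0 -> 0.5 -> 1.0 (10 seeds)."""
    means = {}
    for intensity in (0.0, 0.5, 1.0):
        vals = []
        for seed in range(10):
            sweeps = ([] if intensity == 0 else
                      [SweepSpec("scaffold_1", 50_001, 200_000, "JJ",
                                 intensity)])
            cfg = SimulationConfig(
                n_scaffolds=1, scaffold_length_bp=250_000,
                n_variants_per_scaffold=1_500, indel_rate=0.0,
                private_allele_rate=0.0, seed=seed, sweep_specs=sweeps)
            table, _ = simulate_cohort(cfg)
            jj = table.genotypes[table.sample_indices("JJ"), :]
            pos = table.variants["pos"].to_numpy()
            m = (pos >= 50_001) & (pos <= 200_000)
            vals.append((jj[:, m] == 1).mean())
        means[intensity] = np.mean(vals)
    assert means[0.0] > means[0.5] > means[1.0]
    assert means[1.0] == 0.0


def test_muscovy_pair_frequencies_most_correlated():
    """The shared-branch pair's sample allele frequencies correlate more
    with each other than with the mallard-like population (>= 9/10 seeds)."""
    wins = 0
    for seed in range(10):
        cfg = SimulationConfig(n_scaffolds=2, scaffold_length_bp=250_000,
                               n_variants_per_scaffold=5_000, indel_rate=0.0,
                               private_allele_rate=0.0, seed=seed)
        table, _ = simulate_cohort(cfg)
        ac = allele_counts(table)
        f = {p: ac.alt_freq(p) for p in ("JJ", "FF", "YD")}
        r_pair = np.corrcoef(f["JJ"], f["FF"])[0, 1]
        r_out = np.corrcoef(f["JJ"], f["YD"])[0, 1]
        wins += r_pair > r_out
    assert wins >= 9


def test_genome_deterministic_and_fasta_matches_vcf_ref(small_cfg,
                                                        small_genome,
                                                        small_cohort):
    table, _ = small_cohort
    assert simulate_genome(small_cfg).keys() == small_genome.keys()
    for v in table.variants.itertuples(index=False):
        seq = small_genome[v.scaffold]
        assert seq[v.pos - 1:v.pos - 1 + len(v.ref)] == v.ref


def test_gene_model_determinism(small_cfg, small_models):
    again = simulate_gene_models(small_cfg)
    assert [m.gene_id for m in again] == [m.gene_id for m in small_models]
    assert [m.cds for m in again] == [m.cds for m in small_models]
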