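import numpy as np
import pandas as pd
import pytest

from popsweep.genotypes import GenotypeTable
from popsweep.simulate import (SimulationConfig, SweepSpec, simulate_cohort,
                               simulate_gene_models, simulate_genome,
                               simulate_term_maps, write_cohort)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """Compact two-scaffold cohort with one planted sweep and private sites."""
    return SimulationConfig(
        n_scaffolds=2,
        scaffold_length_bp=300_000,
        n_variants_per_scaffold=800,
        private_allele_rate=0.02,
        indel_rate=0.05,
        seed=11,
        sweep_specs=[SweepSpec("scaffold_1", 100_001, 200_000, "JJ", 1.0)],
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    table, truth = simulate_cohort(small_cfg)
    return table, truth


@pytest.fixture(scope="session")
def small_models(small_cfg):
    return simulate_gene_models(small_cfg)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def written_cohort(small_cfg, small_cohort, small_models, small_genome,
                   tmp_path_factory):
    table, truth = small_cohort
    go, pw = simulate_term_maps(small_cfg, small_models)
    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(table, truth, small_models, out,
                         genome=small_genome, go_map=go, pathway_map=pw)
    return paths


def make_table(genotypes, populations=None, depths=None, positions=None,
               scaffold="s1", scaffold_length=1_000_000, vclass="SNP"):
    """Hand-build a GenotypeTable from a genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    if populations is None:
        populations = ["P1"] * n_samples
    samples = [f"{p}_{i}" for i, p in enumerate(populations)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    variants = pd.DataFrame({
        "scaffold": [scaffold] * n_sites,
        "pos": positions,
        "ref": ["A"] * n_sites,
        "alt": ["G"] * n_sites,
        "vclass": [vclass] * n_sites,
    })
    d = None if depths is None else np.asarray(depths, dtype=np.int32)
    return GenotypeTable(samples=samples, populations=list(populations),
                         variants=variants, genotypes=g, depths=d,
                         scaffold_lengths={scaffold: scaffold_length})
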