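"""Pipeline configuration: one YAML file naming every stage parameter.

A bare default configuration reproduces the full analysis procedure on a
synthetic five-population cohort: depth bounds 4/500, MAF 0.1, 100 kb
windows stepping 50 kb over scaffolds > 150 kb, windows with > 20 SNPs,
joint top-5% outliers, 1 kb flanks, and >= 2 focal carriers for private
SNPs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .simulate import SimulationConfig, SweepSpec
from .sweep import ScanConfig


@dataclass
class FilterConfig:
    depth_low: int = 4
    depth_high: int = 500
    maf: float = 0.1


@dataclass
class SpecificConfig:
    focal: str = "JJ"
    min_individuals: int = 2
    strict_missing: bool = False


@dataclass
class EnrichConfig:
    alpha: float = 0.05
    on: str = "p_value"
    top: int = 20


@dataclass
class InputPaths:
    vcf: str
    population_map: str
    gff3: str | None = None
    fasta: str | None = None
    gene2go: str | None = None
    gene2pathway: str | None = None


@dataclass
class PipelineConfig:
    output_dir: str = "popsweep_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: InputPaths | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    annotation_flank: int = 1_000
    specific: SpecificConfig = field(default_factory=SpecificConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("JJ", "YD"), ("JJ", "BD")])
    enrichment: EnrichConfig = field(default_factory=EnrichConfig)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of 'simulate' and 'inputs' must be configured")

    def canonical_yaml(self) -> str:
        d = asdict(self)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (the output
        destination does not change the run's identity)."""
        d = asdict(self)
        d.pop("output_dir", None)
        return hashlib.sha256(
            yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()


def default_config(seed: int = 0, output_dir: str = "popsweep_out"
                   ) -> PipelineConfig:
    """Default synthetic run: five populations, one planted focal sweep."""
    sim = SimulationConfig(
        seed=seed,
        sweep_specs=[SweepSpec(scaffold="scaffold_1", start=400_001,
                               end=550_000, focal_population="JJ",
                               intensity=1.0)],
    )
    return PipelineConfig(output_dir=output_dir, seed=seed, simulate=sim)


def _pop(d: dict, key: str):
    return d.pop(key) if key in d else None


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    seed = raw.pop("seed", 0)
    sim_block = raw.pop("simulate", None)
    inputs_block = raw.pop("inputs", None)
    sim = None
    if sim_block is not None:
        sim_block = dict(sim_block)
        sweeps = [SweepSpec(**sw) for sw in sim_block.pop("sweep_specs", [])]
        if "populations" in sim_block:
            sim_block["populations"] = tuple(sim_block["populations"])
        sim = SimulationConfig(seed=sim_block.pop("seed", seed),
                               sweep_specs=sweeps, **sim_block)
    inputs = InputPaths(**inputs_block) if inputs_block is not None else None
    filters = FilterConfig(**raw.pop("filters", {}))
    specific = SpecificConfig(**raw.pop("specific", {}))
    scan = ScanConfig(**raw.pop("scan", {}))
    enrichment = EnrichConfig(**raw.pop("enrichment", {}))
    contrasts = [tuple(c) for c in raw.pop("contrasts",
                                           [("JJ", "YD"), ("JJ", "BD")])]
    return PipelineConfig(
        output_dir=raw.pop("output_dir", "popsweep_out"),
        seed=seed, simulate=sim, inputs=inputs, filters=filters,
        annotation_flank=raw.pop("annotation_flank", 1_000),
        specific=specific, scan=scan, contrasts=contrasts,
        enrichment=enrichment,
    )


def write_default_config(path, seed: int = 0) -> None:
    cfg = default_config(seed=seed)
    with open(path, "w") as fh:
        fh.write(cfg.canonical_yaml())
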