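"""Core in-memory containers for multi-population genotype data.

The pipeline's central object is the :class:`GenotypeTable`: an ordered
samples x variants matrix of alternate-allele dosages (0/1/2, with -1 for
missing calls) together with population labels, per-sample read depths and
scaffold lengths.  All filters and scans operate on this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: dosage code for a missing (uncalled) genotype
MISSING = -1

#: variant class labels
SNP = "SNP"
INDEL = "indel"


@dataclass
class GenotypeTable:
    """Samples x variants dosage matrix with population labels.

    Parameters
    ----------
    samples
        Ordered sample names.
    populations
        Population label for each sample (parallel to ``samples``).
    variants
        DataFrame with columns ``scaffold``, ``pos`` (1-based), ``ref``,
        ``alt``, ``vclass`` (``"SNP"`` or ``"indel"``), ordered as in the
        source VCF.
    genotypes
        int8 array of shape (n_samples, n_variants); 0/1/2 alternate-allele
        dosage, ``MISSING`` (-1) for uncalled.
    depths
        int32 array of per-sample read depth (DP), same shape as
        ``genotypes``; -1 where DP was absent.  May be ``None``.
    scaffold_lengths
        Mapping scaffold name -> length in bp.
    """

    samples: list[str]
    populations: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray | None
    scaffold_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.populations):
            raise ValueError("samples and populations must be parallel lists")
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.depths is not None and self.depths.shape != self.genotypes.shape:
            raise ValueError("depth matrix shape must match genotype matrix")
        for scaf in self.variants["scaffold"].unique():
            if scaf not in self.scaffold_lengths:
                raise ValueError(f"no length known for scaffold {scaf!r}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def population_names(self) -> list[str]:
        """Unique population labels in first-appearance order."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def sample_indices(self, population: str) -> np.ndarray:
        """Row indices of the samples belonging to *population*."""
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return np.flatnonzero(np.asarray(self.populations) == population)

    # ------------------------------------------------------------------
    def subset_variants(self, keep: np.ndarray) -> "GenotypeTable":
        """Return a new table restricted to variant indices/mask *keep*."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeTable(
            samples=list(self.samples),
            populations=list(self.populations),
            variants=self.variants.iloc[keep].reset_index(drop=True),
            genotypes=self.genotypes[:, keep],
            depths=None if self.depths is None else self.depths[:, keep],
            scaffold_lengths=dict(self.scaffold_lengths),
        )

    def snp_mask(self) -> np.ndarray:
        """Boolean mask over variants that are SNPs."""
        return (self.variants["vclass"] == SNP).to_numpy()


@dataclass
class SiteAlleleCounts:
    """Per-site, per-population allele counts among called chromosomes.

    ``ref``/``alt`` have shape (n_populations, n_sites).  The major allele
    within a population at a site is the more frequent of the two; ties are
    resolved in favour of the reference allele, so ``n_maj`` is reference-
    stable and deterministic.
    """

    populations: list[str]
    ref: np.ndarray
    alt: np.ndarray

    @property
    def called(self) -> np.ndarray:
        """Called chromosome count (nMAJ + nMIN) per population and site."""
        return self.ref + self.alt

    @property
    def n_maj(self) -> np.ndarray:
        return np.maximum(self.ref, self.alt)

    @property
    def n_min(self) -> np.ndarray:
        return np.minimum(self.ref, self.alt)

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"unknown population {population!r}") from None

    def alt_freq(self, population: str) -> np.ndarray:
        """Alternate-allele frequency per site; NaN where nothing called."""
        i = self.pop_index(population)
        called = self.called[i].astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called > 0, self.alt[i] / called, np.nan)


def allele_counts(table: GenotypeTable) -> SiteAlleleCounts:
    """Count reference and alternate alleles per population at every site.

    Missing genotypes contribute no chromosomes; a called diploid genotype
    contributes two.
    """
    pops = table.population_names
    n_sites = table.n_variants
    ref = np.zeros((len(pops), n_sites), dtype=np.int64)
    alt = np.zeros((len(pops), n_sites), dtype=np.int64)
    for i, pop in enumerate(pops):
        g = table.genotypes[table.sample_indices(pop), :]
        called = g != MISSING
        dosage = np.where(called, g, 0)
        alt[i] = dosage.sum(axis=0)
        ref[i] = 2 * called.sum(axis=0) - alt[i]
    return SiteAlleleCounts(populations=pops, ref=ref, alt=alt)
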