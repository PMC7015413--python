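"""Population-specific (private) SNP discovery.

A variant is specific to a focal population when at least
``min_individuals`` focal individuals carry the alternate allele (het or
hom both count — the rule is zygosity-agnostic) and no individual of any
other population carries it.  Missing genotypes outside the focal
population are not evidence of the allele; a strict mode additionally
requires every non-focal genotype to be a called homozygous reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable


def find_specific_snps(table: GenotypeTable, focal_population: str,
                       min_individuals: int = 2,
                       strict_missing: bool = False,
                       snps_only: bool = True) -> pd.DataFrame:
    """Return the focal population's private variants.

    Parameters
    ----------
    table
        Genotype table.
    focal_population
        Population whose private alleles are sought.
    min_individuals
        Minimum number of focal carriers (default 2 of 3).
    strict_missing
        When True, a missing genotype outside the focal population
        disqualifies the site; by default missing calls are treated as
        "allele not observed".
    snps_only
        Restrict to SNP records (the effect classes downstream are
        SNP-only).

    Returns a DataFrame with columns ``site_index``, ``scaffold``, ``pos``,
    ``ref``, ``alt``, ``n_carriers``, ``zygosity`` ("het", "hom" or
    "het+hom").
    """
    focal_rows = table.sample_indices(focal_population)  # KeyError if unknown
    if min_individuals > len(focal_rows):
        raise ValueError(
            f"min_individuals={min_individuals} exceeds the "
            f"{len(focal_rows)} individuals of {focal_population}"
        )
    other_rows = np.setdiff1d(np.arange(table.n_samples), focal_rows)
    g = table.genotypes
    focal = g[focal_rows, :]
    others = g[other_rows, :]

    carriers = (focal > 0).sum(axis=0)
    exclusive = ~(others > 0).any(axis=0)
    if strict_missing:
        exclusive &= ~(others == MISSING).any(axis=0)
    mask = (carriers >= min_individuals) & exclusive
    if snps_only:
        mask &= table.snp_mask()

    idx = np.flatnonzero(mask)
    het = (focal[:, idx] == 1).any(axis=0)
    hom = (focal[:, idx] == 2).any(axis=0)
    zyg = np.where(het & hom, "het+hom", np.where(hom, "hom", "het"))
    out = table.variants.iloc[idx][["scaffold", "pos", "ref", "alt"]].copy()
    out.insert(0, "site_index", idx)
    out["n_carriers"] = carriers[idx]
    out["zygosity"] = zyg
    return out.reset_index(drop=True)


def effect_breakdown(calls: pd.DataFrame, annotations: pd.DataFrame
                     ) -> dict:
    """Region-category and exonic-effect accounting of specific SNPs.

    ``annotations`` must be the table-aligned frame from
    :func:`popsweep.annotate.annotate_table`; every call's ``site_index``
    must be covered.

    Returns a dict with per-category counts, per-effect counts among
    exonic calls, and the exonic fraction of the total.
    """
    if len(calls) and calls["site_index"].max() >= len(annotations):
        raise ValueError("annotation frame does not cover all specific calls")
    ann = annotations.iloc[calls["site_index"]] if len(calls) else \
        annotations.iloc[[]]
    n_total = len(calls)
    by_category = ann["category"].value_counts().to_dict() if n_total else {}
    exonic = ann[ann["category"] == "exonic"] if n_total else ann
    n_exonic = len(exonic)
    by_effect = {e: 0 for e in ("synonymous", "nonsynonymous", "stopgain",
                                "stoploss")}
    if n_exonic:
        for e, n in exonic["effect"].value_counts().items():
            if e:
                by_effect[e] = int(n)
    return {
        "n_specific": int(n_total),
        "by_category": {k: int(v) for k, v in sorted(by_category.items())},
        "n_exonic": int(n_exonic),
        "exonic_fraction": (n_exonic / n_total) if n_total else 0.0,
        "by_effect": by_effect,
    }


def genes_with_specific_nonsynonymous(calls: pd.DataFrame,
                                      annotations: pd.DataFrame) -> list[str]:
    """Deduplicated genes carrying >= 1 specific strictly-nonsynonymous SNP.

    Stop-gain and stop-loss calls are reported separately by
    :func:`effect_breakdown` and do not qualify here.
    """
    if not len(calls):
        return []
    ann = annotations.iloc[calls["site_index"]]
    hit = ann[(ann["effect"] == "nonsynonymous") & (ann["gene"] != "")]
    return sorted(hit["gene"].unique())
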