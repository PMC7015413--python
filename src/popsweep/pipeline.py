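"""End-to-end orchestration of the analysis stages.

``run_all`` executes: simulate (optional) -> read/filter -> annotate ->
population-specific SNPs -> structure (NJ tree + PCA) -> sweep scans for
each configured contrast -> enrichment of sweep genes and of
specific-nonsynonymous genes, writing every stage output plus a run
manifest.  The run is a pure function of (inputs, config, seed): repeated
runs produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd

from . import __version__
from .annotate import annotate_table, summarize_regions
from .config import PipelineConfig
from .enrich import enrich, read_term_map, top_terms, write_enrichment_tsv
from .genes import PROTEIN_CODING, read_fasta, read_gff3
from .simulate import (simulate_cohort, simulate_gene_models, simulate_genome,
                       simulate_term_maps, write_cohort)
from .specific import (effect_breakdown, find_specific_snps,
                       genes_with_specific_nonsynonymous)
from .structure import ibs_distance, neighbor_joining, pca, write_newick
from .sweep import run_scan, write_regions_bed, write_windows_tsv
from .variants import (filter_depth, maf_filter, read_vcf,
                       write_filter_report)

log = logging.getLogger(__name__)


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    counts: dict = {}

    # ---- stage: simulate or load ------------------------------------
    if config.simulate is not None:
        sim_dir = os.path.join(out, "sim")
        table_mem, truth = simulate_cohort(config.simulate)
        models = simulate_gene_models(config.simulate)
        genome = simulate_genome(config.simulate)
        go_map, pw_map = simulate_term_maps(config.simulate, models)
        paths = write_cohort(table_mem, truth, models, sim_dir,
                             genome=genome, go_map=go_map,
                             pathway_map=pw_map)
        vcf_path, pop_path = paths["vcf"], paths["population_map"]
        table = read_vcf(vcf_path, pop_path)
    else:
        inp = config.inputs
        table = read_vcf(inp.vcf, inp.population_map)
        models = read_gff3(inp.gff3) if inp.gff3 else []
        genome = read_fasta(inp.fasta) if inp.fasta else None
        go_map = read_term_map(inp.gene2go) if inp.gene2go else None
        pw_map = read_term_map(inp.gene2pathway) if inp.gene2pathway else None
    counts["variants_read"] = table.n_variants
    counts["samples"] = table.n_samples

    # ---- stage: depth filter ----------------------------------------
    table, n_depth = filter_depth(table, config.filters.depth_low,
                                  config.filters.depth_high)
    counts["removed_by_depth"] = n_depth
    counts["variants_after_depth"] = table.n_variants
    write_filter_report(os.path.join(out, "filter_report.tsv"),
                        {"depth": n_depth})

    # ---- stage: annotation ------------------------------------------
    annotations = annotate_table(table, models, genome=genome,
                                 flank=config.annotation_flank)
    annotations.to_csv(os.path.join(out, "annotations.tsv"), sep="\t",
                       index=False)
    summary = summarize_regions(annotations)
    summary.to_csv(os.path.join(out, "region_summary.tsv"), sep="\t",
                   index=False, float_format="%.2f")

    # ---- stage: population-specific SNPs ----------------------------
    sp = config.specific
    calls = find_specific_snps(table, sp.focal,
                               min_individuals=sp.min_individuals,
                               strict_missing=sp.strict_missing)
    calls_out = calls.copy()
    ann_sel = annotations.iloc[calls["site_index"]] if len(calls) else None
    if ann_sel is not None:
        calls_out["category"] = ann_sel["category"].to_numpy()
        calls_out["effect"] = ann_sel["effect"].to_numpy()
    calls_out.to_csv(os.path.join(out, "specific_snps.tsv"), sep="\t",
                     index=False)
    breakdown = effect_breakdown(calls, annotations)
    _write_json(breakdown, os.path.join(out, "specific_summary.json"))
    specific_genes = genes_with_specific_nonsynonymous(calls, annotations)
    counts["specific_snps"] = len(calls)
    counts["specific_nonsyn_genes"] = len(specific_genes)

    # ---- stage: structure (MAF filter applies here) -----------------
    struct_table, n_maf = maf_filter(table, config.filters.maf)
    counts["removed_by_maf"] = n_maf
    dist = ibs_distance(struct_table)
    tree = neighbor_joining(dist)
    write_newick(tree, os.path.join(out, "nj_tree.nwk"))
    pc = pca(struct_table)
    pca_df = pd.DataFrame(
        pc.coordinates[:, :10],
        columns=[f"PC{i + 1}" for i in range(min(10, pc.coordinates.shape[1]))])
    pca_df.insert(0, "sample", pc.samples)
    pca_df.to_csv(os.path.join(out, "pca_coordinates.tsv"), sep="\t",
                  index=False, float_format="%.6f")
    _write_json(
        {"variance_explained_pct":
            [round(float(v), 4) for v in pc.variance_explained[:10]],
         "n_variants_used": pc.n_variants_used},
        os.path.join(out, "pca_summary.json"))
    counts["pca_variants"] = pc.n_variants_used

    # ---- stage: sweep scans -----------------------------------------
    background = sorted(m.gene_id for m in models
                        if m.biotype == PROTEIN_CODING)
    sweep_gene_lists: dict[str, list[str]] = {}
    for focal, contrast in config.contrasts:
        tag = f"{focal}_vs_{contrast}"
        windows, outliers, regions, genes = run_scan(
            table, focal, contrast, models, config.scan)
        write_windows_tsv(windows,
                          os.path.join(out, f"windows_{tag}.tsv"))
        write_regions_bed(regions,
                          os.path.join(out, f"regions_{tag}.bed"))
        with open(os.path.join(out, f"sweep_genes_{tag}.txt"), "w") as fh:
            fh.write("\n".join(genes) + ("\n" if genes else ""))
        sweep_gene_lists[tag] = genes
        counts[f"windows_retained_{tag}"] = len(windows)
        counts[f"outlier_windows_{tag}"] = len(outliers)
        counts[f"sweep_regions_{tag}"] = len(regions)
        counts[f"sweep_genes_{tag}"] = len(genes)

    # ---- stage: enrichment ------------------------------------------
    def _enrich_to(genes: list[str], term_map, label: str) -> None:
        if term_map is None or not len(term_map):
            return
        if not genes:
            log.warning("empty gene list for %s; enrichment skipped", label)
            counts[f"enrichment_{label}"] = 0
            return
        try:
            rows = enrich(genes, term_map, background)
        except ValueError as exc:
            log.warning("enrichment %s skipped: %s", label, exc)
            counts[f"enrichment_{label}"] = 0
            return
        write_enrichment_tsv(rows, os.path.join(out, f"enrich_{label}.tsv"))
        write_enrichment_tsv(
            top_terms(rows, config.enrichment.top),
            os.path.join(out, f"enrich_{label}_top.tsv"))
        counts[f"enrichment_{label}"] = len(rows)

    for tag, genes in sweep_gene_lists.items():
        _enrich_to(genes, go_map, f"go_{tag}")
        _enrich_to(genes, pw_map, f"pathway_{tag}")
    _enrich_to(specific_genes, go_map, "go_specific_nonsyn")
    _enrich_to(specific_genes, pw_map, "pathway_specific_nonsyn")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "counts": counts,
    }
    _write_json(manifest, os.path.join(out, "manifest.json"))
    return manifest
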