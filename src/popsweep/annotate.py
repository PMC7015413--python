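"""Genomic-region and coding-effect classification of variants.

Assigns each variant exactly one region category (exonic, splicing, UTR5,
UTR3, intronic, upstream, downstream, upstream;downstream, ncRNA_exonic,
ncRNA_intronic, intergenic) using an ANNOVAR-style precedence order, and
classifies SNPs inside CDS into synonymous / nonsynonymous / stop-gain /
stop-loss by codon substitution under the standard genetic code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .genes import NCRNA, PROTEIN_CODING, GeneModel
from .genotypes import GenotypeTable

log = logging.getLogger(__name__)

#: splice window: intronic positions within this many bp of a junction
SPLICE_WINDOW = 2
#: default upstream/downstream flank, bp from the transcript span
FLANK = 1_000

# precedence: lower rank wins; upstream and downstream share a rank and
# combine to "upstream;downstream" when both flanks are hit.  ncRNA
# categories rank just below their coding counterparts.
_PRECEDENCE = {
    "splicing": 0,
    "exonic": 1,
    "ncRNA_exonic": 2,
    "UTR5": 3,
    "UTR3": 4,
    "intronic": 5,
    "ncRNA_intronic": 6,
    "upstream": 7,
    "downstream": 7,
    "intergenic": 9,
}

CATEGORIES = [
    "exonic", "splicing", "UTR5", "UTR3", "intronic", "upstream",
    "downstream", "upstream;downstream", "ncRNA_exonic", "ncRNA_intronic",
    "intergenic",
]

EFFECTS = ["synonymous", "nonsynonymous", "stopgain", "stoploss"]


@dataclass
class RegionCall:
    scaffold: str
    pos: int
    category: str
    gene_id: str | None


@dataclass
class EffectCall:
    scaffold: str
    pos: int
    effect: str
    gene_id: str
    codon_change: str
    aa_change: str


class GeneIndex:
    """Per-scaffold interval index over transcript spans plus flanks."""

    def __init__(self, models: list[GeneModel], flank: int = FLANK):
        self.flank = flank
        self.by_scaffold: dict[str, IntervalTree] = {}
        self.models = {m.gene_id: m for m in models}
        for m in models:
            tree = self.by_scaffold.setdefault(m.scaffold, IntervalTree())
            # intervaltree is half-open; store [start-flank, end+flank]
            tree.addi(max(1, m.start - flank), m.end + flank + 1, m.gene_id)

    def query(self, scaffold: str, pos: int) -> list[GeneModel]:
        tree = self.by_scaffold.get(scaffold)
        if tree is None:
            return []
        hits = sorted(iv.data for iv in tree.at(pos))
        return [self.models[g] for g in hits]


def _near_junction(pos: int, model: GeneModel) -> bool:
    """True when *pos* is intronic and within SPLICE_WINDOW of a junction."""
    for (s1, e1), (s2, e2) in zip(model.exons, model.exons[1:]):
        if e1 < pos < s2:  # inside this intron
            return pos - e1 <= SPLICE_WINDOW or s2 - pos <= SPLICE_WINDOW
    return False


def _gene_category(pos: int, m: GeneModel, flank: int) -> str | None:
    """Category of *pos* relative to one gene, or None when out of range."""
    nc = m.biotype == NCRNA
    if m.start <= pos <= m.end:
        if m.in_any(pos, m.exons):
            if nc:
                return "ncRNA_exonic"
            if m.in_any(pos, m.cds):
                return "exonic"
            if m.in_any(pos, m.utr5):
                return "UTR5"
            if m.in_any(pos, m.utr3):
                return "UTR3"
            return "exonic"
        if _near_junction(pos, m):
            # canonical donor/acceptor window; ncRNA introns keep their
            # intronic label (the category set has no ncRNA_splicing)
            return "ncRNA_intronic" if nc else "splicing"
        return "ncRNA_intronic" if nc else "intronic"
    if m.end < pos <= m.end + flank:
        side_up = m.strand == "-"
    elif m.start - flank <= pos < m.start:
        side_up = m.strand == "+"
    else:
        return None
    return "upstream" if side_up else "downstream"


def classify_region(scaffold: str, pos: int, index: GeneIndex) -> RegionCall:
    """Assign the single highest-precedence category over nearby genes.

    Ties at equal precedence report the alphabetically first gene id.
    A variant within the flank of genes on both sides (one upstream, one
    downstream) is labelled ``upstream;downstream``.
    """
    if scaffold not in index.by_scaffold:
        log.warning("scaffold %s has no gene models; calling intergenic",
                    scaffold)
        return RegionCall(scaffold, pos, "intergenic", None)
    best: tuple[int, str, str] | None = None  # (rank, gene_id, category)
    flank_sides: dict[str, str] = {}
    for m in index.query(scaffold, pos):
        cat = _gene_category(pos, m, index.flank)
        if cat is None:
            continue
        if cat in ("upstream", "downstream"):
            flank_sides.setdefault(cat, m.gene_id)
        rank = _PRECEDENCE[cat]
        if best is None or (rank, m.gene_id) < (best[0], best[1]):
            best = (rank, m.gene_id, cat)
    if best is None:
        return RegionCall(scaffold, pos, "intergenic", None)
    rank, gene_id, cat = best
    if cat in ("upstream", "downstream") and len(flank_sides) == 2:
        gene_id = min(flank_sides.values())
        return RegionCall(scaffold, pos, "upstream;downstream", gene_id)
    return RegionCall(scaffold, pos, cat, gene_id)


def classify_effect(pos: int, ref: str, alt: str, model: GeneModel,
                    scaffold_seq: str) -> EffectCall:
    """Coding-effect call for a SNP inside the CDS of *model*.

    Builds the reference codon from the spliced CDS honouring strand and
    frame, substitutes the alternate base (reverse-complemented on the
    minus strand) and translates both codons with the standard genetic
    code.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("effect classification is defined for SNPs only")
    if model.biotype != PROTEIN_CODING:
        raise ValueError(f"{model.gene_id} is not protein-coding")
    if scaffold_seq[pos - 1] != ref:
        raise ValueError(
            f"reference base mismatch at {model.scaffold}:{pos}: "
            f"VCF says {ref!r}, sequence has {scaffold_seq[pos - 1]!r}"
        )
    offset = model.cds_offset(pos)  # raises if outside CDS
    cds = model.cds_sequence(scaffold_seq)
    codon_i = offset // 3
    within = offset % 3
    ref_codon = cds[codon_i * 3:codon_i * 3 + 3]
    sub = alt if model.strand == "+" else str(Seq(alt).complement())
    alt_codon = ref_codon[:within] + sub + ref_codon[within + 1:]

    stops = set(standard_dna_table.stop_codons)
    ref_stop, alt_stop = ref_codon in stops, alt_codon in stops
    aa_ref = "*" if ref_stop else str(Seq(ref_codon).translate())
    aa_alt = "*" if alt_stop else str(Seq(alt_codon).translate())
    if ref_stop and not alt_stop:
        effect = "stoploss"
    elif alt_stop and not ref_stop:
        effect = "stopgain"
    elif aa_ref == aa_alt:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return EffectCall(
        scaffold=model.scaffold, pos=pos, effect=effect,
        gene_id=model.gene_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{aa_ref}{codon_i + 1}{aa_alt}",
    )


def annotate_table(table: GenotypeTable, models: list[GeneModel],
                   genome: dict[str, str] | None = None,
                   flank: int = FLANK) -> pd.DataFrame:
    """Region (and, where possible, effect) calls for every variant.

    Returns a DataFrame aligned with ``table.variants``: columns
    ``category``, ``gene``, ``effect`` (empty string when not an exonic
    SNP or no genome sequence was supplied), ``codon_change``,
    ``aa_change``.
    """
    index = GeneIndex(models, flank=flank)
    cats, gene_ids, effects, codons, aas = [], [], [], [], []
    for v in table.variants.itertuples(index=False):
        call = classify_region(v.scaffold, v.pos, index)
        cats.append(call.category)
        gene_ids.append(call.gene_id or "")
        eff = codon = aa = ""
        if (call.category == "exonic" and v.vclass == "SNP"
                and genome is not None and call.gene_id):
            model = index.models[call.gene_id]
            if model.in_any(v.pos, model.cds):
                ec = classify_effect(v.pos, v.ref, v.alt, model,
                                     genome[v.scaffold])
                eff, codon, aa = ec.effect, ec.codon_change, ec.aa_change
        effects.append(eff)
        codons.append(codon)
        aas.append(aa)
    out = table.variants.copy()
    out["category"] = cats
    out["gene"] = gene_ids
    out["effect"] = effects
    out["codon_change"] = codons
    out["aa_change"] = aas
    return out


def summarize_regions(annotations: pd.DataFrame) -> pd.DataFrame:
    """Count and percentage per category, SNPs and indels separately.

    Percentages are computed against each variant class's total and sum
    to 100 (up to rounding) per class.
    """
    rows = []
    for vclass, sub in annotations.groupby("vclass", sort=True):
        total = len(sub)
        counts = sub["category"].value_counts()
        for cat in CATEGORIES:
            n = int(counts.get(cat, 0))
            rows.append((vclass, cat, n, 100.0 * n / total if total else 0.0))
    return pd.DataFrame(rows, columns=["vclass", "category", "count",
                                       "percent"])
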