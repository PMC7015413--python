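"""Gene models and GFF3/FASTA input-output.

A :class:`GeneModel` is a scaffold-anchored transcript: ordered exons,
CDS intervals (for protein-coding genes), UTRs and a strand.  Coordinates
are 1-based inclusive throughout, as in GFF3 and VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

Interval = tuple[int, int]

PROTEIN_CODING = "protein_coding"
NCRNA = "ncRNA"


def _sorted_disjoint(intervals: list[Interval]) -> bool:
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            return False
    return all(s <= e for s, e in intervals)


@dataclass
class GeneModel:
    """One transcript anchored on a scaffold.

    Invariants enforced on construction: exons sorted and non-overlapping;
    CDS contained in exons; CDS total length divisible by 3 for
    protein-coding genes.
    """

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    biotype: str = PROTEIN_CODING

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.utr5 = sorted(self.utr5)
        self.utr3 = sorted(self.utr3)
        if not _sorted_disjoint(self.exons):
            raise ValueError(f"{self.gene_id}: exons overlap or are malformed")
        for c in self.cds:
            if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                raise ValueError(f"{self.gene_id}: CDS {c} not within an exon")
        if self.biotype == PROTEIN_CODING and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_any(self, pos: int, intervals: list[Interval]) -> bool:
        return any(s <= pos <= e for s, e in intervals)

    def cds_sequence(self, scaffold_seq: str) -> str:
        """Spliced CDS on the coding strand (starts with the start codon)."""
        forward = "".join(scaffold_seq[s - 1:e] for s, e in self.cds)
        if self.strand == "-":
            return str(Seq(forward).reverse_complement())
        return forward

    def cds_offset(self, pos: int) -> int:
        """0-based offset of genomic *pos* within the coding-strand CDS."""
        if not self.in_any(pos, self.cds):
            raise ValueError(f"position {pos} is not in the CDS of {self.gene_id}")
        forward_off = 0
        for s, e in self.cds:
            if s <= pos <= e:
                forward_off += pos - s
                break
            forward_off += e - s + 1
        if self.strand == "-":
            return self.cds_length - 1 - forward_off
        return forward_off


# ----------------------------------------------------------------------
# GFF3
# ----------------------------------------------------------------------

def write_gff3(models: list[GeneModel], path) -> None:
    """Emit gene/mRNA(or ncRNA)/exon/CDS/UTR features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            tx_type = "mRNA" if m.biotype == PROTEIN_CODING else "ncRNA"
            gid, tid = m.gene_id, f"{m.gene_id}.t1"
            common = f"{m.scaffold}\tpopsweep\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(f"{common}gene\t{m.start}\t{m.end}{tail}.\t"
                     f"ID={gid};biotype={m.biotype}\n")
            fh.write(f"{common}{tx_type}\t{m.start}\t{m.end}{tail}.\t"
                     f"ID={tid};Parent={gid}\n")
            for s, e in m.exons:
                fh.write(f"{common}exon\t{s}\t{e}{tail}.\tParent={tid}\n")
            # CDS phase on the coding strand
            cds = m.cds if m.strand == "+" else list(reversed(m.cds))
            done = 0
            for s, e in cds:
                phase = (3 - done % 3) % 3
                fh.write(f"{common}CDS\t{s}\t{e}{tail}{phase}\tParent={tid}\n")
                done += e - s + 1
            for s, e in m.utr5:
                fh.write(f"{common}five_prime_UTR\t{s}\t{e}{tail}.\tParent={tid}\n")
            for s, e in m.utr3:
                fh.write(f"{common}three_prime_UTR\t{s}\t{e}{tail}.\tParent={tid}\n")


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (one transcript per gene expected)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        biotype = gene.attributes.get("biotype", [PROTEIN_CODING])[0]
        transcripts = list(db.children(gene, level=1))
        if not transcripts:
            continue
        tx = transcripts[0]
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        utr5 = [(f.start, f.end)
                for f in db.children(tx, featuretype="five_prime_UTR")]
        utr3 = [(f.start, f.end)
                for f in db.children(tx, featuretype="three_prime_UTR")]
        models.append(GeneModel(
            gene_id=gene.id, scaffold=gene.seqid, strand=gene.strand,
            start=gene.start, end=gene.end, exons=exons, cds=cds,
            utr5=utr5, utr3=utr3, biotype=biotype,
        ))
    return models


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
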