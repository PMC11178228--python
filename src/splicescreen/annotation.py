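"""Gene/intron annotation carriers and FASTA/GFF3 serialization.

Coordinates are genomic, 1-based and inclusive on both ends (the GFF3
convention), on the forward strand of the chromosome.  ``intron_index``
is the 1-based ordinal of the intron along the *transcript*, so for a
minus-strand gene intron 1 is the one with the largest genomic
coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IntronRecord",
    "GeneModel",
    "intron_id",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "donor_hexamer",
]


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    intron_index: int  # 1-based ordinal along the transcript
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"intron {self.gene_id}.{self.intron_index}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def id(self) -> str:
        return intron_id(self.gene_id, self.intron_index)


def intron_id(gene_id: str, intron_index: int) -> str:
    return f"{gene_id}.i{intron_index}"


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    introns: list[IntronRecord] = field(default_factory=list)

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_SOURCE = "splicescreen"


def _gff_line(chrom: str, ftype: str, start: int, end: int, strand: str, attrs: str) -> str:
    return f"{chrom}\t{_SOURCE}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene, exon and explicit ``intron`` features, 1-based inclusive."""
    buf = io.StringIO()
    buf.write("##gff-version 3\n")
    for g in genes:
        buf.write(_gff_line(g.chrom, "gene", g.start, g.end, g.strand, f"ID={g.gene_id}") + "\n")
        for k, (s, e) in enumerate(g.exons, start=1):
            attrs = f"ID={g.gene_id}.e{k};Parent={g.gene_id}"
            buf.write(_gff_line(g.chrom, "exon", s, e, g.strand, attrs) + "\n")
        for intr in g.introns:
            attrs = f"ID={intr.id};Parent={g.gene_id};intron_index={intr.intron_index}"
            buf.write(_gff_line(g.chrom, "intron", intr.start, intr.end, g.strand, attrs) + "\n")
    Path(path).write_text(buf.getvalue())


def _parse_attrs(field9: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in field9.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gff3` (or any GFF3 that
    carries gene/exon/intron features with ID/Parent attributes)."""
    genes: dict[str, GeneModel] = {}
    pending_exons: dict[str, list[tuple[int, int]]] = {}
    pending_introns: dict[str, list[tuple[int, int, int, str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields[:9]
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a["ID"]
                genes[gid] = GeneModel(gid, chrom, int(start), int(end), strand)
            elif ftype == "exon":
                pending_exons.setdefault(a["Parent"], []).append((int(start), int(end)))
            elif ftype == "intron":
                idx = int(a.get("intron_index", len(pending_introns.get(a["Parent"], [])) + 1))
                pending_introns.setdefault(a["Parent"], []).append(
                    (idx, int(start), int(end), chrom, strand)
                )
    for gid, g in genes.items():
        g.exons = sorted(pending_exons.get(gid, []))
        g.introns = sorted(
            (
                IntronRecord(gid, idx, chrom, s, e, strand)
                for idx, s, e, chrom, strand in pending_introns.get(gid, [])
            ),
            key=lambda i: i.intron_index,
        )
    return list(genes.values())


def donor_hexamer(intron: IntronRecord, genome: Mapping[str, str]) -> str:
    """First six intronic nucleotides on the annotated strand (the 5'SS)."""
    seq = genome[intron.chrom]
    if intron.strand == "+":
        return seq[intron.start - 1 : intron.start + 5]
    return str(Seq(seq[intron.end - 6 : intron.end]).reverse_complement())
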