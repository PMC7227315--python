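"""FASTA and GFF3 input/output.

Coordinates are 0-based half-open everywhere inside the package; GFF3 is
read and written in its native 1-based inclusive convention and converted
at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneModel:
    """A gene's placement and exon structure.

    ``start``/``end`` and exon intervals are 0-based half-open. ``exons``
    are sorted, non-overlapping and contained in ``[start, end)``.
    """

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    subgenome: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.id}: invalid span [{self.start}, {self.end})")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.id}: exon ({s}, {e}) outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.id}: overlapping or unsorted exons")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return max(len(self.exons) - 1, 0)

    @property
    def intronless(self) -> bool:
        return len(self.exons) == 1

    @property
    def tss(self) -> int:
        """Transcription start site, 0-based: leftmost base on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end - 1


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def subgenome_of(chromosome: str) -> str | None:
    """Parse an allotetraploid chromosome name to its subgenome tag.

    ``A05``/``chrA05``/``Ghir_A05`` style names map to ``"A"``/``"D"``;
    scaffolds and other names return None (unplaced).
    """
    name = chromosome
    for prefix in ("chr", "Chr", "Ghir_"):
        if name.startswith(prefix):
            name = name[len(prefix):]
    if len(name) >= 2 and name[0] in "AD" and name[1:].isdigit():
        return name[0]
    return None


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon) from a GFF3 file.

    One mRNA per gene is assumed; extra transcripts raise. Exons are taken
    from the mRNA's children and converted to 0-based half-open.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) > 1:
            raise ValueError(f"gene {gene.id}: multiple mRNAs not supported")
        parent = mrnas[0] if mrnas else gene
        exons = [(e.start - 1, e.end) for e in db.children(parent, featuretype="exon", order_by="start")]
        sub = gene.attributes.get("subgenome", [None])[0] or subgenome_of(gene.seqid)
        models.append(
            GeneModel(
                id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                start=gene.start - 1,
                end=gene.end,
                exons=exons,
                subgenome=sub,
            )
        )
    return models


def write_gff3(models: list[GeneModel], path: str | os.PathLike, source: str = "kinfam") -> None:
    """Write gene models as gene/mRNA/exon features, 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            attrs = f"ID={g.id}"
            if g.subgenome:
                attrs += f";subgenome={g.subgenome}"
            row = [g.chromosome, source, "gene", str(g.start + 1), str(g.end), ".", g.strand, "."]
            fh.write("\t".join(row + [attrs]) + "\n")
            tid = f"{g.id}.t1"
            row[2] = "mRNA"
            fh.write("\t".join(row + [f"ID={tid};Parent={g.id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                erow = [g.chromosome, source, "exon", str(s + 1), str(e), ".", g.strand, ".",
                        f"ID={g.id}.e{i};Parent={tid}"]
                fh.write("\t".join(erow) + "\n")


_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]
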