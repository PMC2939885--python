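"""File I/O: FASTA, FASTQ, GFF3 and SAM.

FASTA/FASTQ go through Biopython's SeqIO; SAM through pysam.  The GFF3
dialect written here is 1-based inclusive with ``ID=`` attributes, one
``gene`` feature per gene and one ``CDS``/``exon`` row per part carrying
``exon_number`` (the splice rank) and ``part_strand`` for trans-spliced
parts whose strand differs from the gene's.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import AnnotatedGenome, ExonPart, GeneModel


@dataclass
class FastqRead:
    name: str
    seq: str
    qual: str  # Phred+33

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def quals(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


def write_fasta(path: str, records: Iterable[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=name, description="") for name, s in records),
        path,
        "fasta",
    )


def read_fasta(path: str) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_fastq(path: str, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(path, "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return out


_FEATURE_BY_KIND = {"protein": "CDS", "tRNA": "exon", "rRNA": "exon"}


def write_gff3(path: str, genome: AnnotatedGenome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome.seq)}\n")
        for g in genome.genes:
            a, b = g.span
            attrs = f"ID=gene-{g.name};Name={g.name};gene_kind={g.kind}"
            if g.pseudo:
                attrs += ";pseudo=true"
            fh.write(
                "\t".join(
                    [genome.name, "plastidkit", "gene", str(a + 1), str(b),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )
            ftype = _FEATURE_BY_KIND.get(g.kind, "exon")
            for p in g.ordered_parts():
                pattrs = (
                    f"ID={ftype.lower()}-{g.name}-{p.rank};Parent=gene-{g.name};"
                    f"exon_number={p.rank}"
                )
                if p.strand != g.strand:
                    pattrs += f";part_strand={p.strand}"
                fh.write(
                    "\t".join(
                        [genome.name, "plastidkit", ftype, str(p.start + 1),
                         str(p.end), ".", p.strand, "0" if ftype == "CDS" else ".",
                         pattrs]
                    )
                    + "\n"
                )


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for field in s.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene models from the dialect written by :func:`write_gff3`
    (also accepts plain gene/CDS/exon rows with ID/Parent attributes)."""
    genes: dict[str, GeneModel] = {}
    parts: dict[str, list[ExonPart]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            _, _, ftype, start, end, _, strand, _, attr_s = cols[:9]
            attrs = _parse_attrs(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID", attrs.get("Name", "gene"))
                name = attrs.get("Name", gid.removeprefix("gene-"))
                genes[gid] = GeneModel(
                    name=name,
                    parts=[],
                    strand=strand,
                    kind=attrs.get("gene_kind", "protein"),
                    pseudo=attrs.get("pseudo", "false") == "true",
                )
            elif ftype in ("CDS", "exon"):
                parent = attrs.get("Parent")
                if parent is None:
                    continue
                rank = int(attrs.get("exon_number", len(parts.get(parent, [])) + 1))
                pstrand = attrs.get("part_strand", strand)
                parts.setdefault(parent, []).append(
                    ExonPart(int(start) - 1, int(end), pstrand, rank)
                )
    out = []
    for gid, g in genes.items():
        g.parts = sorted(parts.get(gid, []), key=lambda p: p.rank)
        if g.parts:
            out.append(g)
    return out


def write_tsv(path: str, rows: Iterable[dict], columns: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
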