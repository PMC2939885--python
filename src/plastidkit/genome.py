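"""Annotated circular genome container and gene models.

The central in-memory object is :class:`AnnotatedGenome`: a circular DNA
sequence plus gene models (exons with rank and per-part strand, so
trans-spliced genes are representable), operon definitions, and — when the
genome was simulated — a ``truth`` dictionary recording every planted
feature for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from ._seq import revcomp


@dataclass(frozen=True)
class ExonPart:
    """One exon of a gene model.  ``start``/``end`` are 0-based half-open on
    the genome; ``strand`` is the strand of this part (trans-spliced genes
    may mix strands); ``rank`` orders parts along the mature transcript."""

    start: int
    end: int
    strand: str = "+"
    rank: int = 1

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty exon [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    name: str
    parts: list[ExonPart]
    strand: str = "+"
    kind: str = "protein"  # protein | tRNA | rRNA
    pseudo: bool = False

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint (0-based half-open) covering all parts."""
        return (min(p.start for p in self.parts), max(p.end for p in self.parts))

    @property
    def exonic_length(self) -> int:
        return sum(p.length for p in self.parts)

    def ordered_parts(self) -> list[ExonPart]:
        return sorted(self.parts, key=lambda p: p.rank)

    def exon_intervals(self) -> list[tuple[int, int]]:
        return [(p.start, p.end) for p in self.parts]

    def contains(self, pos0: int) -> bool:
        """True if 0-based position lies inside an exon."""
        return any(p.start <= pos0 < p.end for p in self.parts)

    def in_span(self, pos0: int) -> bool:
        a, b = self.span
        return a <= pos0 < b


@dataclass
class Operon:
    """Co-transcribed gene block: ordered gene names on one strand."""

    genes: list[str]
    strand: str = "+"


@dataclass(frozen=True)
class RegionLayout:
    """Quadripartite coordinates, 0-based half-open, in genome order
    LSC → IRb → SSC → IRa (the conventional linearisation with the origin
    at the IRa/LSC junction)."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def lsc_len(self) -> int:
        return self.lsc[1] - self.lsc[0]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1] - self.ssc[0]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    # Junction positions, 1-based: the position of the LAST base of the
    # upstream region at each boundary.
    @property
    def jlb(self) -> int:
        return self.lsc[1]

    @property
    def jsb(self) -> int:
        return self.irb[1]

    @property
    def jsa(self) -> int:
        return self.ssc[1]

    @property
    def jla(self) -> int:
        return self.ira[1]


@dataclass
class AnnotatedGenome:
    """Circular genome sequence with annotation.

    ``truth`` (present on simulated genomes) maps feature class to the
    planted records, e.g. ``truth["homopolymers"]`` is a list of
    ``(base, start0, length)`` tuples.
    """

    seq: str
    genes: list[GeneModel] = field(default_factory=list)
    operons: list[Operon] = field(default_factory=list)
    layout: Optional[RegionLayout] = None
    circular: bool = True
    name: str = "genome"
    truth: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)

    def gene(self, name: str) -> GeneModel:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def check_layout(self) -> None:
        """Assert the layout invariants: regions tile the genome and the two
        IR copies are exact reverse complements."""
        lay = self.layout
        if lay is None:
            return
        if lay.total != len(self.seq):
            raise ValueError(
                f"region lengths sum to {lay.total}, genome is {len(self.seq)} bp"
            )
        ira = self.seq[lay.ira[0] : lay.ira[1]]
        irb = self.seq[lay.irb[0] : lay.irb[1]]
        if ira != revcomp(irb):
            raise ValueError("IRa is not the reverse complement of IRb")


def genes_overlapping(genes: Iterable[GeneModel], start0: int, end0: int) -> list[GeneModel]:
    """Genes whose span intersects [start0, end0)."""
    out = []
    for g in genes:
        a, b = g.span
        if a < end0 and start0 < b:
            out.append(g)
    return out
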