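"""Codon usage statistics for plastid protein-coding genes.

Splices coding sequences out of an annotated genome (handling introns,
minus-strand genes, and trans-spliced genes whose parts sit on both
strands), counts codons under the plastid/bacterial genetic code
(translation table 11), and derives the classical summaries: RSCU
(relative synonymous codon usage), amino-acid composition, positional
A+T content, and a start-codon audit.

Conventions
-----------
* The internal alphabet is DNA (T); report helpers render codons with U.
* Stop codons are counted and included in the denominator of amino-acid
  percentages; their RSCU is reported as 0 by convention.
* RSCU for a codon c of amino acid a with synonymous family size k is
  ``n_c * k / sum(n_c' for c' in family)``; Leu/Ser/Arg are 6-fold
  families, Met and Trp are 1-fold (RSCU identically 1 when present).
* Printed values use round-half-up (2 decimals for RSCU, 1-2 for
  percentages) to match the usual presentation in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from Bio.Data import CodonTable as _BioCodonTable

from ._seq import revcomp
from .genome import ExonPart, GeneModel

_CODE11 = _BioCodonTable.unambiguous_dna_by_id[11]

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

ALL_CODONS = tuple(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)
STOP_CODONS = tuple(_CODE11.stop_codons)

# synonymous families: one-letter aa -> tuple of sense codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _CODE11.forward_table.items():
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (1.285 -> 1.29), matching printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon under table 11 ('*' = stop)."""
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        return "*"
    return _CODE11.forward_table[codon]


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass
class CdsRecord:
    """A spliced coding sequence.

    ``parts`` keeps the exon intervals in splice-rank order (genomic order
    and rank order differ for trans-spliced genes).  ``upstream_seq`` is
    sequence 5' of the annotated start in coding orientation, captured at
    extraction for the start-codon audit.  ``frame_ok`` is False when the
    spliced length is not divisible by 3 (flagged, never dropped).
    """

    gene: str
    spliced_sequence: str
    strand: str
    parts: list[ExonPart] = field(default_factory=list)
    upstream_seq: str = ""
    frame_ok: bool = True

    def __len__(self) -> int:
        return len(self.spliced_sequence)

    def codons(self) -> list[str]:
        s = self.spliced_sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


@dataclass
class CodonTable:
    """Codon counts over all 64 codons (DNA alphabet internally)."""

    counts: dict[str, int]
    code_id: int = 11
    ambiguous: int = 0  # codons skipped for holding N etc.

    def __post_init__(self):
        norm = {c: 0 for c in ALL_CODONS}
        for codon, n in self.counts.items():
            norm[to_dna(codon)] = int(n)
        self.counts = norm

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts[to_dna(codon)]


def extract_cds(
    genome_seq: str,
    annotation: Iterable[GeneModel],
    upstream: int = 60,
    include_pseudo: bool = False,
) -> list[CdsRecord]:
    """Splice coding sequences from gene models.

    Exons are concatenated in splice-rank order, each part reverse
    complemented when it lies on the minus strand, so trans-spliced genes
    mixing strands come out correctly.  Pseudogenes are excluded unless
    ``include_pseudo``.  Records whose length is not divisible by 3 are
    flagged via ``frame_ok=False``.
    """
    n = len(genome_seq)
    out = []
    for gene in annotation:
        if gene.pseudo and not include_pseudo:
            continue
        if gene.kind != "protein":
            continue
        pieces = []
        for part in gene.ordered_parts():
            if part.start < 0 or part.end > n:
                raise ValueError(
                    f"exon of gene {gene.name!r} outside genome bounds: "
                    f"[{part.start + 1}, {part.end}] vs length {n}"
                )
            piece = genome_seq[part.start : part.end]
            if part.strand == "-":
                piece = revcomp(piece)
            pieces.append(piece)
        spliced = "".join(pieces)
        first = gene.ordered_parts()[0]
        if first.strand == "+":
            lo = max(0, first.start - upstream)
            up = genome_seq[lo : first.start]
        else:
            hi = min(n, first.end + upstream)
            up = revcomp(genome_seq[first.end : hi])
        out.append(
            CdsRecord(
                gene=gene.name,
                spliced_sequence=spliced,
                strand=gene.strand,
                parts=gene.ordered_parts(),
                upstream_seq=up,
                frame_ok=len(spliced) % 3 == 0,
            )
        )
    return out


def count_codons(cds_list: Iterable[CdsRecord]) -> CodonTable:
    """Count codons (stops included) over all records.  Codons holding
    ambiguity characters are skipped and tallied in ``ambiguous``."""
    counts: dict[str, int] = {}
    ambiguous = 0
    for rec in cds_list:
        for codon in rec.codons():
            codon = to_dna(codon)
            if set(codon) <= set("ACGT"):
                counts[codon] = counts.get(codon, 0) + 1
            else:
                ambiguous += 1
    return CodonTable(counts=counts, ambiguous=ambiguous)


def rscu(table: CodonTable) -> dict[str, float]:
    """RSCU per codon (DNA keys).  Stop codons are 0 by convention; a
    family with zero total yields 0 for all its members."""
    if table.total <= 0:
        raise ValueError("empty codon table")
    out: dict[str, float] = {}
    for aa, family in FAMILIES.items():
        fam_total = sum(table.counts[c] for c in family)
        k = len(family)
        for c in family:
            out[c] = table.counts[c] * k / fam_total if fam_total else 0.0
    for c in STOP_CODONS:
        out[c] = 0.0
    return out


def aa_composition(table: CodonTable) -> dict[str, tuple[int, float]]:
    """Per amino acid (3-letter name, 'Ter' for stops): (count, percent of
    all codons, stops included in the denominator)."""
    if table.total <= 0:
        raise ValueError("empty codon table")
    agg: dict[str, int] = {}
    for codon, n in table.counts.items():
        name = AA3[translate_codon(codon)]
        agg[name] = agg.get(name, 0) + n
    total = table.total
    return {aa: (n, 100.0 * n / total) for aa, n in agg.items()}


def positional_base_composition(table: CodonTable) -> tuple[float, float, float]:
    """A+T percentage at codon positions 1..3, weighted by codon counts."""
    total = table.total
    if total <= 0:
        raise ValueError("empty codon table")
    out = []
    for p in range(3):
        at = sum(n for codon, n in table.counts.items() if codon[p] in "AT")
        out.append(100.0 * at / total)
    return tuple(out)


@dataclass
class StartAudit:
    gene: str
    start_codon: str
    canonical: bool
    upstream_stop_offset: Optional[int] = None  # bp between stop and start
    notes: list[str] = field(default_factory=list)


def audit_start_codons(
    cds_list: Iterable[CdsRecord],
    upstream_window: int = 30,
    hp_min_len: int = 8,
) -> list[StartAudit]:
    """Report every CDS's first codon and flag non-canonical starts.

    The upstream sequence (in coding orientation) is scanned for in-frame
    stop codons within ``upstream_window`` bp of the start; a nearby stop
    combined with a long A/T homopolymer run around the start is the
    classic signature of an ambiguous start call in AT-rich plastid
    genomes, and both are reported as notes.
    """
    out = []
    for rec in cds_list:
        start = rec.spliced_sequence[:3]
        audit = StartAudit(
            gene=rec.gene, start_codon=to_rna(start), canonical=start == "ATG"
        )
        up = rec.upstream_seq
        # walk upstream in frame: codon ends at offsets 3, 6, ... before start
        off = 3
        while off <= min(len(up), upstream_window):
            codon = up[len(up) - off : len(up) - off + 3]
            if codon in STOP_CODONS:
                audit.upstream_stop_offset = off
                audit.notes.append(
                    f"in-frame stop {to_rna(codon)} {off} bp upstream of start"
                )
                break
            off += 3
        neighborhood = up[-upstream_window:] + rec.spliced_sequence[:upstream_window]
        for base in "AT":
            run = base * hp_min_len
            if run in neighborhood:
                audit.notes.append(
                    f"homopolymer run of {base} (>= {hp_min_len} bp) near start;"
                    " possible pyrosequencing frame ambiguity"
                )
                break
        if not audit.canonical:
            audit.notes.append(f"non-canonical start codon {to_rna(start)}")
        if audit.upstream_stop_offset is not None and audit.notes:
            if any("homopolymer" in n for n in audit.notes):
                audit.notes.append("start codon assignment ambiguous")
        out.append(audit)
    return out


def usage_report(table: CodonTable) -> "pd.DataFrame":
    """Tidy per-codon report (RNA codons, amino acid, count, RSCU rounded
    to 2 dp) in the conventional published layout."""
    import pandas as pd

    vals = rscu(table)
    rows = []
    for codon in ALL_CODONS:
        rows.append(
            {
                "amino_acid": AA3[translate_codon(codon)],
                "codon": to_rna(codon),
                "count": table.counts[codon],
                "rscu": round_half_up(vals[codon], 2),
            }
        )
    return pd.DataFrame(rows)
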