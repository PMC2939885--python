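"""Intravarietal (heteroplasmic) SNP and indel calling from read pileups.

A plant cell carries hundreds to thousands of plastid genome copies, so
deep read alignments expose loci where two genotypes coexist: a major and
a minor allele whose read fractions reflect the within-cell population.
The caller applies four conservative filters designed for pyrosequencing
data: (1) quality-weighted depth at the locus must exceed ``min_depth``
(strict), (2) the largest minor genotype must exceed ``min_minor_pct``
percent (strict), (3) reads bearing an alignment gap at the locus are
removed before the depth test (a gap is more likely a one-base indel
artifact), and (4) loci overlapping homopolymer runs are excluded
outright, since run-length miscalls pile up spurious minor alleles at run
edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import complement_base
from .align import Alignment
from .assemble import HomopolymerRun
from .codonstats import CdsRecord, round_half_up, translate_codon, AA3
from .genome import GeneModel

_BASES = "ACGT"
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _BASE_CODE[ord(_b)] = _i


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------


@dataclass
class PileupColumn:
    position: int  # 1-based
    base_counts: dict[str, int]
    gap_reads: int

    @property
    def depth_q(self) -> int:
        return sum(self.base_counts.values())


class Pileup:
    """Per-locus base/quality/gap tallies over a circular genome.

    ``counts`` is an (n, 4) matrix of quality-passing base observations;
    ``gap`` counts reads whose alignment has a deletion at the locus;
    ``insertions`` maps a 0-based anchor position to the observed inserted
    strings (between anchor and anchor+1) with their read counts;
    ``junction_cov`` counts reads spanning each inter-base junction.
    """

    def __init__(self, n: int):
        self.n = n
        self.counts = np.zeros((n, 4), dtype=np.int32)
        self.gap = np.zeros(n, dtype=np.int32)
        self.junction_cov = np.zeros(n, dtype=np.int32)
        self.insertions: dict[int, dict[str, int]] = {}

    def column(self, position: int) -> PileupColumn:
        i = position - 1
        return PileupColumn(
            position=position,
            base_counts={
                b: int(self.counts[i, k]) for k, b in enumerate(_BASES)
                if self.counts[i, k]
            },
            gap_reads=int(self.gap[i]),
        )

    def __iter__(self):
        for i in range(self.n):
            yield self.column(i + 1)


def build_pileup(
    alignments: Iterable[Alignment],
    genome: str,
    min_qual: int = 20,
) -> Pileup:
    """Accumulate a pileup from alignments.  Bases with Phred <= ``min_qual``
    are excluded from base counts (quality strictly greater than the
    threshold is required); alignment positions wrap the circular origin.
    Raises if a non-wrapped alignment runs past the genome end."""
    n = len(genome)
    pile = Pileup(n)
    for aln in alignments:
        if aln.ref_start >= n:
            raise ValueError(
                f"alignment of {aln.query_name!r} starts past genome end"
            )
        rpos = aln.ref_start
        qpos = 0
        seq_codes = _BASE_CODE[np.frombuffer(aln.seq.encode(), dtype=np.uint8)]
        quals = np.asarray(aln.quals, dtype=np.int16)
        for op, length in aln.cigar:
            if op in "=XM":
                pos = np.arange(rpos, rpos + length) % n
                codes = seq_codes[qpos : qpos + length]
                ok = (quals[qpos : qpos + length] > min_qual) & (codes >= 0)
                np.add.at(pile.counts, (pos[ok], codes[ok]), 1)
                rpos += length
                qpos += length
            elif op == "D":
                pos = np.arange(rpos, rpos + length) % n
                np.add.at(pile.gap, pos, 1)
                rpos += length
            elif op == "I":
                anchor = (rpos - 1) % n
                ins = aln.seq[qpos : qpos + length]
                if all(q > min_qual for q in aln.quals[qpos : qpos + length]):
                    slot = pile.insertions.setdefault(anchor, {})
                    slot[ins] = slot.get(ins, 0) + 1
                qpos += length
        span = rpos - aln.ref_start
        if span > 1:
            jpos = np.arange(aln.ref_start, aln.ref_start + span - 1) % n
            np.add.at(pile.junction_cov, jpos, 1)
    return pile


# ---------------------------------------------------------------------------
# SNP calls
# ---------------------------------------------------------------------------


@dataclass
class CdsContext:
    gene: str
    strand: str
    cds_pos: int  # 1-based position in the spliced CDS, coding orientation
    major_codon: str  # affected position uppercase, rest lowercase
    minor_codon: str
    major_aa: str
    minor_aa: str
    effect: str  # synonymous | nonsynonymous | nonsense


@dataclass
class SnpCall:
    position: int  # 1-based genome coordinate
    major: str
    minor: str
    major_n: int
    minor_n: int
    major_pct: float
    minor_pct: float
    mutation_class: str = ""  # transition | transversion
    context_kind: str = ""  # intergenic | intron | CDS
    contexts: list[CdsContext] = field(default_factory=list)
    ambiguous: bool = False  # tied top counts
    notes: list[str] = field(default_factory=list)


def homopolymer_mask(
    runs: Sequence[HomopolymerRun], n: int, flank: int = 1
) -> np.ndarray:
    """Boolean mask over the genome marking homopolymer runs +/- ``flank``."""
    mask = np.zeros(n, dtype=bool)
    for r in runs:
        a = max(0, r.start - 1 - flank)
        b = min(n, r.end + flank)
        mask[a:b] = True
    return mask


def call_intrasnps(
    pileup: Pileup,
    min_depth: int = 50,
    min_minor_pct: float = 10.0,
    hp_mask: Sequence[HomopolymerRun] | np.ndarray = (),
    mask_flank: int = 1,
) -> list[SnpCall]:
    """Emit heteroplasmic SNP calls passing the four filters.

    Depth after gap-read removal must be strictly above ``min_depth``; at
    least two bases must be observed; the largest minor genotype must be
    strictly above ``min_minor_pct`` percent of qualifying reads; and the
    locus must not overlap the homopolymer mask.  Percentages are computed
    over the two reported genotypes only.
    """
    counts = pileup.counts
    depth = counts.sum(axis=1)
    if isinstance(hp_mask, np.ndarray):
        mask = hp_mask
    else:
        mask = homopolymer_mask(hp_mask, pileup.n, flank=mask_flank)
    candidates = np.flatnonzero(
        (depth > min_depth) & ((counts > 0).sum(axis=1) >= 2) & ~mask
    )
    calls = []
    for i in candidates:
        row = counts[i]
        order = np.argsort(-row, kind="stable")  # ties -> alphabetical
        maj_k, min_k = int(order[0]), int(order[1])
        maj_n, min_n = int(row[maj_k]), int(row[min_k])
        if min_n == 0:
            continue
        if 100.0 * min_n / depth[i] <= min_minor_pct:
            continue
        two = maj_n + min_n
        calls.append(
            SnpCall(
                position=int(i) + 1,
                major=_BASES[maj_k],
                minor=_BASES[min_k],
                major_n=maj_n,
                minor_n=min_n,
                major_pct=round_half_up(100.0 * maj_n / two, 1),
                minor_pct=round_half_up(100.0 * min_n / two, 1),
                mutation_class=mutation_class(_BASES[maj_k], _BASES[min_k]),
                ambiguous=maj_n == min_n,
            )
        )
    return calls


def mutation_class(a: str, b: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs
    transversion."""
    pair = {a, b}
    return "transition" if pair in ({"A", "G"}, {"C", "T"}) else "transversion"


def genotype_percentages(major_n: int, minor_n: int) -> tuple[float, float]:
    """Major/minor percentages over the two reported genotypes, rounded to
    one decimal (half-up)."""
    two = major_n + minor_n
    return (
        round_half_up(100.0 * major_n / two, 1),
        round_half_up(100.0 * minor_n / two, 1),
    )


def _mark_codon(codon: str, offset: int) -> str:
    return "".join(
        c.upper() if t == offset else c.lower() for t, c in enumerate(codon)
    )


def classify_snp(
    call: SnpCall,
    annotation: Sequence[GeneModel],
    genome: str,
) -> SnpCall:
    """Fill the gene context of a call: intergenic, intron, or CDS with
    codon change and effect.  Overlapping genes each yield a context."""
    p0 = call.position - 1
    if not (0 <= p0 < len(genome)):
        raise ValueError(f"position {call.position} outside genome")
    in_span = False
    for gene in annotation:
        if gene.kind != "protein" or gene.pseudo:
            continue
        hit_part = None
        cum = 0
        for part in gene.ordered_parts():
            if part.start <= p0 < part.end:
                hit_part = part
                if part.strand == "+":
                    cds_pos0 = cum + (p0 - part.start)
                else:
                    cds_pos0 = cum + (part.end - 1 - p0)
                break
            cum += part.length
        if hit_part is None:
            if gene.in_span(p0):
                in_span = True
            continue
        spliced = _splice(genome, gene)
        codon_idx, codon_off = divmod(cds_pos0, 3)
        codon = spliced[codon_idx * 3 : codon_idx * 3 + 3]
        if len(codon) < 3:
            continue
        maj_c = call.major if hit_part.strand == "+" else complement_base(call.major)
        min_c = call.minor if hit_part.strand == "+" else complement_base(call.minor)
        major_codon = codon[:codon_off] + maj_c + codon[codon_off + 1 :]
        minor_codon = codon[:codon_off] + min_c + codon[codon_off + 1 :]
        maj_aa = translate_codon(major_codon)
        min_aa = translate_codon(minor_codon)
        if min_aa == "*":
            effect = "nonsense"
        elif maj_aa == min_aa:
            effect = "synonymous"
        else:
            effect = "nonsynonymous"
        call.contexts.append(
            CdsContext(
                gene=gene.name,
                strand=gene.strand,
                cds_pos=cds_pos0 + 1,
                major_codon=_mark_codon(major_codon, codon_off),
                minor_codon=_mark_codon(minor_codon, codon_off),
                major_aa=AA3[maj_aa] if maj_aa != "*" else "-",
                minor_aa=AA3[min_aa] if min_aa != "*" else "-",
                effect=effect,
            )
        )
    if call.contexts:
        call.context_kind = "CDS"
    elif in_span:
        call.context_kind = "intron"
    else:
        call.context_kind = "intergenic"
    return call


def _splice(genome: str, gene: GeneModel) -> str:
    from ._seq import revcomp

    pieces = []
    for part in gene.ordered_parts():
        piece = genome[part.start : part.end]
        if part.strand == "-":
            piece = revcomp(piece)
        pieces.append(piece)
    return "".join(pieces)


def annotate_shared_codons(calls: Sequence[SnpCall]) -> None:
    """Mark pairs of calls hitting the same codon of the same gene (they
    are reported per site, with a shared-codon note)."""
    seen: dict[tuple[str, int], SnpCall] = {}
    for call in calls:
        for ctx in call.contexts:
            key = (ctx.gene, (ctx.cds_pos - 1) // 3)
            if key in seen and seen[key] is not call:
                note = f"shares codon with site {seen[key].position}"
                if note not in call.notes:
                    call.notes.append(note)
                other = f"shares codon with site {call.position}"
                if other not in seen[key].notes:
                    seen[key].notes.append(other)
            else:
                seen[key] = call


# ---------------------------------------------------------------------------
# indel calls
# ---------------------------------------------------------------------------


@dataclass
class IndelCall:
    position: int  # 1-based anchor; insertion lies between position and +1
    inserted: str
    with_n: int
    without_n: int
    minor: bool

    @property
    def fraction(self) -> float:
        total = self.with_n + self.without_n
        return self.with_n / total if total else 0.0


def call_intra_indels(pileup: Pileup, min_reads: int = 2) -> list[IndelCall]:
    """Report insertion polymorphisms: identical inserted strings observed
    in >= ``min_reads`` reads, with with/without counts over the reads
    spanning the insertion point.  ``minor`` marks insertions carried by
    the minority of reads (heteroplasmic); an insertion carried by all
    spanning reads is a consensus difference, not heteroplasmy."""
    out = []
    for anchor, variants in sorted(pileup.insertions.items()):
        spanning = int(pileup.junction_cov[anchor])
        for ins, with_n in sorted(variants.items()):
            if with_n < min_reads:
                continue
            without_n = max(0, spanning - with_n)
            out.append(
                IndelCall(
                    position=anchor + 1,
                    inserted=ins,
                    with_n=with_n,
                    without_n=without_n,
                    minor=with_n < without_n,
                )
            )
    return out


# ---------------------------------------------------------------------------
# major/minor comparison across genomes
# ---------------------------------------------------------------------------


@dataclass
class SwapRecord:
    gene: str
    genome_pos: int
    cds_pos: int
    major: str  # coding orientation
    minor: str
    comparator_base: str
    status: str  # swap | no_swap | third


def compare_genotypes(
    calls: Sequence[SnpCall],
    own_cds: dict[str, CdsRecord],
    other_cds: dict[str, str],
    min_identity: float = 0.60,
) -> list[SwapRecord]:
    """Map each CDS call through a pairwise global alignment of the
    orthologous coding sequences and report whether the comparator's
    consensus base matches the call's minor genotype (a major/minor swap),
    its major genotype, or a third state."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5

    maps: dict[str, Optional[dict[int, str]]] = {}
    out = []
    for call in calls:
        for ctx in call.contexts:
            rec = own_cds.get(ctx.gene)
            other = other_cds.get(ctx.gene)
            if rec is None or other is None:
                continue
            if ctx.gene not in maps:
                maps[ctx.gene] = _align_map(
                    aligner, rec.spliced_sequence, other, min_identity
                )
                if maps[ctx.gene] is None:
                    warnings.warn(
                        f"ortholog pair for {ctx.gene} below {min_identity:.0%} "
                        "identity; calls skipped"
                    )
            mapping = maps[ctx.gene]
            if mapping is None:
                continue
            comp_base = mapping.get(ctx.cds_pos - 1, "")
            if not comp_base:
                continue
            off = next(
                t for t, c in enumerate(ctx.major_codon) if c.isupper()
            )
            major = ctx.major_codon[off].upper()
            minor = ctx.minor_codon[off].upper()
            if comp_base == minor:
                status = "swap"
            elif comp_base == major:
                status = "no_swap"
            else:
                status = "third"
            out.append(
                SwapRecord(
                    gene=ctx.gene,
                    genome_pos=call.position,
                    cds_pos=ctx.cds_pos,
                    major=major,
                    minor=minor,
                    comparator_base=comp_base,
                    status=status,
                )
            )
    return out


def _align_map(aligner, own: str, other: str, min_identity: float):
    aln = aligner.align(own, other)[0]
    blocks_own, blocks_other = aln.aligned
    matches = 0
    mapping: dict[int, str] = {}
    for (a0, a1), (b0, b1) in zip(blocks_own, blocks_other):
        for t in range(a1 - a0):
            mapping[a0 + t] = other[b0 + t]
            if own[a0 + t] == other[b0 + t]:
                matches += 1
    if matches / max(len(own), len(other)) < min_identity:
        return None
    return mapping
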