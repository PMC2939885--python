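"""Synthetic plastome, read, and cDNA simulation.

Generates circular quadripartite genomes (LSC and SSC separated by two
exact inverted repeats), AT-rich like a real plastome (~63% A+T), with
planted genes and operons, homopolymer runs, dispersed repeats, and
stem-loop small inversions — each recorded as ground truth so every
downstream stage can be tested by round-trip.  Read simulation emulates
long pyrosequencing reads (~350-400 bp) whose dominant error mode is a
+/-1 length miscall inside homopolymer runs, plus optional heteroplasmic
minor alleles at specified fractions.  cDNA simulation emulates a
polyT-primed library: reads derive from operon transcripts and genes
downstream of genomic polyA-like tracks are over-enriched.

Every stochastic operation takes its seed from its config object and uses
a single numpy Generator, so outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import circular_slice, random_dna, revcomp
from .genome import AnnotatedGenome, ExonPart, GeneModel, Operon, RegionLayout
from .io import FastqRead
from .structure import hairpin_score

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class OperonSpec:
    """One co-transcribed gene block: gene names in transcription order,
    the strand, and the intergenic spacer lengths between consecutive
    genes (len(spacers) == len(genes) - 1)."""

    genes: list[str]
    strand: str = "+"
    spacers: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.spacers:
            self.spacers = [30] * (len(self.genes) - 1)
        if len(self.spacers) != len(self.genes) - 1:
            raise ValueError("need one spacer length per adjacent gene pair")


@dataclass
class GenomeSpec:
    """Blueprint for a simulated quadripartite plastome.

    Region lengths are in bp; the genome totals
    ``lsc_len + ssc_len + 2 * ir_len``.  The default A+T fraction matches
    the AT-rich composition typical of plastomes.  Planted features are
    placed at random non-overlapping positions inside the LSC (with a
    safety margin), and their realized coordinates are recorded in the
    returned genome's ``truth``.
    """

    lsc_len: int
    ssc_len: int
    ir_len: int
    at_fraction: float = 0.63
    n_genes: int = 0
    operon_specs: list[OperonSpec] = field(default_factory=list)
    homopolymer_plants: list[tuple[str, int]] = field(default_factory=list)
    repeat_plants: list[tuple[int, int, str]] = field(default_factory=list)
    si_plants: list[tuple[int, int]] = field(default_factory=list)
    gene_len_range: tuple[int, int] = (300, 600)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.at_fraction <= 1.0):
            raise ValueError("at_fraction must be in [0, 1]")
        if self.ir_len >= self.lsc_len:
            raise ValueError("ir_len must be smaller than lsc_len")
        for base, length in self.homopolymer_plants:
            if base not in "ACGT" or length < 7:
                raise ValueError("homopolymer plants need base in ACGT, length >= 7")
        for stem, loop in self.si_plants:
            if not (11 <= stem <= 24) or loop > 50:
                raise ValueError("SI plants need stem in [11, 24] and loop <= 50")

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass
class ReadSimConfig:
    mean_len: float = 380.0
    len_sd: float = 40.0
    depth: float = 50.0
    hp_error_rate: float = 0.04  # per run: p(+/-1) = min(0.9, rate * (L - 3))
    sub_error_rate: float = 0.002
    mean_q: int = 30
    q_decay: float = 5.0  # mean Phred drop from read start to end
    seed: int = 0

    def validate(self) -> None:
        for r in (self.hp_error_rate, self.sub_error_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("error rates must be in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class HeteroplasmySpec:
    """Planted within-individual polymorphism: SNP sites as
    (1-based position, major base, minor base, minor fraction in (0, 0.5])
    and insertions as (1-based anchor position, inserted string, fraction).
    """

    sites: list[tuple[int, str, str, float]] = field(default_factory=list)
    indels: list[tuple[int, str, float]] = field(default_factory=list)

    def validate(self, genome: str) -> None:
        for pos, major, minor, frac in self.sites:
            if not (1 <= pos <= len(genome)):
                raise ValueError(f"heteroplasmy site {pos} outside genome")
            if major == minor:
                raise ValueError("minor base must differ from major")
            if not (0.0 < frac <= 0.5):
                raise ValueError("minor fraction must be in (0, 0.5]")
            if genome[pos - 1] != major:
                raise ValueError(
                    f"genome holds {genome[pos - 1]} at {pos}, not major {major}"
                )
        for pos, ins, frac in self.indels:
            if not (1 <= pos <= len(genome)):
                raise ValueError(f"indel anchor {pos} outside genome")
            if not ins or not (0.0 < frac <= 0.5):
                raise ValueError("indel needs a nonempty string, fraction in (0, 0.5]")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------


class _Placer:
    """Non-overlapping random placement inside one region, with margins."""

    def __init__(self, rng: np.random.Generator, region_len: int, margin: int = 12):
        self.rng = rng
        self.region_len = region_len
        self.margin = margin
        self.occupied: list[tuple[int, int]] = []

    def place(self, length: int, tries: int = 500) -> int:
        lo = self.margin
        hi = self.region_len - self.margin - length
        if hi < lo:
            raise ValueError(
                "planted features overlap: region too small for a "
                f"{length}-bp feature"
            )
        for _ in range(tries):
            start = int(self.rng.integers(lo, hi + 1))
            if all(
                start + length + self.margin <= a or b + self.margin <= start
                for a, b in self.occupied
            ):
                self.occupied.append((start, start + length))
                return start
        raise ValueError(
            "planted features overlap: could not place a "
            f"{length}-bp feature without collision"
        )


def _gene_sequence(rng: np.random.Generator, length: int) -> str:
    """ATG + random sense codons + TAA, with no homopolymer run >= 5."""
    n_codons = max(2, length // 3) - 2
    while True:
        body = "".join(
            _SENSE_CODONS[int(i)]
            for i in rng.integers(0, len(_SENSE_CODONS), n_codons)
        )
        seq = "ATG" + body + "TAA"
        if not _has_run(seq, 5):
            return seq


def _has_run(seq: str, min_len: int) -> bool:
    return any(b * min_len in seq for b in "ACGT")


def _write(region: list[str], start: int, payload: str) -> None:
    region[start : start + len(payload)] = list(payload)


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(len(choices)))]


def _break_stray_runs(
    region: list[str],
    rng: np.random.Generator,
    exempt: list[tuple[int, int]],
    max_run: int = 4,
) -> None:
    """Mutate one interior base of every background homopolymer run longer
    than ``max_run`` that does not fall inside a planted feature, so the
    only long runs in the genome are the planted ones."""
    i = 0
    n = len(region)
    while i < n:
        j = i
        while j < n and region[j] == region[i]:
            j += 1
        if j - i > max_run and not any(a <= i and j <= b for a, b in exempt):
            mid = (i + j) // 2
            region[mid] = _other_base(rng, region[i])
        i = j


def simulate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Build a circular quadripartite genome per the spec, with all planted
    features recorded in ``truth`` and ground-truth annotation attached.

    The returned sequence is linearised at the IRa→LSC junction (LSC
    first); IRa is the exact reverse complement of IRb by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L, S, I = spec.lsc_len, spec.ssc_len, spec.ir_len

    lsc = list(random_dna(rng, L, spec.at_fraction))
    ssc = list(random_dna(rng, S, spec.at_fraction))
    irb = list(random_dna(rng, I, spec.at_fraction))

    placer = _Placer(rng, L)
    genes: list[GeneModel] = []
    operons: list[Operon] = []
    truth: dict = {"homopolymers": [], "repeats": [], "sis": [], "polya": []}

    gene_lo, gene_hi = spec.gene_len_range

    def sample_gene_len() -> int:
        return 3 * int(rng.integers(gene_lo // 3, gene_hi // 3 + 1))

    # operons: one contiguous block each, genes in transcription order
    for op in spec.operon_specs:
        lens = [sample_gene_len() for _ in op.genes]
        block = sum(lens) + sum(op.spacers)
        start = placer.place(block)
        # physical layout: for '-' operons transcription runs right-to-left
        order = list(zip(op.genes, lens))
        if op.strand == "-":
            order = order[::-1]
        pos = start
        placed: dict[str, tuple[int, int]] = {}
        spacers = op.spacers if op.strand == "+" else op.spacers[::-1]
        for k, (gname, glen) in enumerate(order):
            gseq = _gene_sequence(rng, glen)
            if op.strand == "-":
                gseq = revcomp(gseq)
            _write(lsc, pos, gseq)
            placed[gname] = (pos, pos + len(gseq))
            pos += len(gseq)
            if k < len(order) - 1:
                pos += spacers[k]
        for gname in op.genes:
            a, b = placed[gname]
            genes.append(
                GeneModel(
                    name=gname,
                    parts=[ExonPart(a, b, op.strand, 1)],
                    strand=op.strand,
                )
            )
        operons.append(Operon(genes=list(op.genes), strand=op.strand))

    # singleton genes
    for g in range(spec.n_genes):
        glen = sample_gene_len()
        strand = "+" if rng.random() < 0.5 else "-"
        gseq = _gene_sequence(rng, glen)
        if strand == "-":
            gseq = revcomp(gseq)
        start = placer.place(len(gseq))
        _write(lsc, start, gseq)
        genes.append(
            GeneModel(
                name=f"gene{g + 1}",
                parts=[ExonPart(start, start + len(gseq), strand, 1)],
                strand=strand,
            )
        )

    # homopolymer runs (flanked by a different base to keep them maximal)
    for base, length in spec.homopolymer_plants:
        start = placer.place(length + 2)
        flank_l = _other_base(rng, base)
        flank_r = _other_base(rng, base)
        _write(lsc, start, flank_l + base * length + flank_r)
        truth["homopolymers"].append((base, start + 2, length))

    # dispersed repeats
    for unit_len, mismatches, kind in spec.repeat_plants:
        if mismatches > (unit_len - 2) // 2:
            raise ValueError("too many mismatches for repeat unit")
        unit = random_dna(rng, unit_len, spec.at_fraction)
        copy2 = list(unit)
        mpos = rng.choice(np.arange(1, unit_len - 1), size=mismatches, replace=False)
        for m in mpos:
            copy2[m] = _other_base(rng, copy2[m])
        copy2 = "".join(copy2)
        if kind == "I":
            copy2 = revcomp(copy2)
        s1 = placer.place(unit_len + 2)
        s2 = placer.place(unit_len + 2)
        if s1 > s2:
            s1, s2 = s2, s1
        # boundary bases chosen to block extension of the maximal repeat
        _write(lsc, s1 + 1, unit)
        _write(lsc, s2 + 1, copy2)
        _block_repeat_extension(lsc, rng, s1 + 1, s2 + 1, unit_len, kind)
        truth["repeats"].append(
            {"unit_len": unit_len, "start1": s1 + 2, "start2": s2 + 2,
             "type": kind, "mismatches": mismatches}
        )

    # small inversions (stable stem-loop hairpins)
    for stem, loop in spec.si_plants:
        span = _make_hairpin(rng, stem, loop, spec.at_fraction)
        start = placer.place(len(span) + 2)
        _write(lsc, start + 1, span)
        # block outward stem extension: the bases flanking the span must
        # not be complementary to each other
        lsc[start] = _other_base(rng, complement_of(lsc[start + 1 + len(span)]))
        truth["sis"].append(
            {"start": start + 2, "stem": stem, "loop": loop, "sequence": span}
        )

    exempt = [(a, b) for a, b in placer.occupied]
    _break_stray_runs(lsc, rng, exempt)
    _break_stray_runs(ssc, rng, [])
    _break_stray_runs(irb, rng, [])

    # keep the planted IR maximal: block inward and outward extension
    if ssc[0] == complement_of(ssc[-1]):
        ssc[0] = _other_base(rng, ssc[0], complement_of(ssc[-1]))
    if lsc[-1] == complement_of(lsc[0]):
        lsc[-1] = _other_base(rng, lsc[-1], complement_of(lsc[0]))

    irb_s = "".join(irb)
    seq = "".join(lsc) + irb_s + "".join(ssc) + revcomp(irb_s)
    layout = RegionLayout(
        lsc=(0, L), irb=(L, L + I), ssc=(L + I, L + I + S),
        ira=(L + I + S, L + I + S + I),
    )
    genome = AnnotatedGenome(
        seq=seq, genes=genes, operons=operons, layout=layout,
        name=f"synthetic_cp_{spec.seed}", truth=truth,
    )
    genome.check_layout()
    return genome


def complement_of(base: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G"}.get(base, "N")


def _block_repeat_extension(
    region: list[str],
    rng: np.random.Generator,
    s1: int,
    s2: int,
    unit_len: int,
    kind: str,
) -> None:
    """Adjust the single bases flanking both repeat copies so the maximal
    repeat is exactly the planted unit."""
    if kind == "F":
        if region[s1 - 1] == region[s2 - 1]:
            region[s2 - 1] = _other_base(rng, region[s1 - 1])
        if region[s1 + unit_len] == region[s2 + unit_len]:
            region[s2 + unit_len] = _other_base(rng, region[s1 + unit_len])
    else:
        # extending copy1 leftwards pairs with the base right of copy2
        if region[s1 - 1] == complement_of(region[s2 + unit_len]):
            region[s2 + unit_len] = _other_base(
                rng, region[s2 + unit_len], complement_of(region[s1 - 1])
            )
        if region[s1 + unit_len] == complement_of(region[s2 - 1]):
            region[s2 - 1] = _other_base(
                rng, region[s2 - 1], complement_of(region[s1 + unit_len])
            )


def _make_hairpin(
    rng: np.random.Generator, stem: int, loop: int, at: float,
    score_threshold: float = -10.0,
) -> str:
    """A stem-loop span whose perfect stem is exactly ``stem`` bp, whose
    loop cannot extend the stem inward, and whose stability score clears
    the detector's default threshold."""
    for _ in range(200):
        stem_seq = random_dna(rng, stem, min(at, 0.45))
        loop_seq = random_dna(rng, loop, at)
        if loop >= 2 and loop_seq[0] == complement_of(loop_seq[-1]):
            loop_seq = _other_base(rng, complement_of(loop_seq[-1])) + loop_seq[1:]
        span = stem_seq + loop_seq + revcomp(stem_seq)
        if hairpin_score(span, stem_len=stem) <= score_threshold - 0.5:
            return span
    raise ValueError(f"could not build a stable hairpin (stem {stem}, loop {loop})")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    genome: AnnotatedGenome | str,
    cfg: ReadSimConfig,
    het: Optional[HeteroplasmySpec] = None,
) -> tuple[list[FastqRead], list[dict]]:
    """Sample pyrosequencing-like reads uniformly over the circle.

    Returns (reads, truth) where truth records each read's origin
    (0-based start, length drawn, strand) before errors.  Heteroplasmic
    minor alleles are applied per read with their specified fractions;
    homopolymer-length miscalls occur only inside runs (probability
    min(0.9, rate * (run_len - 3)) of a +/-1 length change); substitution
    errors are uniform per base.
    """
    cfg.validate()
    seq = genome.seq if isinstance(genome, AnnotatedGenome) else str(genome)
    if not seq:
        raise ValueError("empty genome")
    het = het or HeteroplasmySpec()
    het.validate(seq)
    rng = np.random.default_rng(cfg.seed)
    n = len(seq)
    n_reads = int(round(cfg.depth * n / cfg.mean_len))
    if n_reads <= 0:
        raise ValueError("depth/mean_len yield zero reads")

    reads: list[FastqRead] = []
    truth: list[dict] = []
    for i in range(n_reads):
        start = int(rng.integers(n))
        length = int(np.clip(rng.normal(cfg.mean_len, cfg.len_sd), 50, 2 * n))
        raw = circular_slice(seq, start, length)
        edited = _apply_heteroplasmy(raw, start, n, het, rng)
        edited = _apply_hp_errors(edited, cfg.hp_error_rate, rng)
        edited = _apply_sub_errors(edited, cfg.sub_error_rate, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            edited = revcomp(edited)
        qual = _qualities(rng, len(edited), cfg.mean_q, cfg.q_decay)
        reads.append(FastqRead(name=f"read{i}", seq=edited, qual=qual))
        truth.append({"name": f"read{i}", "start": start, "length": length,
                      "strand": strand})
    return reads, truth


def _apply_heteroplasmy(
    raw: str, start: int, n: int, het: HeteroplasmySpec, rng: np.random.Generator
) -> str:
    if not het.sites and not het.indels:
        return raw
    chars = list(raw)
    for pos1, _major, minor, frac in het.sites:
        off = (pos1 - 1 - start) % n
        if off < len(chars) and rng.random() < frac:
            chars[off] = minor
    inserts = []
    for pos1, ins, frac in het.indels:
        off = (pos1 - 1 - start) % n
        if off < len(chars) and rng.random() < frac:
            inserts.append((off, ins))
    for off, ins in sorted(inserts, reverse=True):
        chars[off + 1 : off + 1] = list(ins)
    return "".join(chars)


def _apply_hp_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run_len = j - i
        piece = seq[i:j]
        if run_len >= 4:
            p = min(0.9, rate * (run_len - 3))
            if rng.random() < p:
                if rng.random() < 0.5:
                    piece = piece + seq[i]  # over-call
                else:
                    piece = piece[:-1]  # under-call
        out.append(piece)
        i = j
    return "".join(out)


def _apply_sub_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for h in hits:
        chars[h] = _other_base(rng, chars[h])
    return "".join(chars)


def _qualities(
    rng: np.random.Generator, length: int, mean_q: int, decay: float
) -> str:
    drift = np.linspace(0, decay, length) if length > 1 else np.zeros(length)
    q = rng.normal(mean_q, 2.0, length) - drift
    q = np.clip(np.rint(q), 2, 40).astype(int)
    return "".join(chr(int(v) + 33) for v in q)


# ---------------------------------------------------------------------------
# cDNA simulation (polyT-primed library)
# ---------------------------------------------------------------------------


def simulate_cdna(
    genome: AnnotatedGenome,
    expression: dict[str, float],
    adaptor: str = "",
    mean_len: float = 250.0,
    len_sd: float = 60.0,
    enrichment: float = 50.0,
    polya_min_len: int = 15,
    polya_window: int = 200,
    adaptor_frac: float = 0.5,
    seed: int = 0,
) -> tuple[list[FastqRead], dict[str, int]]:
    """Simulate a polyT-primed cDNA library.

    Reads derive from operon transcripts (so they may span gene junctions
    within a unit); the expected read count of gene ``g`` is
    ``expression[g]``, multiplied by ``enrichment`` when a genomic polyA
    track of >= ``polya_min_len`` pure A lies within ``polya_window`` bp
    upstream of the gene start on its strand (the polyT-priming artifact).
    A fraction of reads carries the adaptor on the 3' end.  Returns
    (reads, per-gene true read counts).
    """
    known = set(genome.gene_names())
    for g in expression:
        if g not in known:
            raise ValueError(f"unknown gene id {g!r}")
    rng = np.random.default_rng(seed)
    units = transcription_units_truth(genome)
    reads: list[FastqRead] = []
    counts: dict[str, int] = {g: 0 for g in known}
    rid = 0
    for unit in units:
        members = [genome.gene(g) for g in unit.genes]
        a = min(g.span[0] for g in members)
        b = max(g.span[1] for g in members)
        tseq = genome.seq[a:b]
        if unit.strand == "-":
            tseq = revcomp(tseq)
        T = len(tseq)
        for g in members:
            mu = float(expression.get(g.name, 0.0))
            if mu <= 0:
                continue
            if _has_upstream_polya(genome.seq, g, polya_min_len, polya_window):
                mu *= enrichment
            n_reads = int(rng.poisson(mu))
            ga, gb = g.span
            if unit.strand == "+":
                t0, t1 = ga - a, gb - a
            else:
                t0, t1 = b - gb, b - ga
            for _ in range(n_reads):
                L = int(np.clip(rng.normal(mean_len, len_sd), 40, max(40, T)))
                lo = max(0, t0 - L + 1)
                hi = min(t1 - 1, T - L)
                if hi < lo:
                    start = lo if lo <= T - L else max(0, T - L)
                else:
                    start = int(rng.integers(lo, hi + 1))
                rseq = tseq[start : start + L]
                if adaptor and rng.random() < adaptor_frac:
                    rseq = rseq + adaptor
                qual = _qualities(rng, len(rseq), 30, 3.0)
                reads.append(FastqRead(f"cdna{rid}", rseq, qual))
                counts[g.name] += 1
                rid += 1
    return reads, counts


def transcription_units_truth(genome: AnnotatedGenome) -> list[Operon]:
    """The true transcription units: declared operons plus every gene not
    in an operon as its own monocistronic unit."""
    in_operon = {g for op in genome.operons for g in op.genes}
    units = list(genome.operons)
    for g in genome.genes:
        if g.name not in in_operon:
            units.append(Operon(genes=[g.name], strand=g.strand))
    return units


def _has_upstream_polya(
    seq: str, gene: GeneModel, min_len: int, window: int
) -> bool:
    ga, gb = gene.span
    if gene.strand == "+":
        region = seq[max(0, ga - window) : ga]
        return "A" * min_len in region
    region = revcomp(seq[gb : gb + window])
    return "A" * min_len in region
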