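"""cDNA mapping, transcription-unit assignment, and polyA-track detection.

Plastid transcription is prokaryote-like: most genes are co-transcribed
in polycistronic units.  Mapped cDNA reads are clustered into
strand-resolved transcript contigs; the genes a contig covers on one
strand form one transcription unit, in genomic order.  Because the
library is polyT-primed, genes sitting just downstream of genomic
polyA-like tracks are artificially enriched; such tracks are detected and
flagged (never corrected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

import edlib

from ._seq import revcomp
from .align import Alignment, map_read
from .genome import AnnotatedGenome, GeneModel
from .io import FastqRead


@dataclass
class GeneTally:
    gene: str
    read_count: int
    coverage_pct: float  # percent of exonic length covered by >= 1 read
    detected: bool


@dataclass
class CdnaMapResult:
    alignments: list[Alignment]
    tallies: dict[str, GeneTally]


@dataclass
class TranscriptionUnit:
    genes: list[str]  # genomic order on the unit's strand
    strand: str
    kind: str  # monocistronic | polycistronic
    support: dict[str, tuple[int, float]] = field(default_factory=dict)


@dataclass
class PolyATrack:
    start: int  # 1-based
    length: int
    purity: float
    strand: str
    nearest_downstream_gene: str = ""
    distance: int = -1  # bp between track and gene start; -1 = none in window


def trim_adaptor(read: FastqRead, adaptor: str, max_err: float = 0.1) -> FastqRead:
    """Remove the adaptor (either orientation) and everything outward of
    it, keeping the longer flank."""
    if not adaptor:
        return read
    best = None
    for ad in (adaptor, revcomp(adaptor)):
        res = edlib.align(ad, read.seq, mode="HW", task="locations",
                          k=int(len(ad) * max_err))
        if res["editDistance"] >= 0 and res["locations"]:
            lo, hi = res["locations"][0]
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], lo, hi)
    if best is None:
        return read
    _, lo, hi = best
    left, right = read.seq[:lo], read.seq[hi + 1 :]
    if len(left) >= len(right):
        return FastqRead(read.name, left, read.qual[:lo])
    return FastqRead(read.name, right, read.qual[hi + 1 :])


def map_cdna(
    reads: Sequence[FastqRead],
    genome: AnnotatedGenome,
    adaptor: str = "",
    min_identity: float = 0.99,
    min_coverage_pct: float = 80.0,
) -> CdnaMapResult:
    """Adaptor-trim and map cDNA reads, then tally per-gene support.

    A gene is "detected" iff the fraction of its exonic length covered by
    at least one qualifying read is strictly above ``min_coverage_pct``
    percent and the supporting reads align at >= ``min_identity``.
    """
    n = len(genome.seq)
    alignments: list[Alignment] = []
    for read in reads:
        trimmed = trim_adaptor(read, adaptor)
        if len(trimmed.seq) < 30:
            continue
        aln = map_read(trimmed, genome.seq, circular=genome.circular)
        if aln is None or aln.identity < min_identity:
            continue
        alignments.append(aln)

    covered = np.zeros(n, dtype=bool)
    for aln in alignments:
        for p in range(aln.ref_start, aln.ref_end):
            covered[p % n] = True

    tallies: dict[str, GeneTally] = {}
    for gene in genome.genes:
        exonic = 0
        hit = 0
        for part in gene.parts:
            exonic += part.length
            hit += int(covered[part.start : part.end].sum())
        count = sum(1 for aln in alignments if _overlaps_gene(aln, gene, n))
        cov_pct = 100.0 * hit / exonic if exonic else 0.0
        tallies[gene.name] = GeneTally(
            gene=gene.name,
            read_count=count,
            coverage_pct=round(cov_pct, 1),
            detected=count > 0 and cov_pct > min_coverage_pct,
        )
    return CdnaMapResult(alignments=alignments, tallies=tallies)


def _overlaps_gene(aln: Alignment, gene: GeneModel, n: int) -> bool:
    for part in gene.parts:
        a, b = aln.ref_start, aln.ref_end
        if a < n and b > n:  # wrapped alignment: check both arcs
            if part.start < b - n or a < part.end:
                return True
        elif part.start < b and a < part.end:
            return True
    return False


def assign_transcription_units(
    alignments: Sequence[Alignment],
    annotation: Sequence[GeneModel],
    min_overlap: int = 20,
    min_gene_coverage_pct: float = 80.0,
    genome_len: Optional[int] = None,
) -> list[TranscriptionUnit]:
    """Cluster strand-resolved alignments into transcript contigs (reads
    overlapping by >= ``min_overlap`` bp merge) and assign genes to units.

    A gene joins a unit when one contig on the gene's strand covers more
    than ``min_gene_coverage_pct`` percent of its exonic span.  Unit genes
    are reported in genomic order; a unit is polycistronic iff it holds
    two or more genes.  Every gene belongs to at most one unit.
    """
    by_strand: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
    for aln in alignments:
        by_strand[aln.strand].append((aln.ref_start, aln.ref_end))
    units: list[TranscriptionUnit] = []
    assigned: set[str] = set()
    for strand, ivals in by_strand.items():
        if not ivals:
            continue
        contigs = _merge_intervals(sorted(ivals), min_overlap)
        for ca, cb in contigs:
            members = []
            for gene in annotation:
                if gene.strand != strand or gene.name in assigned:
                    continue
                exonic = gene.exonic_length
                inside = sum(
                    max(0, min(p.end, cb) - max(p.start, ca)) for p in gene.parts
                )
                if exonic and 100.0 * inside / exonic > min_gene_coverage_pct:
                    members.append(gene)
            if not members:
                continue
            members.sort(key=lambda g: g.span[0], reverse=strand == "-")
            names = [g.name for g in members]
            assigned.update(names)
            units.append(
                TranscriptionUnit(
                    genes=names,
                    strand=strand,
                    kind="polycistronic" if len(names) > 1 else "monocistronic",
                )
            )
    units.sort(key=lambda u: u.genes)
    return units


def _merge_intervals(
    ivals: list[tuple[int, int]], min_overlap: int
) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for a, b in ivals:
        if merged and a <= merged[-1][1] - min_overlap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def expression_table(
    tallies_by_tissue: dict[str, dict[str, GeneTally]],
    genes: Sequence[str],
    tissues: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Gene x tissue matrix of "count(coverage)" cells; genes with zero
    reads in a tissue render as "-"."""
    if tissues is None:
        tissues = list(tallies_by_tissue)
    if not tissues:
        raise ValueError("need at least one tissue")
    rows = {}
    for gene in genes:
        row = {}
        for tissue in tissues:
            tally = tallies_by_tissue.get(tissue, {}).get(gene)
            if tally is None or tally.read_count == 0:
                row[tissue] = "-"
            else:
                cov = tally.coverage_pct
                cov_s = f"{int(cov)}" if cov == int(cov) else f"{cov:.1f}"
                row[tissue] = f"{tally.read_count}({cov_s})"
        rows[gene] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))
    df.index.name = "gene"
    return df


def write_expression_table(path: str, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")


def read_expression_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene", dtype=str)
    return df


def detect_polyA_tracks(
    genome: AnnotatedGenome,
    min_len: int = 10,
    min_purity: float = 0.8,
    window: int = 200,
) -> list[PolyATrack]:
    """Maximal A-rich tracks on either strand, linked to the nearest
    downstream gene start within ``window`` bp.

    A track starts and ends with the target base (A on the plus strand, T
    on the genomic plus strand for minus-strand tracks), has purity >=
    ``min_purity`` and length >= ``min_len``, and cannot be extended under
    the purity rule.  Such tracks upstream of a gene are candidates for
    polyT-priming enrichment bias.
    """
    out: list[PolyATrack] = []
    seq = genome.seq
    for strand, base in (("+", "A"), ("-", "T")):
        for s, e, purity in _pure_tracks(seq, base, min_len, min_purity):
            track = PolyATrack(
                start=s + 1, length=e - s, purity=round(purity, 3), strand=strand
            )
            _link_downstream_gene(track, genome.genes, strand, s, e, window)
            out.append(track)
    out.sort(key=lambda t: t.start)
    return out


def _pure_tracks(seq: str, base: str, min_len: int, min_purity: float):
    n = len(seq)
    i = 0
    while i < n:
        if seq[i] != base:
            i += 1
            continue
        # greedy: extend as far as purity allows, remembering the last
        # position where the window still qualifies and ends on ``base``
        count = 0
        best_end = i
        j = i
        while j < n:
            if seq[j] == base:
                count += 1
                if count / (j - i + 1) >= min_purity:
                    best_end = j + 1
            else:
                if (count + 1) / (j - i + 1) < min_purity:
                    break
            j += 1
        length = best_end - i
        if length >= min_len:
            purity = sum(1 for c in seq[i:best_end] if c == base) / length
            yield i, best_end, purity
            i = best_end
        else:
            i += 1


def _link_downstream_gene(
    track: PolyATrack,
    genes: Sequence[GeneModel],
    strand: str,
    s: int,
    e: int,
    window: int,
) -> None:
    best: Optional[tuple[int, GeneModel]] = None
    for gene in genes:
        if gene.strand != strand:
            continue
        ga, gb = gene.span
        if strand == "+":
            d = ga - e  # bases between track end and gene start
        else:
            d = s - gb  # transcription runs right-to-left
        if 0 <= d <= window and (best is None or d < best[0]):
            best = (d, gene)
    if best is not None:
        track.distance = best[0]
        track.nearest_downstream_gene = best[1].name
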