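"""Read screening, iterative contig elongation, and homopolymer inventory.

The assembly stage mirrors a plastome project built on long pyrosequencing
reads: chloroplast-derived reads are screened out of a mixed pool by
alignment to reference genomes, seed contigs are elongated end-on against
the read pool by majority-vote consensus until the circle closes, and the
homopolymer runs that dominate the platform's error profile are
inventoried so each can be targeted for independent validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from ._seq import canonical_circular, revcomp, validate_dna
from .genome import AnnotatedGenome
from .io import FastqRead

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# homopolymer inventory
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomopolymerRun:
    base: str
    start: int  # 1-based
    length: int

    @property
    def end(self) -> int:  # 1-based inclusive
        return self.start + self.length - 1


def find_homopolymers(seq: str, min_len: int = 7) -> list[HomopolymerRun]:
    """All maximal single-base runs of length >= ``min_len``, sorted by
    position.  Raises for non-ACGT characters, naming the position."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    validate_dna(seq)
    out = []
    pos = 0
    for base, group in groupby(seq):
        n = sum(1 for _ in group)
        if n >= min_len:
            out.append(HomopolymerRun(base=base, start=pos + 1, length=n))
        pos += n
    return out


def homopolymer_summary(runs: Sequence[HomopolymerRun], min_len: int = 7) -> dict:
    """Counts split into runs equal to and above the threshold length."""
    return {
        "equal": sum(1 for r in runs if r.length == min_len),
        "above": sum(1 for r in runs if r.length > min_len),
        "total": len(runs),
    }


def validation_windows(
    runs: Sequence[HomopolymerRun],
    genome: AnnotatedGenome | int,
    flank: int = 300,
) -> list[tuple[int, int]]:
    """Minimal set of windows (run +/- flank, 1-based inclusive, merged when
    overlapping) covering every run — the targeting design for per-run
    validation (e.g. PCR + capillary re-sequencing)."""
    if flank < 50:
        raise ValueError("flank must be >= 50")
    n = len(genome.seq) if isinstance(genome, AnnotatedGenome) else int(genome)
    ivals = sorted(
        (max(1, r.start - flank), min(n, r.end + flank)) for r in runs
    )
    merged: list[list[int]] = []
    for a, b in ivals:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------------------
# cp-read screening
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    kept: list[FastqRead]
    discarded: list[FastqRead]
    report: list[dict]  # read id, best reference, identity, kept flag


def screen_cp_reads(
    reads: Sequence[FastqRead],
    references: Sequence[tuple[str, str]],
    min_identity: float = 0.90,
    min_cov: float = 0.80,
) -> ScreenResult:
    """Partition reads into chloroplast-derived and other.

    A read is kept iff its best infix alignment to any reference (either
    strand, references treated as circular) reaches ``min_identity`` over
    at least ``min_cov`` of the read.  The partition is exhaustive and
    disjoint.
    """
    if not references:
        raise ValueError("references must be nonempty")
    if not reads:
        warnings.warn("empty read set: nothing to screen")
        return ScreenResult([], [], [])
    targets = []
    for name, seq in references:
        doubled = seq + seq[: min(len(seq), 1000)]
        targets.append((name, doubled))
    kept, discarded, report = [], [], []
    for read in reads:
        best_ident, best_ref = 0.0, ""
        for name, target in targets:
            for q in (read.seq, revcomp(read.seq)):
                ident = _screen_identity(q, target, min_cov)
                if ident > best_ident:
                    best_ident, best_ref = ident, name
        ok = best_ident >= min_identity
        (kept if ok else discarded).append(read)
        report.append(
            {
                "read": read.name,
                "best_reference": best_ref,
                "identity": round(best_ident, 4),
                "kept": ok,
            }
        )
    return ScreenResult(kept, discarded, report)


def _screen_identity(q: str, target: str, min_cov: float) -> float:
    res = edlib.align(q, target, mode="HW")
    full = 1.0 - res["editDistance"] / len(q)
    if full >= 0.99 or min_cov >= 1.0:
        return full
    # allow a partially covered read: best qualifying prefix/suffix
    w = max(1, int(len(q) * min_cov))
    best = full
    for sub in (q[:w], q[-w:]):
        res = edlib.align(sub, target, mode="HW")
        best = max(best, 1.0 - res["editDistance"] / len(sub))
    return best


# ---------------------------------------------------------------------------
# iterative contig elongation
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    sequence: str
    support: np.ndarray = field(default=None)  # per-base read-depth votes
    closed: bool = False

    def __post_init__(self):
        if self.support is None:
            self.support = np.ones(len(self.sequence), dtype=np.int32)
        if len(self.support) != len(self.sequence):
            raise ValueError("support length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


class _ReadIndex:
    """Exact-match index of all ``w``-mers in a read pool (both strands)."""

    def __init__(self, reads: Sequence[str], w: int):
        self.w = w
        self.reads: list[str] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for seq in reads:
            for oriented in (seq, revcomp(seq)):
                rid = len(self.reads)
                self.reads.append(oriented)
                for off in range(len(oriented) - w + 1):
                    self.index.setdefault(oriented[off : off + w], []).append(
                        (rid, off)
                    )

    def occurrences(self, anchor: str) -> list[tuple[int, int]]:
        return self.index.get(anchor, [])


def _vote_extension(
    contig_seq: str,
    idx: _ReadIndex,
    min_support: int,
    min_identity: float,
) -> tuple[str, bool]:
    """Consensus extension beyond the right end of ``contig_seq``.

    Reads anchored by an exact match of the terminal w-mer (and consistent
    with the contig over their full overlap at >= ``min_identity``) vote
    per position; the extension stops where support drops below
    ``min_support`` or no strict majority exists.  Returns (extension,
    ambiguous) where ambiguous marks a halted tie.
    """
    w = idx.w
    if len(contig_seq) < w:
        return "", False
    anchor = contig_seq[-w:]
    votes: list[dict[str, int]] = []
    for rid, off in idx.occurrences(anchor):
        read = idx.reads[rid]
        # overlap check: the read's prefix before the anchor must agree
        # with the contig within the identity budget
        overlap = min(off, len(contig_seq) - w)
        if overlap:
            a = contig_seq[-(w + overlap) : -w]
            b = read[off - overlap : off]
            mism = sum(1 for x, y in zip(a, b) if x != y)
            if mism > (1 - min_identity) * (overlap + w):
                continue
        ext = read[off + w :]
        for t, base in enumerate(ext):
            if t >= len(votes):
                votes.append({})
            votes[t][base] = votes[t].get(base, 0) + 1
    out = []
    for tally in votes:
        total = sum(tally.values())
        if total < min_support:
            break
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return "".join(out), True  # tie: ambiguous, halt this end
        # qualified majority: a bare plurality is not enough — reads
        # leaving a long exact repeat split into near-equal camps, and
        # extending on sampling noise would build a chimera.  Halt there;
        # such ends are resolved by contigs that span the repeat junction.
        if ranked[0][1] < 0.7 * total:
            return "".join(out), len(ranked) > 1
        out.append(ranked[0][0])
    return "".join(out), False


def _try_close(seq: str, min_overlap: int) -> Optional[str]:
    """If the contig's two ends overlap each other by >= ``min_overlap``
    identical bases the molecule is circular: trim the duplicated arc."""
    w = min_overlap
    if len(seq) < 2 * w:
        return None
    head = seq[:w]
    p = seq.find(head, w)
    while p != -1:
        if seq[p:] == seq[: len(seq) - p]:
            return seq[:p]
        p = seq.find(head, p + 1)
    return None


def _try_merge(a: str, b: str, min_overlap: int) -> Optional[str]:
    """Merge two contigs when a suffix of ``a`` equals a prefix of ``b``
    (>= min_overlap, exact)."""
    w = min_overlap
    if len(a) < w or len(b) < w:
        return None
    probe = b[:w]
    p = a.find(probe)
    while p != -1:
        q = len(a) - p
        if q <= len(b) and a[p:] == b[: q]:
            return a + b[q:]
        p = a.find(probe, p + 1)
    return None


def elongate_contigs(
    contigs: Sequence[Contig | str],
    reads: Sequence[FastqRead | str],
    min_overlap: int = 40,
    min_support: int = 3,
    min_identity: float = 0.98,
    max_rounds: int = 500,
) -> list[Contig]:
    """Iteratively extend both ends of each contig against the read pool.

    Each round, reads anchored to a contig end by ``min_overlap`` exact
    terminal bases vote per position on the extension; bases are appended
    while at least ``min_support`` reads agree by strict majority.  Contigs
    whose ends mutually overlap are merged; a contig whose own two ends
    overlap by >= ``min_overlap`` is trimmed and marked closed (circular).
    Terminates when nothing changes.  Conflicting extensions with equal
    support halt that end, with the ambiguity logged.
    """
    if min_overlap < 20:
        raise ValueError("min_overlap must be >= 20")
    pool = [r.seq if isinstance(r, FastqRead) else str(r) for r in reads]
    idx = _ReadIndex(pool, min_overlap)
    work = [
        c if isinstance(c, Contig) else Contig(sequence=str(c)) for c in contigs
    ]

    for _ in range(max_rounds):
        changed = False
        for c in work:
            if c.closed:
                continue
            # right end
            ext, ambiguous = _vote_extension(
                c.sequence, idx, min_support, min_identity
            )
            if ambiguous:
                log.info("ambiguous extension halted at right end of contig")
            if ext:
                c.sequence += ext
                c.support = np.concatenate(
                    [c.support, np.full(len(ext), min_support, dtype=np.int32)]
                )
                changed = True
            # left end via reverse complement
            rc = revcomp(c.sequence)
            ext, ambiguous = _vote_extension(rc, idx, min_support, min_identity)
            if ambiguous:
                log.info("ambiguous extension halted at left end of contig")
            if ext:
                c.sequence = revcomp(rc + ext)
                c.support = np.concatenate(
                    [np.full(len(ext), min_support, dtype=np.int32), c.support]
                )
                changed = True
            closed_seq = _try_close(c.sequence, min_overlap)
            if closed_seq is not None:
                c.sequence = closed_seq
                c.support = c.support[: len(closed_seq)]
                c.closed = True
                changed = True

        # pairwise merging of mutually overlapping contig ends
        merged = True
        while merged:
            merged = False
            for i in range(len(work)):
                for j in range(len(work)):
                    if i == j or work[i].closed or work[j].closed:
                        continue
                    for bseq in (work[j].sequence, revcomp(work[j].sequence)):
                        m = _try_merge(work[i].sequence, bseq, min_overlap)
                        if m is not None:
                            work[i].sequence = m
                            work[i].support = np.ones(len(m), dtype=np.int32)
                            del work[j]
                            merged = True
                            changed = True
                            break
                    if merged:
                        break
                if merged:
                    break
        if not changed:
            break
    return work


def canonicalize_closed(contig: Contig | str) -> str:
    """Canonical rotation/strand of a closed circular contig: the
    lexicographically least rotation of the lexicographically smaller
    strand.  Two closed contigs describe the same molecule iff their
    canonical forms are equal."""
    seq = contig.sequence if isinstance(contig, Contig) else str(contig)
    return canonical_circular(seq)
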