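"""Quadripartite architecture, dispersed repeats, and small inversions.

Plastid genomes of most angiosperms carry two large exact inverted
repeats (IRa/IRb) separating a large and a small single-copy region
(LSC/SSC).  This module locates that architecture on a circular sequence,
reports the gene context of the four junctions (JLB, JSB, JSA, JLA),
finds dispersed forward/inverted repeats under a Hamming-distance budget
(REPuter-style maximal k-mismatch repeats), and detects small inversions:
short loops flanked by an inverted-repeat stem that fold into hairpins.

Coordinates in all public records are 1-based inclusive; internal
arithmetic is 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import is_complement, revcomp, seq_to_u8
from .genome import GeneModel

# ---------------------------------------------------------------------------
# quadripartite layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadripartiteLayout:
    """Quadripartite regions on the input coordinates.

    Each region is ``(start0, length)`` with ``start0`` 0-based on the
    (possibly rotated) input circle; regions may wrap the origin.
    Junction positions are 1-based: the last base of the upstream region
    at each boundary, in the order LSC|IRb (JLB), IRb|SSC (JSB),
    SSC|IRa (JSA), IRa|LSC (JLA).
    """

    genome_len: int
    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]

    @property
    def lsc_len(self) -> int:
        return self.lsc[1]

    @property
    def ssc_len(self) -> int:
        return self.ssc[1]

    @property
    def ir_len(self) -> int:
        return self.irb[1]

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def _end1(self, region: tuple[int, int]) -> int:
        start, length = region
        return (start + length - 1) % self.genome_len + 1

    @property
    def junctions(self) -> dict[str, int]:
        return {
            "JLB": self._end1(self.lsc),
            "JSB": self._end1(self.irb),
            "JSA": self._end1(self.ssc),
            "JLA": self._end1(self.ira),
        }


def _extend_ir_pair(seq: str, a: int, b: int, length: int) -> tuple[int, int, int]:
    """Maximally extend an inverted pair copy1=[a,a+L), copy2=[b,b+L) on the
    circle, keeping seq[a:a+L] == revcomp(seq[b:b+L]) and the copies
    disjoint.  Returns (a, b, L)."""
    n = len(seq)

    def sep_after(a, b, L):  # gap from end of copy1 to start of copy2
        return (b - (a + L)) % n

    def sep_before(a, b, L):  # gap from end of copy2 to start of copy1
        return (a - (b + L)) % n

    # grow right end of copy1 together with left end of copy2
    while sep_after(a, b, length) > 0 and is_complement(
        seq[(a + length) % n], seq[(b - 1) % n]
    ):
        length += 1
        b = (b - 1) % n
    # grow left end of copy1 together with right end of copy2
    while sep_before(a, b, length) > 0 and is_complement(
        seq[(a - 1) % n], seq[(b + length) % n]
    ):
        a = (a - 1) % n
        length += 1
    return a, b, length


def detect_quadripartite(
    seq: str, min_ir_len: int = 1000
) -> Optional[QuadripartiteLayout]:
    """Locate the maximal exact inverted-repeat pair of length >=
    ``min_ir_len`` on the circular sequence and derive the quadripartite
    layout (larger single-copy interval labelled LSC; the IR copy
    immediately downstream of the LSC end labelled IRb).

    Returns None when no qualifying IR exists ("no quadripartite
    structure"), never raises for that case.
    """
    n = len(seq)
    if n < 1000:
        raise ValueError("genome shorter than 1 kb")
    k = min(24, max(8, min_ir_len // 4))
    s2 = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(s2[i : i + k], []).append(i)

    step = max(1, min_ir_len // 3)
    best: Optional[tuple[int, int, int]] = None
    seen: set[tuple[int, int]] = set()
    for i in range(0, n, step):
        target = revcomp(s2[i : i + k])
        for p in index.get(target, []):
            if (i, p) in seen or (p, i) in seen:
                continue
            a, b, L = _extend_ir_pair(seq, i, p, k)
            seen.add((a, b))
            # the two copies must be disjoint arcs
            if L * 2 > n:
                continue
            if best is None or L > best[2]:
                best = (a, b, L)
    if best is None or best[2] < min_ir_len:
        return None
    a, b, L = best
    gap1 = (b - (a + L)) % n  # arc after copy1, before copy2
    gap2 = (a - (b + L)) % n  # arc after copy2, before copy1
    if gap1 + gap2 + 2 * L != n:
        return None  # overlapping copies; not a quadripartite architecture
    if gap1 >= gap2:
        lsc = ((a + L) % n, gap1)
        irb = (b, L)
        ssc = ((b + L) % n, gap2)
        ira = (a, L)
    else:
        lsc = ((b + L) % n, gap2)
        irb = (a, L)
        ssc = ((a + L) % n, gap1)
        ira = (b, L)
    return QuadripartiteLayout(n, lsc=lsc, irb=irb, ssc=ssc, ira=ira)


# ---------------------------------------------------------------------------
# junction gene context
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionContext:
    junction: str
    side: str  # "left" (upstream of the boundary) or "right"
    gene: str
    strand: str
    distance: Optional[int]  # bp from gene to boundary; None if spanning
    overlap: Optional[int]  # bp of the gene beyond the boundary; None if not


def junction_report(
    layout: QuadripartiteLayout, annotation: Sequence[GeneModel]
) -> list[JunctionContext]:
    """Nearest gene on each side of each junction, with its distance to
    the boundary, or the overlap length when the gene spans it."""
    if not annotation:
        warnings.warn("empty annotation: junction contexts are empty")
        return []
    n = layout.genome_len
    out = []
    for name, j1 in layout.junctions.items():
        c = j1 % n  # 0-based boundary coordinate: between index c-1 and c
        spanning = [g for g in annotation if g.span[0] < c < g.span[1]]
        # left side: gene whose end is nearest upstream of the boundary
        left = None
        if spanning:
            g = max(spanning, key=lambda g: g.span[1])
            left = JunctionContext(name, "left", g.name, g.strand, None, g.span[1] - c)
        else:
            cands = [(( c - g.span[1]) % n, g) for g in annotation]
            d, g = min(cands, key=lambda t: t[0])
            left = JunctionContext(name, "left", g.name, g.strand, d, None)
        out.append(left)
        right = None
        if spanning:
            g = min(spanning, key=lambda g: g.span[0])
            right = JunctionContext(name, "right", g.name, g.strand, None, c - g.span[0])
        else:
            cands = [((g.span[0] - c) % n, g) for g in annotation]
            d, g = min(cands, key=lambda t: t[0])
            right = JunctionContext(name, "right", g.name, g.strand, d, None)
        out.append(right)
    return out


# ---------------------------------------------------------------------------
# dispersed repeats (maximal k-mismatch repeat pairs)
# ---------------------------------------------------------------------------


@dataclass
class RepeatHit:
    unit_len: int
    start1: int  # 1-based
    start2: int  # 1-based
    type: str  # "F" (forward) or "I" (inverted)
    mismatches: int
    loc1: str = ""
    loc2: str = ""

    def intervals0(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.start1 - 1, self.start1 - 1 + self.unit_len),
            (self.start2 - 1, self.start2 - 1 + self.unit_len),
        )


def _maximal_windows(
    mm: np.ndarray, m_len: int, budget: int, min_len: int = 1
) -> list[tuple[int, int]]:
    """Maximal windows over a diagonal of length ``m_len`` holding at most
    ``budget`` of the mismatch positions ``mm`` (sorted), keeping only
    windows of length >= ``min_len``.  A window is maximal when extending
    either side would add a mismatch beyond the budget or run off the
    diagonal."""
    if len(mm) <= budget:
        return [(0, m_len)] if m_len >= min_len else []
    ext = np.concatenate(([-1], mm, [m_len]))
    starts = ext[: len(ext) - budget - 1] + 1
    ends = ext[budget + 1 :]
    sel = np.flatnonzero(ends - starts >= min_len)
    return [(int(starts[i]), int(ends[i])) for i in sel]


def find_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    exclude: Iterable[tuple[int, int]] = (),
    annotation: Optional[Sequence[GeneModel]] = None,
    circular: bool = False,
) -> list[RepeatHit]:
    """All maximal forward and inverted repeat pairs with unit length >=
    ``min_len`` and Hamming distance <= ``max_mismatch``.

    Pairs with both copies fully inside the ``exclude`` intervals (0-based
    half-open) are suppressed — used to mask the genome-scale IR
    duplication itself.  Hits whose two copies are both contained in a
    longer hit's copies are containment-redundant and dropped.  When
    ``circular`` the sequence is linearised with a wrapped prefix so
    repeats across the origin are seen (up to the appended length).
    """
    if min_len < 10:
        raise ValueError("min_len must be >= 10")
    n0 = len(seq)
    s = seq
    if circular:
        wrap = min(n0, 4 * min_len)
        s = seq + seq[:wrap]
    n = len(s)
    if n < min_len + 1:
        return []
    a = seq_to_u8(s)
    b = seq_to_u8(revcomp(s))

    raw: dict[tuple[str, int, int, int], int] = {}

    # forward: compare s against itself shifted by d
    for d in range(1, n - min_len + 1):
        m = a[: n - d] != a[d:]
        if m.size < min_len:
            break
        mm = np.flatnonzero(m)
        for ws, we in _maximal_windows(mm, m.size, max_mismatch, min_len):
            mis = int(((mm >= ws) & (mm < we)).sum())
            raw[("F", ws, ws + d, we - ws)] = mis

    # inverted: forward windows between s and revcomp(s).  A window at
    # (i, t, L) there corresponds to copies at starts (i, n - t - L) here.
    for o in range(-(n - min_len), n - min_len + 1):
        if o >= 0:
            x, y, base = a[: n - o], b[o:], 0
        else:
            x, y, base = a[-o:], b[: n + o], -o
        m = x != y
        if m.size < min_len:
            continue
        mm = np.flatnonzero(m)
        for ws, we in _maximal_windows(mm, m.size, max_mismatch, min_len):
            L = we - ws
            i = base + ws
            t = i + o
            j = n - t - L
            if j < 0:
                continue
            s1, s2 = min(i, j), max(i, j)
            if s1 == s2 and i == j:
                continue  # self-reverse-complementary window
            mis = int(((mm >= ws) & (mm < we)).sum())
            raw[("I", s1, s2, L)] = mis

    hits = [
        RepeatHit(unit_len=L, start1=s1 + 1, start2=s2 + 1, type=t, mismatches=mis)
        for (t, s1, s2, L), mis in raw.items()
    ]

    if circular:
        folded: dict[tuple[str, int, int, int], RepeatHit] = {}
        for h in hits:
            s1 = (h.start1 - 1) % n0
            s2 = (h.start2 - 1) % n0
            s1, s2 = min(s1, s2), max(s1, s2)
            key = (h.type, s1, s2, h.unit_len)
            if key not in folded:
                h.start1, h.start2 = s1 + 1, s2 + 1
                folded[key] = h
        hits = list(folded.values())

    hits = _suppress_contained(hits)

    excl = sorted(exclude)
    if excl:
        hits = [
            h
            for h in hits
            if not all(_covered(iv, excl) for iv in h.intervals0())
        ]

    if annotation:
        for h in hits:
            (a1, b1), (a2, b2) = h.intervals0()
            h.loc1 = classify_location(a1, b1, annotation)
            h.loc2 = classify_location(a2, b2, annotation)

    hits.sort(key=lambda h: (h.start1, h.start2, -h.unit_len))
    return hits


def _covered(interval: tuple[int, int], sorted_intervals: list[tuple[int, int]]) -> bool:
    s, e = interval
    pos = s
    for a, b in sorted_intervals:
        if a <= pos < b:
            pos = max(pos, min(e, b))
            if pos >= e:
                return True
    return pos >= e


def _suppress_contained(hits: list[RepeatHit]) -> list[RepeatHit]:
    hits = sorted(hits, key=lambda h: -h.unit_len)
    kept: list[RepeatHit] = []
    for h in hits:
        (a1, b1), (a2, b2) = h.intervals0()
        redundant = False
        for k in kept:
            if k.type != h.type:
                continue
            (c1, d1), (c2, d2) = k.intervals0()
            if c1 <= a1 and b1 <= d1 and c2 <= a2 and b2 <= d2 and k.unit_len > h.unit_len:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def classify_location(
    start0: int, end0: int, annotation: Sequence[GeneModel]
) -> str:
    """Annotation class of an interval: a gene name when inside an exon,
    ``intron(gene)`` when inside a gene span but not its exons, otherwise
    ``IGS(left-right)`` naming the flanking genes."""
    for g in annotation:
        for p in g.parts:
            if p.start <= start0 and end0 <= p.end:
                return g.name
    for g in annotation:
        ga, gb = g.span
        if ga <= start0 and end0 <= gb:
            return f"intron({g.name})"
    for g in annotation:
        ga, gb = g.span
        if ga < end0 and start0 < gb:
            return f"{g.name}*"  # partly inside the gene
    lefts = [(start0 - g.span[1], g) for g in annotation if g.span[1] <= start0]
    rights = [(g.span[0] - end0, g) for g in annotation if g.span[0] >= end0]
    left = min(lefts, key=lambda t: t[0])[1].name if lefts else "start"
    right = min(rights, key=lambda t: t[0])[1].name if rights else "end"
    return f"IGS({left}-{right})"


# ---------------------------------------------------------------------------
# small inversions (stem-loop hairpins)
# ---------------------------------------------------------------------------


@dataclass
class SmallInversion:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    stem_len: int
    loop_len: int
    sequence: str
    score: float
    status: str = "putative"  # "confirmed" once homology support exists
    homology_support: list[tuple[str, float, str]] = field(default_factory=list)
    location: str = ""

    @property
    def span_len(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SmallInversionResult:
    confirmed: list[SmallInversion]
    putative: list[SmallInversion]

    def all(self) -> list[SmallInversion]:
        return self.confirmed + self.putative


def hairpin_score(
    sequence: str,
    stem_len: Optional[int] = None,
    loop_penalty: float = 0.5,
    max_mismatch: int = 0,
) -> float:
    """Simple additive stability score for a stem-loop candidate: each
    paired G:C contributes -3, each A:T -2, plus a loop-size penalty
    ``loop_penalty * max(0, loop_len - 4)``.  More negative is more
    stable.  Stems with more than ``max_mismatch`` non-complementary
    positions score +inf (rejected).  When ``stem_len`` is omitted the
    maximal perfect inverted flank of the sequence is used."""
    s = sequence.upper()
    if stem_len is None:
        stem_len = 0
        while (
            stem_len < len(s) // 2
            and is_complement(s[stem_len], s[len(s) - 1 - stem_len])
        ):
            stem_len += 1
    if stem_len == 0 or 2 * stem_len > len(s):
        return float("inf")
    loop_len = len(s) - 2 * stem_len
    stacking = 0.0
    mismatches = 0
    for t in range(stem_len):
        b1, b2 = s[t], s[len(s) - 1 - t]
        if is_complement(b1, b2):
            stacking += 3.0 if b1 in "GC" else 2.0
        else:
            mismatches += 1
    if mismatches > max_mismatch:
        return float("inf")
    return -stacking + loop_penalty * max(0, loop_len - 4)


def find_small_inversions(
    seq: str,
    stem_range: tuple[int, int] = (11, 24),
    max_loop: int = 50,
    comparators: Iterable[tuple[str, str]] = (),
    min_homology: float = 0.90,
    max_stem_mismatch: int = 0,
    score_threshold: float = -10.0,
    loop_penalty: float = 0.5,
    annotation: Optional[Sequence[GeneModel]] = None,
) -> SmallInversionResult:
    """Three-stage small-inversion detection.

    (i) enumerate maximal inverted-repeat stems with length inside
    ``stem_range`` separated by a loop shorter than ``max_loop``;
    (ii) keep candidates whose hairpin score is at or below
    ``score_threshold`` (a stable stem-loop), resolving overlaps in
    favour of the most stable candidate; (iii) align each survivor to the
    ``comparators`` (name, sequence) — a candidate matching at least one
    comparator at >= ``min_homology`` identity over its span is confirmed
    (recording identity and loop orientation per comparator), the rest
    remain putative.
    """
    stem_min, stem_max = stem_range
    if not (5 <= stem_min <= stem_max <= 50):
        raise ValueError("stem_range must lie within [5, 50]")
    n = len(seq)
    a = seq_to_u8(seq)
    b = seq_to_u8(revcomp(seq))

    candidates: dict[tuple[int, int], SmallInversion] = {}
    for o in range(-(n - stem_min), n - stem_min + 1):
        if o >= 0:
            x, y, base = a[: n - o], b[o:], 0
        else:
            x, y, base = a[-o:], b[: n + o], -o
        if x.size < stem_min:
            continue
        mm = np.flatnonzero(x != y)
        for ws, we in _maximal_windows(mm, x.size, max_stem_mismatch, stem_min):
            L = we - ws
            if L > stem_max:
                continue
            i = base + ws
            j = n - (i + o) - L
            if j < i + L:
                continue  # overlapping or reversed copies
            loop = j - (i + L)
            if loop >= max_loop:
                continue
            span = seq[i : j + L]
            score = hairpin_score(
                span, stem_len=L, loop_penalty=loop_penalty,
                max_mismatch=max_stem_mismatch,
            )
            candidates.setdefault(
                (i, j + L),
                SmallInversion(
                    start=i + 1,
                    end=j + L,
                    stem_len=L,
                    loop_len=loop,
                    sequence=span,
                    score=score,
                ),
            )

    stable = [c for c in candidates.values() if c.score <= score_threshold]
    stable.sort(key=lambda c: (c.score, -c.stem_len, c.start))
    selected: list[SmallInversion] = []
    for c in stable:
        if all(
            c.end < k.start or k.end < c.start for k in selected
        ):
            selected.append(c)
    selected.sort(key=lambda c: c.start)

    if annotation:
        for c in selected:
            c.location = classify_location(c.start - 1, c.end, annotation)

    comparators = list(comparators)
    confirmed, putative = [], []
    for c in selected:
        for name, comp_seq in comparators:
            ident, orient = _best_span_homology(c, comp_seq)
            if ident >= min_homology:
                c.homology_support.append((name, ident, orient))
        if c.homology_support:
            c.status = "confirmed"
            confirmed.append(c)
        else:
            putative.append(c)
    return SmallInversionResult(confirmed=confirmed, putative=putative)


def _best_span_homology(si: SmallInversion, comp_seq: str) -> tuple[float, str]:
    """Best identity of the SI span against a comparator genome (either
    strand), and the orientation of the loop within the matched region
    ("same" or "inverted")."""
    import edlib

    span = si.sequence
    best = (0.0, "same")
    res = edlib.align(span, comp_seq, mode="HW", task="locations")
    candidates = [(res, comp_seq, False)]
    res_rc = edlib.align(span, revcomp(comp_seq), mode="HW", task="locations")
    candidates.append((res_rc, revcomp(comp_seq), True))
    for res, target, was_rc in candidates:
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        ident = 1.0 - res["editDistance"] / len(span)
        if ident <= best[0]:
            continue
        lo, hi = res["locations"][0]
        region = target[lo : hi + 1]
        loop = span[si.stem_len : len(span) - si.stem_len]
        fwd = edlib.align(loop, region, mode="HW")["editDistance"]
        rev = edlib.align(revcomp(loop), region, mode="HW")["editDistance"]
        orient = "same" if fwd <= rev else "inverted"
        best = (ident, orient)
    return best
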