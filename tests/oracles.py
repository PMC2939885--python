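"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorised diagonal machinery of the package:
pure-Python prefix-sum scans over diagonals (forward) and anti-diagonals
(inverted), with a bisect-based maximal-window derivation.  They are slow
but simple enough to inspect, and serve as ground truth on small inputs.
"""

from __future__ import annotations

from bisect import bisect_right

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _maximal_windows_prefix(flags: list[bool], k: int) -> set[tuple[int, int]]:
    """All maximal windows holding at most k True flags, derived via
    prefix sums + bisect (each start's rightmost end; keep starts that
    cannot move left)."""
    m = len(flags)
    prefix = [0]
    for f in flags:
        prefix.append(prefix[-1] + (1 if f else 0))
    out = set()
    for s in range(m):
        # rightmost e with prefix[e] - prefix[s] <= k
        e = bisect_right(prefix, prefix[s] + k) - 1
        e = min(e, m)
        if e <= s:
            continue
        left_blocked = s == 0 or prefix[e] - prefix[s - 1] > k
        if left_blocked:
            out.add((s, e))
    return out


def brute_force_repeats(
    seq: str, min_len: int = 30, max_mismatch: int = 3
) -> set[tuple[str, int, int, int]]:
    """All maximal repeat pairs as (type, start1, start2, unit_len) with
    1-based starts, before containment suppression."""
    n = len(seq)
    hits: set[tuple[str, int, int, int]] = set()

    # forward: diagonals at offset d
    for d in range(1, n - min_len + 1):
        m = n - d
        flags = [seq[i] != seq[i + d] for i in range(m)]
        for s, e in _maximal_windows_prefix(flags, max_mismatch):
            if e - s >= min_len:
                hits.add(("F", s + 1, s + d + 1, e - s))

    # inverted: anti-diagonals.  Pair positions (x, y) with x + y = c are
    # aligned; a window [x0, x1) of paired positions is the stem pair
    # copy1 = [x0, x1), copy2 = [c - x1 + 1, c - x0 + 1).
    for c in range(2 * n - 1):
        xs = [x for x in range(max(0, c - n + 1), min(n, c + 1))]
        if len(xs) < min_len:
            continue
        flags = [seq[x] != _COMP[seq[c - x]] for x in xs]
        base = xs[0]
        for s, e in _maximal_windows_prefix(flags, max_mismatch):
            L = e - s
            if L < min_len:
                continue
            i = base + s
            j = c - (base + e - 1)
            s1, s2 = min(i, j), max(i, j)
            if i == j:
                # a window equal to its own reverse complement is one
                # palindromic site, not a pair of repeat copies
                continue
            hits.add(("I", s1 + 1, s2 + 1, L))
    return hits


def suppress_contained_brute(
    hits: set[tuple[str, int, int, int]]
) -> set[tuple[str, int, int, int]]:
    """Drop hits whose two copies are both contained in a longer hit's
    copies (same repeat type)."""
    out = set()
    for h in hits:
        t, s1, s2, L = h
        contained = False
        for t2, u1, u2, L2 in hits:
            if t2 != t or L2 <= L:
                continue
            if u1 <= s1 and s1 + L <= u1 + L2 and u2 <= s2 and s2 + L <= u2 + L2:
                contained = True
                break
        if not contained:
            out.add(h)
    return out


def brute_force_homopolymers(seq: str, min_len: int) -> list[tuple[str, int, int]]:
    """Regex-free rescan of maximal runs, for cross-checking."""
    import re

    out = []
    for m in re.finditer(r"(A+|C+|G+|T+)", seq):
        if m.end() - m.start() >= min_len:
            out.append((m.group()[0], m.start() + 1, m.end() - m.start()))
    return out
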