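"""Low-level DNA string helpers shared across modules.

All sequences are plain upper-case DNA strings (alphabet ACGT, with N
tolerated only where a function says so).  Coordinates are 0-based
half-open internally; public report types convert to the 1-based
inclusive convention used in chloroplast genome literature.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def is_complement(a: str, b: str) -> bool:
    """True when base ``a`` pairs with base ``b`` (Watson-Crick)."""
    return a.translate(_COMPLEMENT) == b


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def random_dna(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    """Random DNA with expected A+T fraction ``at`` (A/T and G/C equiprobable
    within their class, matching the compositional symmetry of a double
    strand)."""
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(np.array(list("AGCT"))[idx])


def seq_to_u8(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def circular_slice(seq: str, start: int, length: int) -> str:
    """Slice ``length`` bases starting at ``start`` on a circular sequence."""
    n = len(seq)
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    out = seq[start:]
    # may wrap more than once for pathological lengths
    full, rest = divmod(length - (n - start), n)
    return out + seq * full + seq[:rest]


def rotate(seq: str, k: int) -> str:
    """Rotate a circular sequence so that position ``k`` becomes position 0."""
    k %= len(seq)
    return seq[k:] + seq[:k]


def least_rotation(seq: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    s = seq + seq
    n = len(s)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s[j]
        i = f[j - k - 1]
        while i != -1 and sj != s[k + i + 1]:
            if sj < s[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s[k + i + 1]:
            if sj < s[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_circular(seq: str) -> str:
    """Canonical form of a circular double-stranded sequence: the smaller of
    the least rotations of the two strands.  Two circular molecules are the
    same iff their canonical forms are equal."""
    fwd = rotate(seq, least_rotation(seq))
    rc = revcomp(seq)
    rev = rotate(rc, least_rotation(rc))
    return min(fwd, rev)


def validate_dna(seq: str, allow_n: bool = False) -> None:
    """Raise ValueError naming the first offending position if ``seq`` holds
    characters outside the DNA alphabet."""
    allowed = set("ACGTN" if allow_n else "ACGT")
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"non-DNA character {c!r} at position {i + 1}")
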