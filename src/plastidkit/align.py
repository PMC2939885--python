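"""Internal read mapper and alignment records.

A light seed-free mapper built on edlib's infix (HW) alignment: each read
is aligned to the doubled genome (so reads wrapping the circular origin
map contiguously) on both strands and the better strand wins.  CIGARs use
SAM conventions ('='/'X' consume both, 'I' consumes the query, 'D' the
reference).  This is adequate for the read lengths and error modes the
simulator produces; it is not a general-purpose aligner.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import edlib

from ._seq import revcomp
from .io import FastqRead

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class Alignment:
    query_name: str
    ref_start: int  # 0-based on the linear (unwrapped) genome; < genome length
    strand: str  # '+' if the read matched the forward strand
    cigar: list[tuple[str, int]]
    seq: str  # read sequence oriented to the reference strand
    quals: list[int]  # per-base Phred, oriented with ``seq``
    edit_distance: int

    @property
    def ref_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "=XMD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_len

    @property
    def identity(self) -> float:
        aln_len = sum(n for _, n in self.cigar)
        return 1.0 - self.edit_distance / aln_len if aln_len else 0.0

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIG_RE.findall(cigar)]


def map_read(
    read: FastqRead,
    genome: str,
    circular: bool = True,
    max_edit_frac: float = 0.35,
) -> Optional[Alignment]:
    """Best-strand infix alignment of one read.  Returns None when neither
    strand aligns within ``max_edit_frac`` errors."""
    n = len(genome)
    ref = genome + genome[: min(n, len(read.seq) + 50)] if circular else genome
    k = int(len(read.seq) * max_edit_frac)
    best = None
    for strand, qseq, quals in (
        ("+", read.seq, read.quals),
        ("-", revcomp(read.seq), read.quals[::-1]),
    ):
        res = edlib.align(qseq, ref, mode="HW", task="path", k=k)
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], strand, qseq, quals, res)
    if best is None:
        return None
    dist, strand, qseq, quals, res = best
    start, _ = res["locations"][0]
    return Alignment(
        query_name=read.name,
        ref_start=start % n,
        strand=strand,
        cigar=parse_cigar(res["cigar"]),
        seq=qseq,
        quals=list(quals),
        edit_distance=dist,
    )


def map_reads(
    reads: Iterable[FastqRead],
    genome: str,
    circular: bool = True,
    max_edit_frac: float = 0.35,
) -> list[Alignment]:
    out = []
    for read in reads:
        aln = map_read(read, genome, circular=circular, max_edit_frac=max_edit_frac)
        if aln is not None:
            out.append(aln)
    return out


def global_identity(a: str, b: str) -> float:
    """Identity of a global (NW) alignment of two sequences."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def write_sam(path: str, alignments: Iterable[Alignment], ref_name: str, ref_len: int) -> None:
    """Write alignments as plain-text SAM (via pysam)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref_name, "LN": ref_len}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for aln in alignments:
            rec = pysam.AlignedSegment(fh.header)
            rec.query_name = aln.query_name
            rec.reference_id = 0
            rec.reference_start = aln.ref_start
            rec.flag = 16 if aln.strand == "-" else 0
            rec.query_sequence = aln.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in aln.quals)
            )
            rec.cigarstring = aln.cigar_string().replace("=", "M").replace("X", "M")
            rec.mapping_quality = 60
            fh.write(rec)


def read_sam(path: str, genome: str) -> list[Alignment]:
    """Load alignments from a SAM file into the internal record type.

    M operations are resolved into '='/'X' against the given reference so
    downstream pileups can distinguish matches from substitutions.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            cigar: list[tuple[str, int]] = []
            qpos, rpos = 0, rec.reference_start
            qseq = rec.query_sequence
            tuples = list(rec.cigartuples)
            # trim soft clips off the stored sequence so cigar walks line up
            if tuples and tuples[0][0] == 4:
                qseq = qseq[tuples[0][1] :]
                tuples = tuples[1:]
            if tuples and tuples[-1][0] == 4:
                qseq = qseq[: -tuples[-1][1]]
                tuples = tuples[:-1]
            for op, length in tuples:
                code = "MIDNSHP=XB"[op]
                if code == "M":
                    for t in range(length):
                        same = (
                            rpos + t < len(genome)
                            and qseq[qpos + t] == genome[rpos + t]
                        )
                        tag = "=" if same else "X"
                        if cigar and cigar[-1][0] == tag:
                            cigar[-1] = (tag, cigar[-1][1] + 1)
                        else:
                            cigar.append((tag, 1))
                    qpos += length
                    rpos += length
                elif code in "=X":
                    cigar.append((code, length))
                    qpos += length
                    rpos += length
                elif code == "I":
                    cigar.append(("I", length))
                    qpos += length
                elif code == "D":
                    cigar.append(("D", length))
                    rpos += length
                elif code == "S":
                    qpos += length  # soft clip: drop
            if rec.query_qualities is not None:
                full = list(rec.query_qualities)
                off = len(rec.query_sequence) - len(qseq)
                lead = rec.cigartuples[0][1] if rec.cigartuples[0][0] == 4 else 0
                quals = full[lead : lead + len(qseq)] if off else full
            else:
                quals = [30] * len(qseq)
            out.append(
                Alignment(
                    query_name=rec.query_name,
                    ref_start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=cigar,
                    seq=qseq,
                    quals=quals,
                    edit_distance=sum(n for op, n in cigar if op in "XID"),
                )
            )
    return out
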