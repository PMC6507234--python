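"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base loops, position-by-position
scans) and shares no code with the package internals it verifies.
"""

from __future__ import annotations

_REF_OPS = set("MDN=X")
_ALIGNED = set("M=X")

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},
}


def cigar_gaps(pos: int, cigar) -> list[tuple[int, int]]:
    """Reference intervals of every N op, by a plain CIGAR walk."""
    gaps = []
    ref = pos
    for op, n in cigar:
        if op == "N":
            gaps.append((ref, ref + n))
        if op in _REF_OPS:
            ref += n
    return gaps


def tally_junctions(reads, strand: str, min_intron: int) -> dict[tuple[int, int], int]:
    """Brute-force (donor, acceptor) -> count over all reads' N gaps."""
    if strand == ".":
        strand = "+"
    tally: dict[tuple[int, int], int] = {}
    for read in reads:
        for g0, g1 in cigar_gaps(read.pos, read.cigar):
            if g1 - g0 < min_intron:
                continue
            if strand == "+":
                key = (g0 - 1, g1)
            else:
                key = (g1, g0 - 1)
            tally[key] = tally.get(key, 0) + 1
    return tally


def aligned_positions(pos: int, cigar) -> list[int]:
    """Every reference position covered by an aligned (M/=/X) base."""
    out = []
    ref = pos
    for op, n in cigar:
        if op in _ALIGNED:
            out.extend(range(ref, ref + n))
            ref += n
        elif op in ("D", "N"):
            ref += n
    return out


def per_base_depth(reads, start: int, end: int) -> list[int]:
    """Depth at each position of [start, end), counted base by base."""
    depth = [0] * (end - start)
    for read in reads:
        for p in aligned_positions(read.pos, read.cigar):
            if start <= p < end:
                depth[p - start] += 1
    return depth


def naive_motif_scan(sequence: str, consensus: str) -> list[int]:
    """Position-by-position IUPAC consensus matching, overlaps included."""
    sequence = sequence.upper().replace("U", "T")
    consensus = consensus.upper().replace("U", "T")
    m = len(consensus)
    hits = []
    for i in range(len(sequence) - m + 1):
        if all(sequence[i + k] in IUPAC_SETS[consensus[k]] for k in range(m)):
            hits.append(i)
    return hits


def interval_union_membership(intervals, lo: int, hi: int) -> list[bool]:
    """Per-base OR of interval membership over [lo, hi)."""
    member = [False] * (hi - lo)
    for iv in intervals:
        for p in range(max(iv.start, lo), min(iv.end, hi)):
            member[p - lo] = True
    return member
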