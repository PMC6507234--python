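"""Core genomic domain types shared by every other module.

All coordinates are 0-based, half-open ``[start, end)`` internally; the
1-based-inclusive GTF convention and the half-open BED convention are
converted at the I/O boundary (:mod:`splicearc.io`).  Splice junctions are
stored as a (donor, acceptor) pair of *base* coordinates: the donor is the
last transcribed exonic base before the intron, the acceptor the first
transcribed exonic base after it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")

FORWARD = "forward"
BACK = "back"


def effective_strand(strand: str) -> str:
    """Resolve an unstranded ('.') record to '+' with a warning.

    Unstranded junction BEDs exist in the wild; donor/acceptor orientation
    then defaults to the '+' convention.
    """
    if strand == ".":
        logger.warning("unstranded record: treating '.' as '+' for orientation")
        return "+"
    return strand


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on one chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        """Intersection with *other*, or None when disjoint."""
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )


def collapse_exons(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union a set of exon intervals into maximal disjoint intervals.

    Overlapping and book-ended (``[a,b) + [b,c)``) intervals merge; at
    per-base resolution adjacent exons are indistinguishable.  Inputs must
    share one chromosome and strand.

    Returns the merged intervals sorted by ascending start.
    """
    if not intervals:
        return []
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"cannot collapse exons from mixed chromosomes: {sorted(chroms)}")
    if len(strands) > 1:
        raise ValueError(f"cannot collapse exons from mixed strands: {sorted(strands)}")

    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:  # overlap or adjacency
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass(frozen=True)
class GeneModel:
    """Collapsed single-exon-chain model of one gene.

    ``exons`` are disjoint, ascending, and all lie within ``interval``;
    multi-isoform annotations are collapsed to their exon union before
    construction (one exon chain per gene is plotted).
    """

    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.name!r} has no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(
                    f"exon {ex} does not match gene interval chrom/strand"
                )
            if not (self.interval.start <= ex.start and ex.end <= self.interval.end):
                raise ValueError(f"exon {ex} outside gene interval {self.interval}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError("exons overlap or are unsorted after collapse")
            prev_end = ex.end

    @classmethod
    def from_exons(
        cls, name: str, exons: Iterable[GenomicInterval]
    ) -> "GeneModel":
        """Build a model from raw (possibly overlapping) exon intervals."""
        collapsed = collapse_exons(list(exons))
        if not collapsed:
            raise ValueError(f"gene {name!r} has no exons")
        interval = GenomicInterval(
            collapsed[0].chrom,
            collapsed[0].start,
            collapsed[-1].end,
            collapsed[0].strand,
        )
        return cls(name=name, interval=interval, exons=tuple(collapsed))

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive collapsed exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out


@dataclass(frozen=True)
class SpliceJunction:
    """One donor→acceptor splicing event with supporting-read count.

    ``kind`` is 'forward' for a canonical linear junction and 'back' for a
    back-splice (the circRNA-producing junction fusing a downstream donor to
    an upstream acceptor).  ``novel`` marks endpoints that did not coincide
    with an annotated exon boundary during snapping; they are rendered at
    their true position so cryptic sites stay visible.
    """

    chrom: str
    donor: int
    acceptor: int
    strand: str
    count: int
    kind: str
    novel: bool = False

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("junction donor and acceptor coincide")
        if self.count < 0:
            raise ValueError("junction count must be >= 0")
        if self.kind not in (FORWARD, BACK):
            raise ValueError(f"invalid junction kind {self.kind!r}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def left(self) -> int:
        return min(self.donor, self.acceptor)

    @property
    def right(self) -> int:
        return max(self.donor, self.acceptor)


@dataclass
class SampleBundle:
    """One sample's tracks: coverage, junction sets, normalized exon values.

    A bundle may mix tracks from different library preparations (e.g.
    coverage from a poly(A)-selected library with back-splice junctions from
    an RNase-R treated one), so the two junction sets stay separate.
    """

    label: str
    coverage: "object"  # CoverageVector; typed loosely to avoid an import cycle
    forward_junctions: tuple[SpliceJunction, ...] = ()
    back_junctions: tuple[SpliceJunction, ...] = ()
    exon_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.exon_values is not None:
            for v in self.exon_values:
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"normalized exon intensity {v} outside [0, 1]"
                    )
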