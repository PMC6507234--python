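"""Forward-junction extraction, back-splice classification and filtering.

Forward (canonical) junctions are read directly off the N gaps of spliced
alignments; back-splice junctions normally arrive as BED output of an
external caller (e.g. find_circ) and are imported here.  The two evidence
sources are kept in separate tracks — the tool never merges them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import AlignedRead, JunctionRecord
from .model import (
    BACK,
    FORWARD,
    GeneModel,
    GenomicInterval,
    SpliceJunction,
    effective_strand,
)

logger = logging.getLogger(__name__)

#: Reference gaps shorter than this are treated as deletions, not introns.
DEFAULT_MIN_INTRON = 20


@dataclass
class JunctionSet:
    """Junctions of one gene region, keyed by the exact (donor, acceptor) pair."""

    region: GenomicInterval
    junctions: dict[tuple[int, int], SpliceJunction] = field(default_factory=dict)

    def add(self, j: SpliceJunction) -> None:
        if j.chrom != self.region.chrom:
            raise ValueError(
                f"junction on {j.chrom} does not belong to region on {self.region.chrom}"
            )
        key = (j.donor, j.acceptor)
        existing = self.junctions.get(key)
        if existing is None:
            self.junctions[key] = j
        else:
            self.junctions[key] = SpliceJunction(
                j.chrom,
                j.donor,
                j.acceptor,
                existing.strand,
                existing.count + j.count,
                existing.kind,
                existing.novel or j.novel,
            )

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(sorted(self.junctions.values(), key=lambda j: (j.left, j.right)))

    def total_count(self) -> int:
        return sum(j.count for j in self.junctions.values())


def classify_backsplice(donor: int, acceptor: int, strand: str) -> str:
    """Classify a junction as 'forward' or 'back' from donor/acceptor order.

    A back-splice fuses a downstream donor to an upstream acceptor, which on
    the '+' strand means the donor's genomic coordinate exceeds the
    acceptor's; on '-' the orientation is mirrored.  Strand '.' falls back to
    the '+' convention with a warning.
    """
    strand = effective_strand(strand)
    if strand == "+":
        return BACK if donor > acceptor else FORWARD
    return BACK if donor < acceptor else FORWARD


def gap_to_donor_acceptor(gap_start: int, gap_end: int, strand: str) -> tuple[int, int]:
    """Donor/acceptor base coordinates of the intron ``[gap_start, gap_end)``.

    On '+' the donor is the last exonic base before the gap and the acceptor
    the first base after it; on '-' the roles swap.
    """
    strand = effective_strand(strand)
    if strand == "+":
        return gap_start - 1, gap_end
    return gap_end, gap_start - 1


def extract_forward_junctions(
    reads: Iterable[AlignedRead],
    region: GenomicInterval,
    *,
    min_intron: int = DEFAULT_MIN_INTRON,
) -> JunctionSet:
    """Tally one junction per distinct N gap over the reads of *region*.

    Each read contributes one observation per N gap of length >= *min_intron*
    (shorter gaps are deletions); the junction count is the number of reads
    exhibiting that exact gap.  Junction identity is the exact
    (donor, acceptor) pair — no fuzzy merging, so cryptic sites keep their
    single-nucleotide resolution.
    """
    js = JunctionSet(region)
    for read in reads:
        if read.chrom != region.chrom:
            continue
        for g0, g1 in read.reference_gaps():
            if g1 - g0 < min_intron:
                continue
            donor, acceptor = gap_to_donor_acceptor(g0, g1, region.strand)
            js.add(
                SpliceJunction(
                    read.chrom, donor, acceptor, region.strand, 1, FORWARD
                )
            )
    return js


def import_backsplice_bed(
    records: Iterable[JunctionRecord], gene: GeneModel
) -> JunctionSet:
    """Convert caller-emitted back-splice BED rows into a back JunctionSet.

    A back-splice BED row spans the circularized block, so on '+' the
    acceptor sits at ``start`` and the donor at ``end - 1`` (mirrored on
    '-').  Records outside the gene interval are dropped and the number of
    drops logged.
    """
    js = JunctionSet(gene.interval)
    strand = effective_strand(gene.strand)
    dropped = 0
    for rec in records:
        iv_overlaps = (
            rec.chrom == gene.chrom
            and rec.start < gene.interval.end
            and gene.interval.start < rec.end
        )
        if not iv_overlaps:
            dropped += 1
            continue
        if strand == "+":
            donor, acceptor = rec.end - 1, rec.start
        else:
            donor, acceptor = rec.start, rec.end - 1
        js.add(SpliceJunction(rec.chrom, donor, acceptor, gene.strand, rec.count, BACK))
    if dropped:
        logger.info("import_backsplice_bed: dropped %d records outside gene", dropped)
    return js


def filter_junctions(js: JunctionSet, min_count: int) -> JunctionSet:
    """Return a new set keeping junctions with count >= *min_count*."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = JunctionSet(js.region)
    for j in js.junctions.values():
        if j.count >= min_count:
            out.add(j)
    return out


def snap_to_exons(js: JunctionSet, gene: GeneModel, tolerance: int) -> JunctionSet:
    """Snap junction endpoints onto nearby collapsed-exon boundaries.

    An endpoint within *tolerance* nt of an exon edge (an exon's first base
    for acceptor-like edges, last base for donor-like edges; both edge kinds
    are candidates) is moved onto the nearest edge.  Endpoints farther away
    are kept verbatim and the junction is flagged ``novel`` — this is what
    keeps cryptic splice sites visible at their true position.  Tolerance 0
    is the identity.  Total count mass is conserved (junctions that collide
    after snapping merge their counts).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    out = JunctionSet(js.region)
    if tolerance == 0:
        for j in js.junctions.values():
            out.add(j)
        return out

    boundaries = sorted(
        {ex.start for ex in gene.exons} | {ex.end - 1 for ex in gene.exons}
    )

    def snap(pos: int) -> tuple[int, bool]:
        best = min(boundaries, key=lambda b: (abs(b - pos), b))
        if abs(best - pos) <= tolerance:
            return best, False
        return pos, True

    for j in js.junctions.values():
        donor, donor_novel = snap(j.donor)
        acceptor, acc_novel = snap(j.acceptor)
        if donor == acceptor:  # degenerate after snapping; keep verbatim
            out.add(j)
            continue
        out.add(
            SpliceJunction(
                j.chrom,
                donor,
                acceptor,
                j.strand,
                j.count,
                j.kind,
                novel=j.novel or donor_novel or acc_novel,
            )
        )
    return out
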