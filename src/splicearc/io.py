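"""Readers and writers for GTF, BED and SAM/BAM.

Conventions enforced at this boundary:

* GTF is 1-based inclusive; internal coordinates are 0-based half-open.
* BED is already 0-based half-open; the score column carries the junction
  read count (as back-splice callers such as find_circ emit).
* Alignment files are accessed through their index, region-restricted, and
  strictly one file at a time; the module tracks how many alignment files
  are simultaneously open so the sequential-access contract is observable.
"""

from __future__ import annotations

import difflib
import logging
import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

from .model import (
    BACK,
    FORWARD,
    GeneModel,
    GenomicInterval,
    SpliceJunction,
    collapse_exons,
)

logger = logging.getLogger(__name__)

# CIGAR op codes as emitted by pysam.cigartuples
_CIGAR_CODE_TO_OP = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 6: "P", 7: "=", 8: "X"}
_REF_CONSUMING = frozenset("MDN=X")
_ALIGNED_OPS = frozenset("M=X")

# --- sequential-access instrumentation ------------------------------------

_open_alignment_files = 0
_peak_open_alignment_files = 0


def reset_open_file_stats() -> None:
    """Zero the open-alignment-file counters (call before an audited run)."""
    global _open_alignment_files, _peak_open_alignment_files
    _open_alignment_files = 0
    _peak_open_alignment_files = 0


def peak_open_alignment_files() -> int:
    """Maximum number of alignment files simultaneously open since reset."""
    return _peak_open_alignment_files


def _track_open() -> None:
    global _open_alignment_files, _peak_open_alignment_files
    _open_alignment_files += 1
    _peak_open_alignment_files = max(_peak_open_alignment_files, _open_alignment_files)


def _track_close() -> None:
    global _open_alignment_files
    _open_alignment_files -= 1


# --- domain records --------------------------------------------------------


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read reduced to what junction/coverage extraction needs."""

    query_name: str
    chrom: str
    pos: int  # 0-based leftmost aligned reference base
    cigar: tuple[tuple[str, int], ...]
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if not self.cigar:
            raise ValueError("CIGAR must be non-empty")
        if self.reference_length() < 1:
            raise ValueError("read consumes no reference bases")
        for op, length in self.cigar:
            if op not in _CIGAR_CODE_TO_OP.values():
                raise ValueError(f"unknown CIGAR op {op!r}")
            if length <= 0:
                raise ValueError("CIGAR op length must be positive")

    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @property
    def reference_end(self) -> int:
        return self.pos + self.reference_length()

    def aligned_blocks(self) -> list[tuple[int, int]]:
        """Reference intervals covered by aligned (M/=/X) bases."""
        blocks = []
        ref = self.pos
        for op, n in self.cigar:
            if op in _ALIGNED_OPS:
                blocks.append((ref, ref + n))
                ref += n
            elif op in ("D", "N"):
                ref += n
        return blocks

    def reference_gaps(self) -> list[tuple[int, int]]:
        """Reference intervals skipped by N ops (candidate introns)."""
        gaps = []
        ref = self.pos
        for op, n in self.cigar:
            if op == "N":
                gaps.append((ref, ref + n))
            if op in _REF_CONSUMING:
                ref += n
        return gaps


@dataclass(frozen=True)
class JunctionRecord:
    """One BED junction row: a half-open span plus a read count."""

    chrom: str
    start: int
    end: int
    name: str
    count: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"junction record start {self.start} >= end {self.end}")
        if self.count < 0:
            raise ValueError("junction count must be >= 0")


# --- coordinate-convention helpers -----------------------------------------


def gtf_span_to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """GTF 1-based inclusive span -> 0-based half-open."""
    return start_1based - 1, end_inclusive


def internal_span_to_gtf(start: int, end: int) -> tuple[int, int]:
    """0-based half-open span -> GTF 1-based inclusive."""
    return start + 1, end


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def parse_gene_annotation(path: str | Path, gene_name: str) -> GeneModel:
    """Build the collapsed :class:`GeneModel` for one gene from a GTF file.

    Matching is case-sensitive against ``gene_id`` first, then ``gene_name``.
    All "exon" feature lines of the matched gene are collapsed to their
    union; the gene interval spans min(start)..max(end) of those exons.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    KeyError
        If the gene is absent (the message lists nearby candidate names).
    ValueError
        If the gene matches but contributes zero exon lines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")

    by_id: list[GenomicInterval] = []
    by_name: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = _parse_gtf_attributes(attrs)
            gid = attr.get("gene_id", "")
            gname = attr.get("gene_name", "")
            seen.update(x for x in (gid, gname) if x)
            if gid != gene_name and gname != gene_name:
                continue
            s, e = gtf_span_to_internal(int(start), int(end))
            iv = GenomicInterval(chrom, s, e, strand)
            (by_id if gid == gene_name else by_name).append(iv)

    exons = by_id or by_name
    if not exons:
        if gene_name in seen:
            raise ValueError(f"gene {gene_name!r} has no exon lines in {path}")
        candidates = difflib.get_close_matches(gene_name, sorted(seen), n=5, cutoff=0.3)
        hint = f"; nearby names: {', '.join(candidates)}" if candidates else ""
        raise KeyError(f"gene {gene_name!r} not found in {path}{hint}")
    return GeneModel.from_exons(gene_name, exons)


def write_gene_annotation(gene: GeneModel, path: str | Path) -> None:
    """Write a minimal single-transcript GTF for *gene* (round-trip support)."""
    with open(path, "w") as fh:
        g1, g2 = internal_span_to_gtf(gene.interval.start, gene.interval.end)
        attrs = f'gene_id "{gene.name}"; gene_name "{gene.name}"; transcript_id "{gene.name}.t1";'
        fh.write(
            f"{gene.chrom}\tsplicearc\tgene\t{g1}\t{g2}\t.\t{gene.strand}\t.\t{attrs}\n"
        )
        for ex in gene.exons:
            s, e = internal_span_to_gtf(ex.start, ex.end)
            fh.write(
                f"{gene.chrom}\tsplicearc\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
            )


# --- alignment access -------------------------------------------------------


def _to_aligned_read(rec: pysam.AlignedSegment) -> AlignedRead:
    cigar = tuple((_CIGAR_CODE_TO_OP[code], n) for code, n in rec.cigartuples)
    return AlignedRead(
        query_name=rec.query_name or "",
        chrom=rec.reference_name,
        pos=rec.reference_start,
        cigar=cigar,
        strand="-" if rec.is_reverse else "+",
        mapq=rec.mapping_quality,
    )


def ensure_index(path: str | Path) -> None:
    """Create a BAM index next to *path* if one is missing."""
    path = str(path)
    for ext in (".bai", ".csi"):
        if os.path.exists(path + ext):
            return
    directory = os.path.dirname(os.path.abspath(path))
    if not os.access(directory, os.W_OK):
        raise OSError(
            f"{path} has no index and {directory} is not writable; "
            f"index the file first (samtools index)"
        )
    pysam.index(path)


def fetch_alignments(
    path: str | Path,
    region: GenomicInterval,
    *,
    min_mapq: int = 0,
    keep_duplicates: bool = False,
) -> Iterator[AlignedRead]:
    """Yield the mapped reads overlapping *region*, via the index.

    Unmapped, secondary and supplementary records are always excluded;
    duplicate-flagged reads are excluded unless *keep_duplicates*.  Reads
    with mapping quality below *min_mapq* are dropped.  Access is strictly
    region-restricted (the file is never scanned whole) and the file is
    closed as soon as the stream is exhausted, so at most one alignment
    file is open per consumed stream.
    """
    path = str(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"alignment file not found: {path}")
    ensure_index(path)
    _track_open()
    try:
        with pysam.AlignmentFile(path, "rb") as bam:
            if region.chrom not in bam.references:
                logger.warning(
                    "chromosome %s absent from %s header; empty stream",
                    region.chrom,
                    path,
                )
                return
            for rec in bam.fetch(region.chrom, region.start, region.end):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                if rec.is_duplicate and not keep_duplicates:
                    continue
                if rec.mapping_quality < min_mapq:
                    continue
                if rec.cigartuples is None:
                    continue
                yield _to_aligned_read(rec)
    finally:
        _track_close()


# --- junction BED -----------------------------------------------------------


def parse_junction_bed(path: str | Path) -> list[JunctionRecord]:
    """Parse a BED3–BED6 junction file into :class:`JunctionRecord` rows.

    Column 5 (score), when present, is the junction read count; a missing
    score yields count 0 with a warning.  ``track``/``browser``/``#`` lines
    are skipped.  Malformed rows raise with their line number.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            fields = stripped.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED row needs >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {fields[1]!r}/{fields[2]!r}"
                ) from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else f"junction_{lineno}"
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    count = int(fields[4])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer score {fields[4]!r}"
                    ) from exc
            else:
                logger.warning("%s:%d: missing score column; count set to 0", path, lineno)
                count = 0
            strand = fields[5] if len(fields) > 5 else "."
            records.append(JunctionRecord(chrom, start, end, name, count, strand))
    return records


def junction_to_record(j: SpliceJunction) -> JunctionRecord:
    """Map a junction to its BED span.

    Forward junctions span the intron ``[donor+1, acceptor)`` (in left/right
    terms ``[left+1, right)``); back-splice junctions span the circularized
    block ``[left, right+1)`` — the convention back-splice callers emit.
    """
    if j.kind == FORWARD:
        start, end = j.left + 1, j.right
    else:
        start, end = j.left, j.right + 1
    return JunctionRecord(j.chrom, start, end, j.kind, j.count, j.strand)


def record_to_junction(rec: JunctionRecord, kind: str) -> SpliceJunction:
    """Inverse of :func:`junction_to_record` for a known junction kind."""
    strand = rec.strand if rec.strand in ("+", "-") else "+"
    if kind == FORWARD:
        left, right = rec.start - 1, rec.end
    else:
        left, right = rec.start, rec.end - 1
    if kind == FORWARD:
        donor, acceptor = (left, right) if strand == "+" else (right, left)
    else:
        donor, acceptor = (right, left) if strand == "+" else (left, right)
    return SpliceJunction(rec.chrom, donor, acceptor, rec.strand, rec.count, kind)


def write_junction_bed(junctions: Sequence[SpliceJunction], path: str | Path) -> None:
    """Write junctions as BED6 with score = supporting-read count.

    ``parse_junction_bed(write_junction_bed(X))`` reproduces coordinates and
    counts exactly.
    """
    with open(path, "w") as fh:
        for j in junctions:
            rec = junction_to_record(j)
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.name}\t{rec.count}\t{rec.strand}\n"
            )


def write_bedgraph(region: GenomicInterval, depth: Iterable[int], path: str | Path) -> None:
    """Export per-base depth over *region* as a run-length-merged bedGraph."""
    with open(path, "w") as fh:
        run_start = None
        run_val = None
        pos = region.start
        for d in depth:
            if d != run_val:
                if run_val is not None and run_val != 0:
                    fh.write(f"{region.chrom}\t{run_start}\t{pos}\t{run_val}\n")
                run_start, run_val = pos, d
            pos += 1
        if run_val is not None and run_val != 0:
            fh.write(f"{region.chrom}\t{run_start}\t{pos}\t{run_val}\n")
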