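"""Synthetic loci, spliced read sets and back-splice BEDs for testing.

The generator builds a random single-gene locus (FASTA + GTF), emits
alignments for a chosen isoform mix with exact N-gap CIGARs, and writes a
back-splice junction BED in the style an external circRNA caller produces.
Reads are placed at evenly spaced starts along each isoform (no sequencing
error, no fragment-length model): the package under test is a quantifier
and visualizer, and deterministic placement yields exact truth tables —
every simulated junction is returned with the exact number of reads that
support it, so assertions can demand equality rather than tolerance.

Scenario knobs mirror the biological cases of interest: exon skipping
(isoform chains that omit exons), intron retention (a fraction of reads
drawn from the unspliced pre-mRNA, aligned as continuous M), cryptic splice
sites (a signed shift of one donor or acceptor), and circRNA back-splicing
(BED rows spanning the circularized exon block).
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io import AlignedRead, JunctionRecord, write_gene_annotation
from .junctions import gap_to_donor_acceptor
from .model import GeneModel, GenomicInterval


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative parameters of one synthetic experiment."""

    n_exons: int = 4
    exon_len_range: tuple[int, int] = (80, 200)
    intron_len_range: tuple[int, int] = (200, 800)
    strand: str = "+"
    #: isoform mix: (exon-index chain, relative abundance)
    isoforms: tuple[tuple[tuple[int, ...], float], ...] | None = None
    #: back-splice circles: (first exon idx, last exon idx, read count)
    backsplices: tuple[tuple[int, int, int], ...] = ()
    intron_retention_frac: float = 0.0
    #: (intron index i joining exon i to i+1, 'donor'|'acceptor', signed nt offset)
    cryptic_site: tuple[int, str, int] | None = None
    read_length: int = 75
    depth: float = 20.0
    seed: int = 0
    gene_name: str = "GENE1"
    chrom: str = "chrS"
    gene_start: int = 1000

    def __post_init__(self) -> None:
        if self.n_exons < 1:
            raise ValueError("need >= 1 exon")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0.0 <= self.intron_retention_frac <= 1.0):
            raise ValueError("intron_retention_frac must lie in [0, 1]")
        if self.isoforms is not None:
            for chain, ab in self.isoforms:
                if ab <= 0:
                    raise ValueError("isoform abundances must be positive")
                if any(not 0 <= i < self.n_exons for i in chain):
                    raise ValueError("isoform chain indexes an absent exon")

    def effective_isoforms(self) -> tuple[tuple[tuple[int, ...], float], ...]:
        if self.isoforms is not None:
            return self.isoforms
        return ((tuple(range(self.n_exons)), 1.0),)


@dataclass
class LocusFixture:
    """One generated locus: files on disk plus the in-memory model."""

    spec: ScenarioSpec
    fasta_path: Path
    gtf_path: Path
    gene: GeneModel
    sequence: str  # full chromosome sequence


@dataclass
class SimulatedReads:
    """Alignments plus the exact per-junction supporting-read counts."""

    bam_path: Path
    reads: list[AlignedRead]
    truth: dict[tuple[int, int], int]  # (donor, acceptor) -> read count


def generate_locus(spec: ScenarioSpec, out_dir: str | Path) -> LocusFixture:
    """Synthesize the locus FASTA and single-transcript GTF for *spec*.

    The GTF round-trips through the annotation parser to the returned
    :class:`GeneModel`; the same seed always reproduces identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    exon_lens = rng.integers(
        spec.exon_len_range[0], spec.exon_len_range[1] + 1, spec.n_exons
    )
    intron_lens = rng.integers(
        spec.intron_len_range[0], spec.intron_len_range[1] + 1, max(spec.n_exons - 1, 0)
    )
    exons = []
    pos = spec.gene_start
    for i, el in enumerate(exon_lens):
        exons.append(GenomicInterval(spec.chrom, pos, pos + int(el), spec.strand))
        pos += int(el)
        if i < spec.n_exons - 1:
            pos += int(intron_lens[i])
    gene = GeneModel.from_exons(spec.gene_name, exons)

    chrom_len = gene.interval.end + 500
    seq = "".join(rng.choice(list("ACGT"), size=chrom_len))

    fasta_path = out_dir / f"{spec.gene_name}.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{spec.chrom}\n")
        fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")

    gtf_path = out_dir / f"{spec.gene_name}.gtf"
    write_gene_annotation(gene, gtf_path)
    return LocusFixture(spec, fasta_path, gtf_path, gene, seq)


def _isoform_blocks(
    spec: ScenarioSpec, gene: GeneModel, chain: Sequence[int]
) -> list[tuple[int, int]]:
    """Genomic blocks of one isoform, with any cryptic-site shift applied.

    A positive cryptic offset moves the site *downstream in transcription
    direction*: a +k acceptor shift activates a cryptic acceptor k nt inside
    the exon, a +k donor shift a novel intronic donor that retains the first
    k intron bases.  On the '-' strand downstream means decreasing genomic
    coordinate, so the shifts mirror.
    """
    blocks = [[gene.exons[i].start, gene.exons[i].end] for i in chain]
    if spec.cryptic_site is not None:
        intron_idx, site, offset = spec.cryptic_site
        if site not in ("donor", "acceptor"):
            raise ValueError(f"cryptic site must be donor/acceptor, got {site!r}")
        for k in range(len(chain) - 1):
            if chain[k] == intron_idx and chain[k + 1] == intron_idx + 1:
                if site == "acceptor":
                    if spec.strand == "-":
                        blocks[k][1] -= offset
                    else:
                        blocks[k + 1][0] += offset
                else:  # donor
                    if spec.strand == "-":
                        blocks[k + 1][0] -= offset
                    else:
                        blocks[k][1] += offset
    return [(s, e) for s, e in blocks]


def _read_from_blocks(
    blocks: Sequence[tuple[int, int]], t: int, length: int
) -> tuple[int, list[tuple[str, int]], list[tuple[int, int]]]:
    """Alignment of a read starting at transcript offset *t*.

    Returns (leftmost ref pos, CIGAR, N-gap reference intervals).
    """
    segments: list[tuple[int, int]] = []
    remaining = length
    offset = t
    for bs, be in blocks:
        blen = be - bs
        if offset >= blen:
            offset -= blen
            continue
        take = min(blen - offset, remaining)
        segments.append((bs + offset, bs + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    cigar: list[tuple[str, int]] = []
    gaps: list[tuple[int, int]] = []
    for i, (s, e) in enumerate(segments):
        if i > 0:
            prev_end = segments[i - 1][1]
            if s > prev_end:
                cigar.append(("N", s - prev_end))
                gaps.append((prev_end, s))
        if cigar and cigar[-1][0] == "M":  # merge book-ended blocks
            cigar[-1] = ("M", cigar[-1][1] + (e - s))
        else:
            cigar.append(("M", e - s))
    return segments[0][0], cigar, gaps


def synthesize_read_set(
    spec: ScenarioSpec, gene: GeneModel
) -> tuple[list[AlignedRead], dict[tuple[int, int], int]]:
    """In-memory reads for the scenario plus the exact junction truth table.

    For each isoform, read count = round(depth · abundance · L / read_length)
    (at least one), with starts evenly spaced over the transcript so that
    every junction of the isoform is supported whenever reads are longer
    than the spacing.  A fraction ``intron_retention_frac`` of each
    isoform's reads is drawn from the unspliced pre-mRNA instead
    (continuous-M alignments spanning exon/intron boundaries).
    """
    reads: list[AlignedRead] = []
    truth: dict[tuple[int, int], int] = {}
    serial = 0
    for chain, abundance in spec.effective_isoforms():
        blocks = _isoform_blocks(spec, gene, chain)
        L = sum(e - s for s, e in blocks)
        n = max(1, int(round(spec.depth * abundance * L / spec.read_length)))
        n_ret = int(round(spec.intron_retention_frac * n))
        pre_blocks = [(blocks[0][0], blocks[-1][1])]
        for source_blocks, m in ((blocks, n - n_ret), (pre_blocks, n_ret)):
            if m <= 0:
                continue
            src_len = sum(e - s for s, e in source_blocks)
            rl = min(spec.read_length, src_len)
            starts = np.linspace(0, src_len - rl, m).round().astype(int)
            for t in starts:
                pos, cigar, gaps = _read_from_blocks(source_blocks, int(t), rl)
                reads.append(
                    AlignedRead(
                        query_name=f"read{serial}",
                        chrom=spec.chrom,
                        pos=pos,
                        cigar=tuple(cigar),
                        strand="+",
                        mapq=60,
                    )
                )
                serial += 1
                for g0, g1 in gaps:
                    da = gap_to_donor_acceptor(g0, g1, spec.strand)
                    truth[da] = truth.get(da, 0) + 1
    return reads, truth


def write_alignments(
    reads: Sequence[AlignedRead],
    locus: LocusFixture,
    out_dir: str | Path,
    basename: str = "sample",
) -> Path:
    """Write reads as a coordinate-sorted, indexed BAM via the real I/O stack."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": locus.spec.chrom, "LN": len(locus.sequence)}],
    }
    unsorted_path = out_dir / f"{basename}.unsorted.bam"
    with pysam.AlignmentFile(str(unsorted_path), "wb", header=header) as bam:
        for read in reads:
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = read.query_name
            seg.reference_id = 0
            seg.reference_start = read.pos
            seg.mapping_quality = read.mapq
            seg.flag = 0 if read.strand == "+" else 16
            seg.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar)
            qlen = sum(n for op, n in read.cigar if op in "MIS=X")
            seq = []
            ref = read.pos
            for op, n in read.cigar:
                if op in "M=X":
                    seq.append(locus.sequence[ref : ref + n])
                    ref += n
                elif op in "DN":
                    ref += n
                elif op in "IS":
                    seq.append("A" * n)
            seg.query_sequence = "".join(seq)[:qlen]
            bam.write(seg)
    bam_path = out_dir / f"{basename}.bam"
    pysam.sort("-o", str(bam_path), str(unsorted_path))
    unsorted_path.unlink()
    pysam.index(str(bam_path))
    return bam_path


def simulate_reads(
    spec: ScenarioSpec, locus: LocusFixture, out_dir: str | Path, basename: str = "sample"
) -> SimulatedReads:
    """Simulate the scenario's reads and write them as sorted, indexed BAM."""
    reads, truth = synthesize_read_set(spec, locus.gene)
    bam_path = write_alignments(reads, locus, out_dir, basename)
    return SimulatedReads(bam_path, reads, truth)


def simulate_backsplice_bed(
    spec: ScenarioSpec, locus: LocusFixture, path: str | Path
) -> tuple[list[JunctionRecord], dict[tuple[int, int], int]]:
    """Write back-splice BED rows spanning each circularized exon block.

    Emulates the output shape of an external back-splice caller (BED6 with
    score = junction read count); returns the records and the exact
    (donor, acceptor) truth counts for the gene's strand.
    """
    if not spec.backsplices:
        raise ValueError("scenario has no back-splice pairs")
    gene = locus.gene
    records: list[JunctionRecord] = []
    truth: dict[tuple[int, int], int] = {}
    with open(path, "w") as fh:
        for first, last, count in spec.backsplices:
            if not (0 <= first <= last < len(gene.exons)):
                raise ValueError(f"invalid back-splice exon pair ({first}, {last})")
            start = gene.exons[first].start
            end = gene.exons[last].end
            name = f"circ_{first}_{last}"
            fh.write(
                f"{spec.chrom}\t{start}\t{end}\t{name}\t{count}\t{spec.strand}\n"
            )
            records.append(
                JunctionRecord(spec.chrom, start, end, name, count, spec.strand)
            )
            if spec.strand == "-":
                donor, acceptor = start, end - 1
            else:
                donor, acceptor = end - 1, start
            truth[(donor, acceptor)] = truth.get((donor, acceptor), 0) + count
    return records, truth


def random_scenario(seed: int, *, max_exons: int = 6) -> ScenarioSpec:
    """A randomized small scenario (structure, strand, isoform mix, circles)."""
    rng = np.random.default_rng(seed)
    n_exons = int(rng.integers(2, max_exons + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    # full chain plus possibly one exon-skipping chain
    isoforms = [(tuple(range(n_exons)), 1.0)]
    if n_exons >= 3 and rng.random() < 0.5:
        skip = int(rng.integers(1, n_exons - 1))
        chain = tuple(i for i in range(n_exons) if i != skip)
        isoforms.append((chain, float(rng.uniform(0.3, 1.0))))
    backsplices: list[tuple[int, int, int]] = []
    if rng.random() < 0.7:
        first = int(rng.integers(0, n_exons))
        last = int(rng.integers(first, n_exons))
        backsplices.append((first, last, int(rng.integers(1, 50))))
    return ScenarioSpec(
        n_exons=n_exons,
        exon_len_range=(60, 150),
        intron_len_range=(100, 400),
        strand=strand,
        isoforms=tuple(isoforms),
        backsplices=tuple(backsplices),
        read_length=int(rng.integers(50, 101)),
        depth=float(rng.uniform(5, 30)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
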