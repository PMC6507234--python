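"""RNA-binding-protein site prediction by IUPAC consensus scanning.

Binding sites are predicted by exact degenerate-consensus matching (no PWM
scoring): every position of the IUPAC consensus must contain the sequence
base at that offset.  Scanning runs over the spliced transcript sequence by
default (sites are drawn along the transcript); a full-locus scope covers
the unspliced pre-mRNA for intron-retention studies.  The module also
carries generic BED feature tracks such as ALU repeat elements, whose
inverted pairs in flanking introns promote circularization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .io import JunctionRecord
from .model import GeneModel, GenomicInterval

#: IUPAC degenerate nucleotide classes.  A sequence 'N' (unknown base)
#: matches only a consensus 'N', never a resolved degenerate class.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifDef:
    """A named IUPAC consensus; 'U' is normalized to 'T' on construction."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "consensus", self.consensus.upper().replace("U", "T"))
        if not self.consensus:
            raise ValueError(f"motif {self.name!r} has an empty consensus")
        for ch in self.consensus:
            if ch not in IUPAC:
                raise ValueError(
                    f"invalid IUPAC character {ch!r} in motif {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifSite:
    """One genomic piece of a predicted binding site.

    A match that crosses a splice border in transcript-scope scanning is
    split into one piece per exon; pieces of the same match share
    ``match_id`` and their lengths sum to the consensus length.
    """

    motif_name: str
    interval: GenomicInterval
    match_id: int = 0


@dataclass(frozen=True)
class FeatureElement:
    """A named genomic feature (e.g. one ALU element) drawn as a track."""

    name: str
    interval: GenomicInterval


def _consensus_regex(motif: MotifDef) -> re.Pattern:
    # Lookahead so overlapping matches are all reported.
    body = "".join(f"[{IUPAC[ch]}]" for ch in motif.consensus)
    return re.compile(f"(?=({body}))")


def scan_motif(sequence: str, motif: MotifDef) -> list[int]:
    """All 0-based offsets where *motif* matches *sequence* (overlaps included)."""
    sequence = sequence.upper().replace("U", "T")
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    return [m.start() for m in _consensus_regex(motif).finditer(sequence)]


class SequenceSource(Protocol):
    def fetch(self, chrom: str, start: int, end: int) -> str: ...


class DictSequenceSource:
    """Adapter exposing a chrom -> sequence mapping through ``fetch``."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in sequence source")
        seq = self._seqs[chrom]
        if end > len(seq):
            raise ValueError(f"requested span [{start}, {end}) exceeds {chrom} length")
        return seq[start:end]


EXONS_ONLY = "exons_only"
FULL_LOCUS = "full_locus"


def _fetch_checked(source: SequenceSource, chrom: str, start: int, end: int) -> str:
    try:
        seq = source.fetch(chrom, start, end)
    except (KeyError, ValueError) as exc:
        raise ValueError(f"genome sequence missing for {chrom}:{start}-{end}: {exc}") from exc
    if len(seq) != end - start:
        raise ValueError(f"genome sequence does not cover {chrom}:{start}-{end}")
    return seq.upper()


def annotate_gene_motifs(
    gene: GeneModel,
    genome_seq: SequenceSource | Mapping[str, str],
    motifs: Sequence[MotifDef],
    scope: str = EXONS_ONLY,
) -> list[MotifSite]:
    """Predict motif sites on the gene's transcript (or unspliced locus).

    For '-' strand genes the reverse complement is scanned and offsets are
    mapped back to genomic coordinates.  In ``exons_only`` scope the spliced
    exon sequence is scanned; matches crossing an exon border are split into
    per-exon genomic pieces sharing a ``match_id``.
    """
    if scope not in (EXONS_ONLY, FULL_LOCUS):
        raise ValueError(f"unknown scan scope {scope!r}")
    if isinstance(genome_seq, Mapping):
        genome_seq = DictSequenceSource(genome_seq)

    if scope == FULL_LOCUS:
        blocks = [gene.interval]
    else:
        blocks = list(gene.exons)

    pieces = [
        _fetch_checked(genome_seq, gene.chrom, b.start, b.end) for b in blocks
    ]
    spliced = "".join(pieces)
    total = len(spliced)
    minus = gene.strand == "-"
    scan_seq = reverse_complement(spliced) if minus else spliced

    # spliced-coordinate start of each block (genomic order)
    offsets = []
    pos = 0
    for b in blocks:
        offsets.append(pos)
        pos += b.length

    sites: list[MotifSite] = []
    match_id = 0
    for motif in motifs:
        m = len(motif)
        for t in scan_motif(scan_seq, motif):
            # spliced-coordinate interval of the match, genomic orientation
            if minus:
                cs, ce = total - t - m, total - t
            else:
                cs, ce = t, t + m
            for b, off in zip(blocks, offsets):
                lo = max(cs, off)
                hi = min(ce, off + b.length)
                if lo < hi:
                    g0 = b.start + (lo - off)
                    sites.append(
                        MotifSite(
                            motif.name,
                            GenomicInterval(gene.chrom, g0, g0 + (hi - lo), gene.strand),
                            match_id,
                        )
                    )
            match_id += 1
    return sites


def load_motif_table(path: str | Path) -> list[MotifDef]:
    """Read a 2-column TSV (protein name, IUPAC consensus) into MotifDefs."""
    motifs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: need name<TAB>consensus")
            motifs.append(MotifDef(fields[0], fields[1]))
    return motifs


def bundled_motif_table() -> list[MotifDef]:
    """The shipped default motif table (illustrative, user-replaceable)."""
    with resources.as_file(
        resources.files("splicearc").joinpath("data/motifs.tsv")
    ) as path:
        return load_motif_table(path)


def load_feature_track(
    records: Iterable[JunctionRecord], gene: GeneModel
) -> list[FeatureElement]:
    """Clip BED feature rows to the gene interval, preserving names."""
    out = []
    for rec in records:
        if rec.chrom != gene.chrom:
            continue
        lo = max(rec.start, gene.interval.start)
        hi = min(rec.end, gene.interval.end)
        if lo < hi:
            out.append(
                FeatureElement(
                    rec.name, GenomicInterval(gene.chrom, lo, hi, gene.strand)
                )
            )
    return out
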