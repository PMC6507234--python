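"""Per-base coverage, exon-level aggregation and the two normalization modes.

Depth counts sequenced bases only: CIGAR M/=/X positions.  Skipped introns
(N), deletions (D), insertions and clips contribute nothing.  Exon color
intensity is the mean depth over the exon, normalized either within each
sample (each sample divided by its own maximum — highlights alternative
splicing, intron retention and exon exclusion within a sample) or across
all samples (one global maximum — preserves between-sample differences).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io import AlignedRead
from .model import GeneModel, GenomicInterval


@dataclass
class CoverageVector:
    """Read depth per genomic base over a region.

    ``depth[i]`` is the depth at genomic position ``region.start + i``.
    """

    region: GenomicInterval
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if len(self.depth) != self.region.length:
            raise ValueError(
                f"depth length {len(self.depth)} != region length {self.region.length}"
            )
        if (self.depth < 0).any():
            raise ValueError("depth entries must be >= 0")

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        if not (
            self.region.start <= interval.start and interval.end <= self.region.end
        ):
            raise ValueError(f"{interval} outside coverage region {self.region}")
        off = self.region.start
        return self.depth[interval.start - off : interval.end - off]

    def total(self) -> int:
        return int(self.depth.sum())


def compute_base_coverage(
    reads: Iterable[AlignedRead], region: GenomicInterval
) -> CoverageVector:
    """Single-nucleotide depth: number of aligned (M/=/X) bases at each position."""
    depth = np.zeros(region.length, dtype=np.int64)
    for read in reads:
        if read.chrom != region.chrom:
            continue
        for b0, b1 in read.aligned_blocks():
            lo = max(b0, region.start) - region.start
            hi = min(b1, region.end) - region.start
            if lo < hi:
                depth[lo:hi] += 1
    return CoverageVector(region, depth)


def smooth_coverage(cov: CoverageVector, window: int = 1) -> CoverageVector:
    """Moving-mean smoothing for display; window 1 (default) is exact."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return cov
    kernel = np.ones(window) / window
    smoothed = np.convolve(cov.depth.astype(float), kernel, mode="same")
    out = CoverageVector(cov.region, np.zeros_like(cov.depth))
    out.depth = smoothed  # floats allowed post-smoothing
    return out


def exon_mean_coverage(cov: CoverageVector, gene: GeneModel) -> list[float]:
    """Arithmetic mean depth over each collapsed exon, in gene exon order."""
    return [float(cov.slice(ex).mean()) for ex in gene.exons]


WITHIN_SAMPLE = "within_sample"
ACROSS_SAMPLES = "across_samples"


def normalize_exons(
    values_by_sample: Mapping[str, list[float]], mode: str
) -> dict[str, list[float]]:
    """Scale per-exon values into [0, 1] by the scope maximum.

    ``within_sample`` divides each sample by its own max; ``across_samples``
    divides every sample by the global max.  An all-zero scope maps to all
    zeros (no division by zero).  Negative inputs are rejected.
    """
    if mode not in (WITHIN_SAMPLE, ACROSS_SAMPLES):
        raise ValueError(f"unknown normalization mode {mode!r}")
    lengths = {len(v) for v in values_by_sample.values()}
    if len(lengths) > 1:
        raise ValueError("samples have unequal exon-value lengths")
    for label, values in values_by_sample.items():
        if any(v < 0 for v in values):
            raise ValueError(f"negative exon value in sample {label!r}")

    out: dict[str, list[float]] = {}
    if mode == ACROSS_SAMPLES:
        global_max = max(
            (max(v) for v in values_by_sample.values() if v), default=0.0
        )
        for label, values in values_by_sample.items():
            out[label] = (
                [v / global_max for v in values] if global_max > 0 else [0.0] * len(values)
            )
    else:
        for label, values in values_by_sample.items():
            m = max(values) if values else 0.0
            out[label] = [v / m for v in values] if m > 0 else [0.0] * len(values)
    return out
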