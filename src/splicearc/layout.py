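"""Genomic→plot-axis coordinate transform and junction arc geometry.

Introns are typically far larger than exons, so the plot axis compresses
each intron by a user-chosen factor while exons stay at scale 1 (exact:
within an exon, plot distance equals genomic distance).  The map is
strictly monotone and piecewise linear, so it is invertible.  An
alternative mode gives every intron one fixed plot width instead.

Arc geometry: forward junctions arch above the exon row, back-splice
junctions curve below it.  Line weight encodes the read count (log1p);
apex height encodes plot span, so nested junctions stay legible.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass
from typing import Sequence

from .model import BACK, FORWARD, GeneModel, GenomicInterval, SpliceJunction

ABOVE = "above"
BELOW = "below"

#: Floor added to log1p(count) so zero-count junctions keep a visible stroke.
MIN_ARC_WEIGHT = 0.1


@dataclass(frozen=True)
class MapSegment:
    genomic: GenomicInterval
    plot_start: float
    scale: float  # plot units per genomic base, in (0, 1]


@dataclass(frozen=True)
class CoordinateMap:
    """Monotone piecewise-linear genomic→plot transform over one gene."""

    segments: tuple[MapSegment, ...]

    @property
    def genomic_start(self) -> int:
        return self.segments[0].genomic.start

    @property
    def genomic_end(self) -> int:
        return self.segments[-1].genomic.end

    @property
    def total_width(self) -> float:
        last = self.segments[-1]
        return last.plot_start + last.genomic.length * last.scale


def build_coordinate_map(
    gene: GeneModel,
    shrink_factor: float = 1.0,
    *,
    fixed_intron_width: float | None = None,
) -> CoordinateMap:
    """Build the plot-axis map for *gene* with compressed introns.

    Each intron's plot width is its genomic width divided by
    *shrink_factor* (>= 1); exons map at scale 1.  Total plot width is
    Σ exon lengths + Σ intron lengths / shrink_factor.  If
    *fixed_intron_width* is given, every intron instead occupies exactly
    that plot width regardless of genomic size.
    """
    if shrink_factor < 1:
        raise ValueError(f"shrink_factor must be >= 1, got {shrink_factor}")
    if fixed_intron_width is not None and fixed_intron_width <= 0:
        raise ValueError("fixed_intron_width must be positive")

    segments: list[MapSegment] = []
    plot = 0.0
    cursor = gene.interval.start
    for ex in gene.exons:
        if ex.start > cursor:  # intron (or flank) before this exon
            intron = GenomicInterval(gene.chrom, cursor, ex.start, gene.strand)
            if fixed_intron_width is not None:
                scale = fixed_intron_width / intron.length
            else:
                scale = 1.0 / shrink_factor
            segments.append(MapSegment(intron, plot, scale))
            plot += intron.length * scale
        segments.append(MapSegment(ex, plot, 1.0))
        plot += ex.length
        cursor = ex.end
    if cursor < gene.interval.end:  # trailing flank inside the gene interval
        tail = GenomicInterval(gene.chrom, cursor, gene.interval.end, gene.strand)
        scale = (
            fixed_intron_width / tail.length
            if fixed_intron_width is not None
            else 1.0 / shrink_factor
        )
        segments.append(MapSegment(tail, plot, scale))
    return CoordinateMap(tuple(segments))


def map_position(cmap: CoordinateMap, g: int | float) -> float:
    """Plot coordinate of genomic position *g* (strictly increasing in g)."""
    if not (cmap.genomic_start <= g <= cmap.genomic_end):
        raise ValueError(
            f"position {g} outside gene span "
            f"[{cmap.genomic_start}, {cmap.genomic_end}]"
        )
    starts = [seg.genomic.start for seg in cmap.segments]
    i = bisect.bisect_right(starts, g) - 1
    i = max(i, 0)
    seg = cmap.segments[i]
    return seg.plot_start + (g - seg.genomic.start) * seg.scale


def map_plot_to_genomic(cmap: CoordinateMap, x: float) -> float:
    """Inverse transform: genomic coordinate of plot position *x*."""
    if not (0.0 <= x <= cmap.total_width + 1e-9):
        raise ValueError(f"plot position {x} outside [0, {cmap.total_width}]")
    plot_starts = [seg.plot_start for seg in cmap.segments]
    i = bisect.bisect_right(plot_starts, x) - 1
    i = max(i, 0)
    seg = cmap.segments[i]
    return seg.genomic.start + (x - seg.plot_start) / seg.scale


@dataclass(frozen=True)
class ArcSpec:
    """Geometry of one junction arc in plot coordinates."""

    x0: float
    x1: float
    orientation: str  # forward -> above, back -> below
    weight: float
    apex_height: float

    def __post_init__(self) -> None:
        if self.x0 >= self.x1:
            raise ValueError("arc requires x0 < x1")
        if self.orientation not in (ABOVE, BELOW):
            raise ValueError(f"invalid orientation {self.orientation!r}")
        if self.weight <= 0 or self.apex_height <= 0:
            raise ValueError("weight and apex_height must be positive")


def junction_arc(
    cmap: CoordinateMap,
    j: SpliceJunction,
    *,
    apex_scale: float = 0.25,
    apex_cap: float = 1.0,
) -> ArcSpec:
    """Arc geometry for one junction.

    Orientation is a pure function of kind (forward above, back below);
    stroke weight is log1p(count) plus a small floor; apex height grows
    with the square root of the plot span, capped at *apex_cap*.
    """
    x0 = map_position(cmap, j.left)
    x1 = map_position(cmap, j.right)
    span = x1 - x0
    return ArcSpec(
        x0=x0,
        x1=x1,
        orientation=ABOVE if j.kind == FORWARD else BELOW,
        weight=math.log1p(j.count) + MIN_ARC_WEIGHT,
        apex_height=min(apex_cap, apex_scale * math.sqrt(max(span, 1e-9))),
    )
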