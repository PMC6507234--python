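"""Deterministic vector rendering of the gene figure.

One horizontal panel per sample, stacked in input order.  Per panel: exon
boxes filled by colormap(normalized exon mean coverage); a per-base
coverage polyline through the exon row whose height is proportional to
depth (scaled to the panel maximum); forward-splice arcs above the exons
and back-splice arcs below.  Motif and feature tracks sit beneath the
lowest panel.  SVG is the canonical output: every meaningful element
carries a stable ``id`` (``exon-s0-e2``, ``arc-above-s1-j0``, ...), text is
emitted as real text nodes, and with deterministic metadata enabled the
same inputs produce byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.path import Path as MplPath

from .coverage import CoverageVector
from .layout import ABOVE, CoordinateMap, junction_arc, map_position
from .model import GeneModel, SampleBundle, SpliceJunction
from .motifs import FeatureElement, MotifSite

logger = logging.getLogger(__name__)

_HASHSALT = "splicearc"

PANEL_HEIGHT = 1.0
TRACK_HEIGHT = 0.12


@dataclass
class FigureStyle:
    """Plot aesthetics; every field has a working default."""

    colormap: str = "Blues"
    exon_height: float = 0.36
    arc_thickness: tuple[float, float] = (0.8, 3.0)
    font_size: float = 8.0
    label_font_size: float = 9.0
    output_format: str | None = None  # inferred from out_path suffix when None
    dpi: int = 150
    deterministic_metadata: bool = True
    fig_width: float = 10.0
    coverage_color: str = "#303030"
    arc_color_forward: str = "#1f77b4"
    arc_color_back: str = "#d62728"
    show_intron_coverage: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.arc_thickness
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("arc thickness range must be positive and ordered")
        if self.dpi < 72:
            raise ValueError("dpi must be >= 72")
        if self.exon_height <= 0 or self.exon_height >= PANEL_HEIGHT:
            raise ValueError("exon box height must lie in (0, panel height)")


def _panel_center(i: int, n_samples: int) -> float:
    # sample 0 drawn topmost
    return (n_samples - 1 - i) * PANEL_HEIGHT


def _arc_patch(
    x0: float, x1: float, y0: float, apex: float, up: bool, lw: float,
    color: str, gid: str,
) -> PathPatch:
    # quadratic Bezier; control point 2*apex away puts the apex at `apex`
    cy = y0 + 2 * apex if up else y0 - 2 * apex
    path = MplPath(
        [(x0, y0), ((x0 + x1) / 2.0, cy), (x1, y0)],
        [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
    )
    patch = PathPatch(path, facecolor="none", edgecolor=color, linewidth=lw)
    patch.set_gid(gid)
    return patch


def _coverage_xy(
    cov: CoverageVector, cmap: CoordinateMap, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Plot x and raw depth for genomic span [lo, hi) of the coverage vector."""
    off = cov.region.start
    depth = np.asarray(cov.depth[lo - off : hi - off], dtype=float)
    x0 = map_position(cmap, lo)
    # per-base x; exact within exons, linear within compressed segments
    xs = np.array([map_position(cmap, p) for p in range(lo, hi)], dtype=float)
    return xs, depth


def render_sample_legend(ax, samples: Sequence[SampleBundle], style: FigureStyle):
    """Write each sample's label beside its panel, verbatim and in order."""
    if not samples:
        raise ValueError("need at least one sample")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        logger.warning("duplicate sample labels: %s", labels)
    texts = []
    n = len(samples)
    for i, s in enumerate(samples):
        t = ax.text(
            -0.01,
            _panel_center(i, n),
            s.label,
            ha="right",
            va="center",
            fontsize=style.label_font_size,
            transform=ax.get_yaxis_transform(),
        )
        t.set_gid(f"label-s{i}")
        texts.append(t)
    return texts


def _check_bundles(gene: GeneModel, samples: Sequence[SampleBundle]) -> None:
    if not samples:
        raise ValueError("render_gene_figure needs at least one sample")
    for s in samples:
        cov = s.coverage
        if cov.region.chrom != gene.chrom or not (
            cov.region.start <= gene.interval.start
            and gene.interval.end <= cov.region.end
        ):
            raise ValueError(
                f"sample {s.label!r} coverage region {cov.region} does not "
                f"cover gene {gene.name} ({gene.interval})"
            )
        if s.exon_values is not None and len(s.exon_values) != len(gene.exons):
            raise ValueError(
                f"sample {s.label!r} has {len(s.exon_values)} exon values for "
                f"{len(gene.exons)} exons"
            )


def render_gene_figure(
    gene: GeneModel,
    cmap: CoordinateMap,
    samples: Sequence[SampleBundle],
    motif_sites: Sequence[MotifSite] = (),
    features: Sequence[FeatureElement] = (),
    style: FigureStyle | None = None,
    out_path: str | Path = "figure.svg",
) -> Path:
    """Compose the full figure and write it to *out_path*.

    Output format follows the path suffix (svg/pdf/png) unless
    ``style.output_format`` overrides it.  With deterministic metadata
    (default) repeated runs on identical inputs are byte-identical for SVG.
    """
    style = style or FigureStyle()
    _check_bundles(gene, samples)
    out_path = Path(out_path)
    fmt = (style.output_format or out_path.suffix.lstrip(".") or "svg").lower()
    if fmt not in ("svg", "pdf", "png"):
        raise ValueError(f"unsupported output format {fmt!r}")

    n = len(samples)
    n_tracks = (1 if motif_sites else 0) + (1 if features else 0)
    color_map = matplotlib.colormaps[style.colormap]
    h2 = style.exon_height / 2.0
    headroom = PANEL_HEIGHT / 2.0 - h2
    lw_lo, lw_hi = style.arc_thickness

    rc = {
        "svg.hashsalt": _HASHSALT,
        "svg.fonttype": "none",
        "font.size": style.font_size,
    }
    with matplotlib.rc_context(rc):
        fig_h = max(1.5, 1.1 * n + 0.45 * n_tracks + 0.6)
        fig, ax = plt.subplots(figsize=(style.fig_width, fig_h))

        all_weights = [
            np.log1p(j.count) + 0.1
            for s in samples
            for j in tuple(s.forward_junctions) + tuple(s.back_junctions)
        ]
        w_max = max(all_weights) if all_weights else 1.0

        for i, sample in enumerate(samples):
            yc = _panel_center(i, n)
            values = sample.exon_values or tuple(0.0 for _ in gene.exons)

            # exon boxes (z=1)
            for k, (ex, val) in enumerate(zip(gene.exons, values)):
                x0 = map_position(cmap, ex.start)
                rect = Rectangle(
                    (x0, yc - h2),
                    ex.length,  # scale 1 within exons
                    style.exon_height,
                    facecolor=color_map(float(val)),
                    edgecolor="#555555",
                    linewidth=0.5,
                    zorder=1,
                )
                rect.set_gid(f"exon-s{i}-e{k}")
                ax.add_patch(rect)

            # per-base coverage polyline (z=2)
            panel_max = float(np.max(sample.coverage.depth)) or 1.0
            spans = (
                [(gene.interval.start, gene.interval.end)]
                if style.show_intron_coverage
                else [(ex.start, ex.end) for ex in gene.exons]
            )
            for si, (lo, hi) in enumerate(spans):
                xs, depth = _coverage_xy(sample.coverage, cmap, lo, hi)
                ys = yc - h2 + (depth / panel_max) * style.exon_height
                (line,) = ax.plot(
                    xs, ys, color=style.coverage_color, linewidth=0.7, zorder=2
                )
                line.set_gid(f"coverage-s{i}-seg{si}")

            # arcs: forward above (z=3), back below (z=3)
            for kind_label, junctions, up, color in (
                ("above", sample.forward_junctions, True, style.arc_color_forward),
                ("below", sample.back_junctions, False, style.arc_color_back),
            ):
                y0 = yc + h2 if up else yc - h2
                for jn, j in enumerate(
                    sorted(junctions, key=lambda j: (j.left, j.right))
                ):
                    spec = junction_arc(
                        cmap, j, apex_scale=headroom / max(np.sqrt(cmap.total_width), 1e-9),
                        apex_cap=0.95 * headroom,
                    )
                    lw = lw_lo + (lw_hi - lw_lo) * spec.weight / w_max
                    patch = _arc_patch(
                        spec.x0, spec.x1, y0, spec.apex_height,
                        spec.orientation == ABOVE, lw, color,
                        f"arc-{kind_label}-s{i}-j{jn}",
                    )
                    patch.set_zorder(3)
                    ax.add_patch(patch)
                    if j.novel:
                        for mi, xpos in enumerate((spec.x0, spec.x1)):
                            marker = ax.plot(
                                [xpos], [y0], marker="d", markersize=4,
                                color="#ff7f0e", zorder=4,
                            )[0]
                            marker.set_gid(f"novel-{kind_label}-s{i}-j{jn}-{mi}")

        # tracks beneath the lowest panel (z=5)
        track_y = -PANEL_HEIGHT / 2.0 - 0.25
        if motif_sites:
            for mi, site in enumerate(motif_sites):
                x0 = map_position(cmap, site.interval.start)
                x1 = map_position(cmap, site.interval.end)
                rect = Rectangle(
                    (x0, track_y), max(x1 - x0, 1e-6), TRACK_HEIGHT,
                    facecolor="#2ca02c", edgecolor="none", zorder=5,
                )
                rect.set_gid(f"motif-{site.motif_name}-{mi}")
                ax.add_patch(rect)
            t = ax.text(
                -0.01, track_y + TRACK_HEIGHT / 2, "RBP sites",
                ha="right", va="center", fontsize=style.font_size,
                transform=ax.get_yaxis_transform(),
            )
            t.set_gid("track-label-motifs")
            track_y -= 0.3
        if features:
            for fi, feat in enumerate(features):
                x0 = map_position(cmap, feat.interval.start)
                x1 = map_position(cmap, feat.interval.end)
                rect = Rectangle(
                    (x0, track_y), max(x1 - x0, 1e-6), TRACK_HEIGHT,
                    facecolor="#9467bd", edgecolor="none", zorder=5,
                )
                rect.set_gid(f"feature-{feat.name}-{fi}")
                ax.add_patch(rect)
            t = ax.text(
                -0.01, track_y + TRACK_HEIGHT / 2, "features",
                ha="right", va="center", fontsize=style.font_size,
                transform=ax.get_yaxis_transform(),
            )
            t.set_gid("track-label-features")
            track_y -= 0.3

        # text last (z=6)
        render_sample_legend(ax, samples, style)
        title = ax.set_title(
            f"{gene.name}  {gene.chrom}:{gene.interval.start + 1:,}-"
            f"{gene.interval.end:,} ({gene.strand}) 5'→3' "
            + ("←" if gene.strand == "-" else "→"),
            fontsize=style.label_font_size,
        )
        title.set_gid("figure-title")

        ax.set_xlim(-0.02 * cmap.total_width, 1.02 * cmap.total_width)
        ax.set_ylim(track_y - 0.1, (n - 1) * PANEL_HEIGHT + PANEL_HEIGHT / 2.0 + 0.1)
        ax.set_axis_off()

        metadata = None
        if style.deterministic_metadata:
            if fmt == "svg":
                metadata = {"Date": None}
            elif fmt == "pdf":
                metadata = {"CreationDate": None}
        fig.savefig(out_path, format=fmt, dpi=style.dpi, metadata=metadata)
        plt.close(fig)
    return out_path
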