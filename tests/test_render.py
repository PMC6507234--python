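"""Structural contracts of the rendered SVG figure."""

import re
import xml.etree.ElementTree as ET

import numpy as np
import pytest

from splicearc import (
    CoverageVector,
    FigureStyle,
    GeneModel,
    GenomicInterval,
    SampleBundle,
    SpliceJunction,
    build_coordinate_map,
    render_gene_figure,
)
from splicearc.model import BACK, FORWARD
from splicearc.motifs import FeatureElement, MotifDef, MotifSite


def _gene():
    return GeneModel.from_exons(
        "DEMO",
        [GenomicInterval("c", s, s + 100, "+") for s in (0, 500, 1000, 1500)],
    )


def _bundle(gene, label="s", fwd=(), back=(), values=None, depth_peak=30):
    rng = np.random.default_rng(0)
    depth = rng.integers(0, depth_peak, gene.interval.length)
    cov = CoverageVector(gene.interval, depth)
    if values is None:
        values = tuple(np.linspace(0.1, 1.0, len(gene.exons)))
    return SampleBundle(label, cov, tuple(fwd), tuple(back), tuple(values))


def _fwd(gene, i, count=5):
    return SpliceJunction(
        "c", gene.exons[i].end - 1, gene.exons[i + 1].start, "+", count, FORWARD
    )


def _back(gene, i, j, count=5):
    return SpliceJunction(
        "c", gene.exons[j].end - 1, gene.exons[i].start, "+", count, BACK
    )


def _ids(path):
    tree = ET.parse(path)
    return [e.get("id") for e in tree.iter() if e.get("id")]


class TestRenderGeneFigure:
    def test_svg_is_wellformed_and_arc_counts_match_junction_kinds(self, tmp_path):
        gene = _gene()
        bundle = _bundle(
            gene, fwd=[_fwd(gene, 0), _fwd(gene, 1)], back=[_back(gene, 1, 2)]
        )
        out = tmp_path / "fig.svg"
        render_gene_figure(gene, build_coordinate_map(gene, 10), [bundle], out_path=out)
        ids = _ids(out)  # ET.parse doubles as the well-formedness check
        assert sum(1 for i in ids if i.startswith("arc-above")) == 2
        assert sum(1 for i in ids if i.startswith("arc-below")) == 1

    def test_no_junctions_renders_zero_arcs_but_valid_figure(self, tmp_path):
        gene = _gene()
        out = tmp_path / "fig.svg"
        render_gene_figure(gene, build_coordinate_map(gene, 10), [_bundle(gene)], out_path=out)
        ids = _ids(out)
        assert not any(i.startswith("arc-") for i in ids)
        assert sum(1 for i in ids if i.startswith("exon-")) == 4

    def test_three_samples_stack_in_input_order(self, tmp_path):
        gene = _gene()
        bundles = [_bundle(gene, label=f"sample{k}") for k in range(3)]
        out = tmp_path / "fig.svg"
        render_gene_figure(gene, build_coordinate_map(gene, 10), bundles, out_path=out)
        ids = _ids(out)
        for k in range(3):
            assert f"label-s{k}" in ids
            assert f"exon-s{k}-e0" in ids
        # panel of sample 0 sits above panel of sample 2 (smaller SVG y = higher)
        tree = ET.parse(out)
        ns = {"svg": "http://www.w3.org/2000/svg"}
        y = {}
        for k in (0, 2):
            g = tree.find(f".//*[@id='exon-s{k}-e0']")
            path = g.find("svg:path", ns)
            y[k] = float(re.findall(r"[\d.]+", path.get("d"))[1])
        assert y[0] < y[2]

    def test_exon_fill_intensity_monotone_in_normalized_value(self, tmp_path):
        gene = _gene()
        values = (0.0, 0.3, 0.7, 1.0)
        bundle = _bundle(gene, values=values)
        out = tmp_path / "fig.svg"
        style = FigureStyle(colormap="gray_r")  # linear grayscale, higher = darker
        render_gene_figure(
            gene, build_coordinate_map(gene, 10), [bundle], style=style, out_path=out
        )
        text = out.read_text()
        lum = []
        for k in range(4):
            m = re.search(rf'id="exon-s0-e{k}">\s*<path[^>]*>', text)
            assert m, f"no path found for exon {k}"
            fill = re.search(r"fill:\s*#([0-9a-fA-F]{6})", m.group(0))
            rgb = fill.group(1) if fill else "000000"  # SVG default fill is black
            lum.append(sum(int(rgb[i : i + 2], 16) for i in (0, 2, 4)))
        assert lum == sorted(lum, reverse=True)  # darker with larger value

    def test_repeated_runs_are_byte_identical(self, tmp_path):
        gene = _gene()
        bundle = _bundle(gene, fwd=[_fwd(gene, 0)], back=[_back(gene, 0, 2)])
        cmap = build_coordinate_map(gene, 10)
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_gene_figure(gene, cmap, [bundle], out_path=a)
        render_gene_figure(gene, cmap, [bundle], out_path=b)
        assert a.read_bytes() == b.read_bytes()

    def test_labels_appear_verbatim_as_text_nodes(self, tmp_path):
        gene = _gene()
        bundles = [_bundle(gene, label="polyA"), _bundle(gene, label="RNaseR")]
        out = tmp_path / "fig.svg"
        render_gene_figure(gene, build_coordinate_map(gene, 10), bundles, out_path=out)
        texts = {
            el.text
            for el in ET.parse(out).iter()
            if el.tag.endswith("}text") or el.tag.endswith("}tspan")
        }
        assert {"polyA", "RNaseR"} <= texts

    def test_motif_and_feature_tracks_present(self, tmp_path):
        gene = _gene()
        sites = [MotifSite("RBFOX1", GenomicInterval("c", 10, 16, "+"))]
        feats = [FeatureElement("ALU", GenomicInterval("c", 600, 680, "+"))]
        out = tmp_path / "fig.svg"
        render_gene_figure(
            gene, build_coordinate_map(gene, 10), [_bundle(gene)], sites, feats,
            out_path=out,
        )
        ids = _ids(out)
        assert any(i.startswith("motif-RBFOX1") for i in ids)
        assert any(i.startswith("feature-ALU") for i in ids)

    def test_novel_junctions_get_markers(self, tmp_path):
        gene = _gene()
        novel = SpliceJunction("c", 99, 520, "+", 4, FORWARD, novel=True)
        out = tmp_path / "fig.svg"
        render_gene_figure(
            gene, build_coordinate_map(gene, 10), [_bundle(gene, fwd=[novel])],
            out_path=out,
        )
        assert any(i.startswith("novel-") for i in _ids(out))

    def test_empty_sample_list_rejected(self, tmp_path):
        gene = _gene()
        with pytest.raises(ValueError):
            render_gene_figure(
                gene, build_coordinate_map(gene, 10), [], out_path=tmp_path / "x.svg"
            )

    def test_bundle_not_covering_gene_rejected(self, tmp_path):
        gene = _gene()
        other = CoverageVector(GenomicInterval("c", 0, 100, "+"), np.zeros(100))
        bad = SampleBundle("s", other)
        with pytest.raises(ValueError, match="does not.*cover|cover"):
            render_gene_figure(
                gene, build_coordinate_map(gene, 10), [bad], out_path=tmp_path / "x.svg"
            )

    def test_pdf_and_png_outputs_render(self, tmp_path):
        gene = _gene()
        bundle = _bundle(gene)
        cmap = build_coordinate_map(gene, 10)
        for fmt in ("pdf", "png"):
            out = tmp_path / f"fig.{fmt}"
            render_gene_figure(gene, cmap, [bundle], out_path=out)
            assert out.stat().st_size > 0


class TestFigureStyle:
    def test_invalid_styles_rejected(self):
        with pytest.raises(ValueError):
            FigureStyle(arc_thickness=(3.0, 1.0))
        with pytest.raises(ValueError):
            FigureStyle(dpi=30)
        with pytest.raises(ValueError):
            FigureStyle(exon_height=0)
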