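# splicearc

Sashimi-style visualization of **linear and circular RNA splicing** for a
single gene, across one or more RNA-seq samples.

Most mammalian genes produce several transcript isoforms, and the same
spliceosomal reaction that excises introns can also fuse a *downstream*
splice donor to an *upstream* splice acceptor, producing a covalently
closed circular RNA (circRNA). Understanding a gene's isoform repertoire
therefore means looking at forward splicing, back-splicing and coverage
*together* — something standard genome-browser tracks do not show.
`splicearc` is for RNA biologists who have aligned RNA-seq data (e.g. a
poly(A)-selected library for linear transcripts and an RNase-R-treated
library enriched for circRNAs) and want a publication-quality, fully
deterministic figure of one gene's splicing landscape.

For each sample the figure shows:

- **exon-level coverage** — each collapsed exon drawn as a box whose color
  intensity encodes its mean read depth, normalized either within the
  sample or across all samples;
- **single-nucleotide coverage** — a per-base depth polyline drawn through
  the exon row (optionally extended across introns to reveal intron
  retention);
- **forward splice junctions** — arches *above* the exons, extracted
  directly from the `N` operations of spliced alignments (or supplied as a
  junction BED), with line weight ∝ log(1 + read count);
- **back-splice junctions** — curves *below* the exons, imported from the
  BED output of an external circRNA caller;
- optional tracks of predicted **RNA-binding-protein sites** (IUPAC
  consensus scanning of the transcript sequence) and **repeat/feature
  elements** (e.g. ALU) from BED.

Because introns dwarf exons, the genomic axis compresses each intron by a
user-chosen factor while exon coordinates stay exact.

## Core conventions

All internal coordinates are 0-based half-open; GTF (1-based inclusive)
and BED (0-based half-open) are converted at the I/O boundary. A junction
is a `(donor, acceptor)` pair of base coordinates: the donor is the last
transcribed exonic base before the intron, the acceptor the first after
it. On the `+` strand a junction is a **back-splice** iff
`donor > acceptor` (mirrored on `-`): that inversion of the canonical
order is precisely what circularizes the transcript. Alignment files are
accessed through their index, region-restricted, strictly one file at a
time, so memory use is independent of BAM size.

## Worked example

The package ships a synthetic-data generator, so no downloads are needed.
This builds a 3-exon gene in which the linear isoform skips exon 2 while
exon 2 alone circularizes — the situation where exon circularization
precludes the exon's inclusion in the cognate linear transcript:

```python
from splicearc import (
    ScenarioSpec, generate_locus, simulate_reads, simulate_backsplice_bed,
)
from splicearc.cli import RunConfig, SampleInput, run

spec = ScenarioSpec(
    n_exons=3,
    isoforms=(((0, 2), 1.0),),      # linear isoform skips exon 2
    backsplices=((1, 1, 9),),       # exon-2-only circle, 9 supporting reads
    seed=3,
)
locus = generate_locus(spec, "demo_data")
sim = simulate_reads(spec, locus, "demo_data")
simulate_backsplice_bed(spec, locus, "demo_data/backsplice.bed")

run(RunConfig(
    gene="GENE1",
    annotation_path=str(locus.gtf_path),
    samples=[SampleInput("polyA+RNaseR", str(sim.bam_path),
                         bsj_bed="demo_data/backsplice.bed")],
    out_path="GENE1.svg",
))
print("truth table:", sim.truth)
```

Output:

```
INFO splicearc: gene GENE1: chrS:1000-2020 (+), 3 collapsed exons
INFO splicearc: sample polyA+RNaseR: 74 reads in region
INFO splicearc: sample polyA+RNaseR: 1 forward junctions from alignments
INFO splicearc: sample polyA+RNaseR: 1 back-splice junctions
truth table: {(1177, 1919): 26}
```

The one forward junction (donor 1177 → acceptor 1919, 26 reads) joins
exon 1 directly to exon 3, skipping exon 2; the one back-splice junction
spans exon 2 and is drawn as a curve below it. `GENE1.svg` is
byte-identical on every rerun.

The same pipeline is available from the shell:

```bash
splicearc --gene GENE1 --gtf demo_data/GENE1.gtf \
          --bam demo_data/sample.bam --label polyA+RNaseR \
          --bsj-bed demo_data/backsplice.bed \
          --fasta demo_data/GENE1.fa --motifs builtin \
          --intron-scale 10 --normalize sample --out GENE1.svg
```

Useful flags: `--normalize {sample,all}` (exon-color normalization scope),
`--intron-scale` / `--fixed-intron-width` (intron compression),
`--min-count` (junction read-count filter), `--snap` (snap junction ends
onto annotated exon edges; endpoints farther than the tolerance are kept
verbatim and marked as novel — this is how cryptic splice sites stay
visible), `--show-intron-coverage` (intron retention),
`--sj-bed` (take canonical junctions from a BED instead of the BAM),
`--format {svg,pdf,png}`, `--style style.yaml`.

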