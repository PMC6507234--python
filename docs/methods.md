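# Methods

## What the tool computes

`splicearc` quantifies and draws, for one gene, the joint evidence for
linear and circular transcript isoforms:

1. **Gene model.** All `exon` lines of the requested gene (matched by
   `gene_id`, then `gene_name`, case-sensitively) are collapsed to their
   union of maximal disjoint intervals. Adjacent (`[a,b)+[b,c)`) exons
   merge, since they are indistinguishable at per-base resolution. One
   collapsed exon chain is plotted per gene; transcript-resolved models
   are out of scope. When a gene has several isoforms this union is a
   deliberate simplification — junction arcs, not exon boxes, carry the
   isoform-level information.
2. **Coverage.** Per-base depth counts aligned (`M`/`=`/`X`) bases only;
   skipped introns (`N`), deletions (`D`), insertions and clips contribute
   zero, so depth reflects sequenced bases. Exon-level coverage is the
   arithmetic mean of depth over the exon: the mean (rather than max,
   median or total) is robust to exon length and matches the intended
   color-intensity semantics. Optional moving-mean smoothing exists for
   display; the default window of 1 leaves depths exact.
3. **Exon normalization.** Two scopes, chosen by the user: within-sample
   (each sample divided by its own max — highlights alternative splicing,
   intron retention and exon exclusion inside a sample) and across-samples
   (one global max — preserves between-sample level differences). Max, not
   sum, is the denominator because it guarantees the [0, 1] color
   contract; an all-zero scope maps to zeros rather than dividing by zero.
4. **Forward junctions.** One junction per distinct `N` gap of length ≥
   `min_intron` (default 20 nt, the conventional aligner boundary between
   deletions and introns). Junction identity is the exact
   `(donor, acceptor)` pair — no fuzzy merging — so single-nucleotide
   cryptic-site shifts remain resolvable. Junctions may instead be read
   from a BED file whose score column carries the read count.
5. **Back-splices.** Taken from the BED output of an external back-splice
   caller; a row spans the circularized exon block, so on `+` the acceptor
   is `start` and the donor `end − 1` (mirrored on `-`). Classification is
   purely positional: on `+`, back iff donor > acceptor; mirrored on `-`;
   unstranded records fall back to `+` with a warning. BAM-derived and
   BED-supplied junction sets are kept in separate tracks of a sample
   bundle and never deduplicated against each other, since they usually
   come from different library preparations.
6. **Snapping (opt-in, default off).** Junction endpoints within a
   tolerance of a collapsed-exon edge move onto that edge; farther
   endpoints are kept verbatim and flagged *novel*, and the renderer marks
   them at their true position. Off by default because cryptic-site
   analysis depends on not snapping; count mass is conserved (colliding
   junctions merge their counts).
7. **Layout.** The genomic→plot map is piecewise linear and strictly
   monotone: exons at scale 1 (within-exon plot distance equals genomic
   distance to double precision, ~1e-13 relative), introns at scale
   1/`intron_scale`. Total plot width = Σ exon lengths + Σ intron
   lengths / factor. The per-intron uniform scale is the default because
   it preserves relative intron sizes; a fixed-intron-width mode exists
   because a "make all introns small and equal" reading is also useful.
   Minus-strand genes are drawn left-to-right in genomic coordinates with
   an orientation annotation rather than mirrored, keeping position labels
   monotone.
8. **Arcs.** Forward junctions arch above the exon row, back-splices curve
   below — orientation is a pure function of junction kind. Stroke weight
   encodes the read count through log1p plus a small floor (so zero-count
   junctions remain visible); apex height encodes plot span (√span, capped
   at the panel headroom) so nested junctions stay legible. Curves are
   quadratic Béziers with apex at the midpoint.
9. **Motif sites.** Degenerate IUPAC consensus matching (not PWM scoring)
   over the spliced transcript sequence by default, the unspliced locus
   optionally. A sequence `N` matches only a consensus `N`. On `-` strand
   the reverse complement is scanned and offsets mapped back; matches that
   cross a splice border in transcript scope are split into per-exon
   genomic pieces sharing a match id, whose lengths sum to the consensus
   length. The bundled motif table (RBFOX1, HNRNPL, HNRNPA1, PTBP1, MATR3,
   RBM3) contains illustrative consensus sequences and is explicitly
   user-replaceable, not canonical.

## Rendering and determinism

SVG is the canonical output surface: every meaningful element carries a
stable id (`exon-s0-e2`, `arc-above-s0-j1`, `label-s0`, `motif-…`,
`novel-…`), text is emitted as real text nodes, element order is fixed
(background, exons, coverage, arcs, tracks, text), and with deterministic
metadata (default) the date stamp is suppressed and the internal hash salt
fixed, so identical inputs give byte-identical files. PDF and PNG are
conversions of the same figure. The coverage polyline is clipped to exons
by default (it bisects each exon box); `--show-intron-coverage` extends it
across introns, which is what makes intron retention visible.

Alignment access is via the BAM index, one region per file, one file at a
time; the I/O layer counts simultaneously open alignment files so tests
can audit the sequential-access contract. Unmapped, secondary and
supplementary records are always excluded; duplicate-flagged reads are
excluded by default (`--keep-duplicates` restores them, since whether a
visualizer should count duplicates is a judgment call); a mapq floor is
exposed and defaults to 0 (keep all) rather than hardcoding a filter.

## The synthetic-data generator

`splicearc.simulate` builds random single-gene loci (default 4 exons of
80–200 nt separated by introns of 200–800 nt — small enough for fast
tests, large enough that intron compression and junction gaps behave as
in real genes) and emits reads for a chosen isoform mix at a target
per-isoform depth (default 20×, read length 75 nt). Reads are placed at
*evenly spaced* starts along each transcript rather than drawn at random:
the package under test is a quantifier/visualizer, not an aligner, and
deterministic placement guarantees that every junction of an isoform is
supported at any depth and that the returned truth table (exact
supporting-read count per junction) holds for any seed. The seed controls
sequence content and locus geometry.

Scenario knobs map to the biological cases of interest: isoform chains
that omit exons (exon skipping), a pre-mRNA read fraction aligned as
continuous `M` (intron retention; fraction 1.0 yields zero junctions and
nonzero intronic coverage), a signed donor/acceptor shift measured
downstream in transcription direction (cryptic splice sites — e.g. a +20
acceptor shift reproduces a disrupted acceptor whose cryptic replacement
sits 20 nt downstream, and a +k donor shift retains the first k intron
bases with a novel intronic donor), and exon-block circles written as
caller-style BED rows.

What the generator does **not** emulate: sequencing error, base-quality
structure, fragment-length and positional bias, multi-mapping, chimeric
read alignment (back-splice *discovery* is the external caller's job).
Passing tests therefore demonstrate correctness of quantification,
classification, transformation and rendering on clean alignments — not
robustness to aligner artifacts.

## Numerical and degenerate-input choices

- Coordinate-map checks use double precision; width formula and inverse
  mapping hold to 1e-9, within-exon distances to ~1e-13 relative.
- `map_position` rejects positions outside the gene span; the gene's
  interval endpoints themselves are valid inputs.
- Degenerate snapping that would collapse a junction onto a single point
  keeps the junction verbatim.
- An all-zero normalization scope returns zeros; negative inputs are
  rejected rather than clamped.
- Junction sets sum counts on key collision, so re-adding evidence never
  silently overwrites.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
fixtures: ~120 randomized scenarios for the junction/classification
audits, 1000 random sequence/pattern pairs for the motif scanner, 100
random gene models for the coordinate map, six constructed splicing
scenarios (skipping, retention at 0/0.5/1, cryptic acceptor +20 nt,
cryptic donor +40 nt with retained intron head) exercised through real
sorted/indexed BAM files, and three-sample end-to-end renders. These sizes
give exact, fully reproducible expectations while keeping a full run in
the order of seconds.

## Known limitations

- One gene, one collapsed exon chain per figure; no multi-gene loci,
  transcript-level models, CRAM, GFF3 or remote files.
- Back-splice discovery is consumed, never performed; no GT–AG validation
  against the genome.
- No library-size (CPM/TPM) normalization across experiments — exon colors
  are relative within the chosen normalization scope only.
- Motif prediction is consensus matching; no PWM affinities, CLIP peaks or
  enrichment statistics.
- PNG output is rasterized by matplotlib and not guaranteed byte-identical
  across backends; determinism guarantees apply to SVG.
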