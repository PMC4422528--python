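# Methods

## Problem setting

An ENU mutagenesis screen produces mutant lines, each segregating one
causative point mutation on a shared inbred background. When the
sequenced strain is distant from the standard annotated reference, reads
are better aligned to a closely related strain-specific assembly — but
that assembly lacks gene annotation and has its own coordinates. The
package transfers exon/gene annotation onto the alternative assembly by
sequence alignment of the exons themselves, and then isolates candidate
causative variants by exploiting the experimental structure: multiple
unrelated lines on the same background, a known inheritance model per
line, and (sometimes) a linkage region.

## Lift-over model

Each catalog exon sequence is aligned against the target assembly and
exactly one best hit per exon is kept. The built-in aligner is a k-mer
seed-and-extend local aligner:

- **Seeding.** An exact k-mer index of the target (default `k = 16`) is
  queried with every k-mer of the exon and of its reverse complement;
  seed hits are grouped by (chromosome, diagonal) and nearby diagonals
  are clustered into candidates (heaviest first, at most 5 per strand).
- **Extension.** Each candidate is extended by a banded affine-gap
  Smith–Waterman (band half-width 16 around the candidate diagonal;
  match +1, mismatch −2, first gap column −4, each further gap column
  −1). Percent identity is matches / alignment columns × 100, reported
  to 2 decimals — the convention of the 12-column tabular format.
- **Best hit.** Among acceptable hits (alignment covering ≥ 70% of the
  exon, `min_coverage = 0.7`) the maximum of (score, identity, length)
  wins; remaining ties break on lowest (chromosome, start, strand), so
  selection is a deterministic function of the hit set. Exons with no
  acceptable hit are dropped and counted, not errors: low-identity or
  missing lifts are expected for diverged regions and are surfaced in
  the per-chromosome identity summary instead of being silently
  filtered.

Precomputed hits from an external aligner can be substituted through the
12-column tabular reader; minus-strand hits (subject start > end) are
normalized to ascending coordinates with the strand recorded.

**Strand convention.** Catalog exon sequences are expected in
chromosome-forward orientation; the lifted feature strand is the
composition of the source gene strand with the hit strand (two minuses
give +). Exports that provide transcript-oriented sequences must be
reverse-complemented for minus-strand genes before use.

**Gene spans** cover the outermost exon start to the outermost exon end
per gene. If a gene's exons lift to several chromosomes, the majority
chromosome wins and off-chromosome exons are excluded from the span and
logged; the gene strand is the majority exon strand (ties to +). Spans
deliberately include introns: the `GIR`/`GNR` tags answer "which genes
overlap this position", exonic containment is answered by `EID`.

## Annotation

Features are indexed per chromosome in an interval tree; a variant is
annotated by a stabbing query at its POS base only (a deletion's REF
span beyond POS is not considered — the simplest defensible convention,
and the one a position-wise annotation pipeline applies). Empty tags are
omitted; all tag lists are deduplicated and sorted, making output
byte-stable. Annotation is idempotent: the five tags are recomputed,
other INFO content is preserved.

## Filtration cascade

Per line, in order; every stage's output is a subset of its input, so
the per-line stage counts are non-increasing:

1. **Privacy + inheritance.** Keep sites where every sample of the line
   has the expected genotype — homozygous alternative (1/1) for
   recessive, heterozygous (0/1) for dominant — and every sample of
   every other line is homozygous reference. Genotypes are compared as
   unordered, unphased allele-index pairs; allele indices are taken
   literally, so at a multi-allelic site a 2/2 call does not satisfy a
   recessive 1/1 test. Missing-data policy: *strict* (default) excludes
   a site on any missing call among the tested samples; *lenient*
   accepts missing calls in other lines as compatible with homozygous
   reference (for low-coverage cohorts), but a missing call in the
   target line always excludes.
2. **Exonic restriction.** Non-empty `EID` (level `exon`, default) or
   non-empty `GIR` (level `gene`).
3. **One per gene.** A site is excluded iff *any* gene in its `GIR`
   holds ≥ 2 sites of the input set — the conservative reading for
   overlapping genes, since a mutagen hitting the same gene twice is
   highly unlikely; multi-hit genes indicate alignment or calling
   artefacts. Evaluated once against the input set, not iteratively.
4. **Linkage region.** Identity when the line has no region (the
   summary marks the stage NA); otherwise keeps sites whose POS base
   falls in any region. Regions are configured as 1-based inclusive
   `chrom:start-end` strings.
5. **ENU typing.** Flags (does not drop, unless `--enu-only`) sites
   whose ref>alt change is one of T>C, A>G, T>A, A>T — the predominant
   ENU substitution types; the set is closed under reverse complement,
   so strand conventions cannot hide a flag. At multi-allelic sites the
   flag is evaluated per alt allele actually carried by the line's
   samples. Flagged candidates carry INFO tag `ENU=1`; the summary
   counts them separately, mirroring screens that report ENU-type counts
   as a column rather than a hard filter.

## Synthetic data

The simulator emulates the experimental structure at desk scale; all
outputs are pure functions of (config, seed).

- **Genome pair.** Uniform-random source genome (default 4 chromosomes
  × 120 kb — large enough to host the default variant load at realistic
  density while keeping a full pipeline run in seconds); 60
  non-overlapping genes of 2–5 exons (100–250 bp) with 80–400 bp introns
  and random strands. The target genome applies i.i.d. substitutions at
  rate `d` (default 0.01, the regime of closely related inbred strain
  assemblies); optional small indels (1–5 bp) shift downstream
  coordinates and are recorded in a piecewise coordinate map. The
  default is no indels so that source and target coordinates coincide
  and lift-over correctness is checkable against the identity map.
- **Cohort.** Default 8 lines with 4,4,4,4,2,2,2,2 animals, lines 1 and
  4 recessive, the rest dominant, linkage regions (30 kb windows
  containing the plant, the scaled-down analogue of a marker-mapped
  interval) for lines 4, 7 and 8. 5000 shared strain variants
  (non-reference in every sample — the natural background between the
  sequenced strain and its assembly), 200 private noise variants per
  line carrying the line's *expected* genotype (the worst case for the
  privacy filter; a random-genotype mode exists), 40% of them exonic to
  stress the one-per-gene stage. Exactly one causative variant per line
  is planted in an exon of a gene untouched by noise, with ENU-type
  alleles and the line's expected genotype pattern.
- **What it does not model.** Read-level error, coverage-dependent
  missingness, real mutational spectra, CpG structure, repeats and
  segmental duplication, and real transcript structure. Passing tests
  therefore demonstrate the correctness of the algorithms under their
  stated assumptions, not performance on real exomes — in particular
  real data would add missing genotypes (exercised only synthetically
  via the missing-data policies) and repeat-induced ambiguous lifts.

## Numerical and design choices

- Coordinates are converted exactly once, at I/O boundaries: VCF and
  tabular hits 1-based inclusive on disk, everything in memory and BED
  0-based half-open.
- Serialization is canonical (sorted, deduplicated INFO; genotypes
  `a/b` ascending; no timestamps), so identical inputs yield
  byte-identical outputs.
- The banded extension returns the first-found cell among equal-scoring
  optima (lowest query index, then offset), making alignments and
  therefore all downstream outputs deterministic.
- Validation of the divergence response uses longer exons (300–500 bp):
  local alignment trims negative-scoring ends, which biases identity
  upward by O(d/L) per exon; at 300+ bp the bias is far below the
  sampling error of the mean while short-exon catalogs would confound
  the check.
- Per-line VCFs are merged only through an explicit step requiring
  identical sites and disjoint samples; the canonical input is one
  multi-sample VCF.

## Known limitations

- The one-hit-per-exon rule cannot flag paralogous placements; a
  duplicated exon lifts to whichever copy scores best (ties broken
  lexicographically). Inspect the identity summary for suspiciously
  low-identity chromosomes.
- The aligner is designed for high-identity (≥ ~90%) exon-scale
  queries; it is not a general-purpose or splice-aware aligner, and
  whole-genome chain/net lift-over is out of scope.
- INFO handling models string lists only; typed INFO fields of upstream
  callers are carried as opaque strings.
- Annotation at POS only means a multi-base deletion overlapping an
  exon boundary counts as exonic only if its anchor base does.
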