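# Methods

This note documents the models behind `glibind`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions that make runs reproducible.

## Coverage model and peak calling

A coverage track is dense per-base signal with a library size. Normalization
is per-million scaling (`x · 10⁶ / library_size`); control subtraction is
per-base `max(0, tf − control)` after both tracks are normalized, so the
result is non-negative and never exceeds the TF signal.

The caller is a thresholded run-merger rather than a statistical model:
maximal runs above a background threshold become regions, runs separated by
less than the **bandwidth** (250 bp, approximately the sonicated-fragment
size) are merged, and regions narrower than **min_width** (50 bp, to suppress
single-base noise runs; configurable) are discarded. The summit is the
leftmost position of maximum signal (a deterministic tie-break) and the
intensity score is the signal there. No Poisson/FDR peak significance,
duplicate handling, or fragment-shift estimation is attempted — the design
goal is the simplest reproducible scheme consistent with a fixed bandwidth.

The `"auto"` background is the mean of all nonzero subtracted values. This is
parameter-free and behaves sensibly when enrichment occupies a minority of the
genome: planted-peak bases dominate the nonzero mean, so the threshold lands
between background fluctuations and true apex heights. It is a global (not
local) background; strongly non-homogeneous real backgrounds would need an
explicit threshold instead.

Selection applies three criteria as a union, recording per-peak reasons:
intensity > mean + 1 sample SD of the fraction's peak intensities (one
mean/SD per fraction, not per chromosome; `ddof=1`), ≥ 1 bp overlap with a
conserved element, or another fraction's peak within 250 bp.

## MATCH scoring conventions

Matrix similarity uses natural logarithms and no pseudocounts. The
information vector is `I(i) = Σ_b f(i,b) ln(4 f(i,b))` with `0·ln 0 := 0`;
uniform columns carry zero weight, and zero-frequency bases can drive the
minimum attainable score term to 0. Only the matrix-similarity score is
computed (no separate core score), thresholds are strict (`>`), and windows
containing ambiguous bases are skipped rather than raising. A degenerate
matrix whose minimum and maximum attainable scores coincide (e.g. all-N)
scores every window 1.0, consistent with "every position holds a
maximal-frequency base". Reverse-strand scores are computed on the reverse
complement, with hit positions reported in forward coordinates.

The default Gli matrix is built from the IUPAC consensus `GACCACCCA` (the
canonical Gli-binding motif) and the default CTCF matrix from
`CCMMYYCHHGGTGG`; both are configuration values, not hard-coded truths, and
TRANSFAC-style count tables can be loaded instead.

## Interval algebra

"Within distance d" is edge-to-edge gap ≤ d with overlap counting as 0;
book-ended half-open intervals have gap 0, and the relation is monotone in d.
An alternative summit-to-summit reading exists in the literature; edge gap is
the weaker assumption and is what every join here uses. Joins are sorted
sweeps (searchsorted plus running end-maxima), so results are independent of
input order; the O(n²) pairwise definition is retained as the test oracle.

Co-occupied (GIS) records are single-linkage clusters at gap ≤ d over the
union of both fractions' peaks; clusters containing both fractions become one
record spanning the union of members, so GIS counts are cluster counts, not
pair counts. Count conservation holds as
|G1-only| + |G2-only| + |GIS members| = |selected peaks|.

Conservation bins classify every mouse region (mG1 plus the intensity-filtered
mG3 set, both already in human coordinates — coordinate liftover is an input,
not a feature) by its membership vector over (hG1, hG2, mG1, mG3), where a
region's own source set is trivially flagged. Letters are fixed identifiers:
p (mG1-only), q (mG3-only), pq (both mouse, no human — a vector the 9-letter
scheme otherwise leaves unplaced), and r…z for the nine human-overlapping
vectors in lexicographic order. The mouse Gli3 filter keeps intensities
strictly greater than 3.0; under the published Normal(5.4, 2.5) intensity
distribution this retains 1 − Φ((3.0 − 5.4)/2.5) ≈ 83% of regions, i.e. over
three quarters.

## Expression integration

DEG calling is a per-gene Welch two-sample t-test on log2 replicate values
with defaults of 1.5-fold and α = 0.05 — the thresholds are configurable
because upstream microarray pipelines vary; no multiple-testing correction is
applied by default (Benjamini–Hochberg is available). A gene's regulatory
neighborhood runs from the body end of its nearest upstream neighbor to the
body start of its nearest downstream neighbor (one neighbor per side by
default; a two-per-side reading is available via `neighbors_per_side=2`),
clipped to chromosome ends and always containing the gene body. Intergenic
regions therefore credit both flanking genes — deliberate shared credit,
since each gene's neighborhood includes its whole flanking intergenic span.

DEGs carrying ≥ 1 binding label fall into the 7 groups a–g given by the
nonempty subsets of {G1, G2, GIS}, ordered by label count then
lexicographically (a = {G1}, b = {G2}, c = {GIS}, d = {G1,G2}, e = {G1,GIS},
f = {G2,GIS}, g = all). Conservation sets use the (hG1, hG2, mG1, mG3) gene
vector restricted to conserved regions: b′/c′/f′ are the mouse-only sets
(mG1, mG3, both), a′/d′/g′ the corresponding human+mouse common-target sets,
and e′ the human-only remainder. Both letter schemes are documented
conventions; the letters themselves carry no semantics.

ΔΔCt fold changes: per sample, ΔCt = Ct(target) − mean Ct(endogenous
controls); ΔΔCt subtracts the mean carrier ΔCt; fold = 2^(−ΔΔCt).

## Synthetic-data generator

The generator is the package's study stand-in, not a sequencing simulator: it
emulates inputs at the level the analysis consumes them and skips read-level
detail (no FASTQ, error models, or alignment).

* **Genome** — i.i.d. bases at a stated GC fraction (default 0.41,
  human-like). No repeats, CpG structure, or mappability artifacts.
* **Coverage** — homogeneous Poisson background (default 0.5 reads/bp) plus,
  per planted peak, a deterministic flat-top triangular bump of width
  `frag_len` = 250 bp whose apex equals the planted intensity. The plateau
  half-width is `0.05 · frag_len` (12.5 bp), keeping the noise-free apex
  within `frag_len/20` of the planted center and the summit unambiguous under
  noise. Background is structureless by design — the simplest model under
  which mean + 1 SD filtering and control subtraction are testable.
* **Planted intensities** — drawn from the published per-fraction Normal
  parameters (mean 206.8 / SD 120.6 and 89.0 / SD 62.0 coverage units),
  truncated below at 60 so every planted peak clears the auto background
  threshold (signal-to-noise ≥ 100 at the default noise rate). Mouse region
  intensities use the published Normal(3.1, 1.4) and Normal(5.4, 2.5)
  parameters directly.
* **Region sets** — intervals placed so that a stated fraction lies within
  250 bp of a reference set (each co-occupied interval paired with a distinct
  reference so planted fractions are recoverable as cluster counts), the rest
  rejection-sampled beyond the distance.
* **Expression** — log2-scale Normal replicates around a baseline of 8.0 with
  noise SD 0.25 and planted log2 fold-change shifts.

The bundled study (`StudyConfig`) lays one gene per 1-kb block of a 50-kb
chromosome and plants binding loci inside gene bodies, so each gene's
neighborhood contains exactly its own loci and gene-level binding labels have
exact ground truth. It plants 50 peak records — 14 GLI1-only, 24 GLI2-only,
6 co-occupied pairs — giving co-occupancy 6/20 = 0.30 exactly; Gli motifs at
3 co-occupied loci and 15 single loci give motif presence 21/50 = 0.42
exactly; planted expression effects of ±2.0 log2 units at noise SD 0.25
(8 SDs) make the DEG set equal the planted set. Conserved elements cover
every planted locus (binding sites in conserved DNA), so selection reduces to
a labeling pass on this synthetic study while all three criteria are still
exercised and unit-tested separately. These sizes keep a full pipeline run
under a second; they are scaled-down emulations, and passing recovery tests
show algorithmic correctness on data matching the generator's assumptions,
not robustness to real ChIP-seq artifacts (non-uniform background, duplicate
reads, mappability, batch effects in expression).

## Determinism and numerics

All randomness flows from one root seed through spawned per-stage streams
(`numpy` `SeedSequence`), so `run-all` twice with one seed writes
byte-identical files; writers sort chromosomes and use round-trippable float
formatting. Percentages are rounded half-up to one decimal
(`Decimal`-based, avoiding binary-float rounding surprises). Summit and
consensus ties break leftmost. Degenerate inputs fail loudly: fewer than two
peaks for intensity statistics, empty peak lists for motif presence, zero
library sizes, and zero percentage denominators are errors, while empty CTCF
or region-set inputs simply yield empty sets.

## Known limitations

Real peak counts from the original deep-sequencing experiments (tens of
thousands of regions genome-wide) depend on unreleased reads and an
undocumented detection procedure, so they are emulated in structure, not
matched in magnitude. The caller has no statistical significance model; the
motif module does no de novo discovery; GO/pathway enrichment and microarray
preprocessing are out of scope.
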