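# Methods

## The density model

Chromosome conformation capture data are point patterns: each read pair is a
point `(x, y) = (pos1 - 1, pos2 - 1)` in the plane of two chromosomal axes
(pairs files store 1-based positions; everything internal is 0-based
half-open, converted once at the I/O boundary). For a viewport `V` (a
rectangle `[start_x, end_x) x [start_y, end_y)`, closed for point
membership), the Voronoi cell of pair *i* is

    C_i = { p in V : |p - s_i| <= |p - s_j| for all j },

where coincident pairs collapse to one seed `s_i` with multiplicity `m_i`.
The local density estimate is `rho_i = m_i / area(C_i)`. Because the clipped
cells tile the viewport, the estimate conserves mass: `sum m_i = n` and
`sum rho_i area(C_i) = n`. This is the classical adaptive (reciprocal-area)
Voronoi density estimator; unlike fixed bins it has no resolution
hyperparameter and never reports an empty bin.

### Tessellation numerics

The diagram is computed by Qhull through `scipy.spatial.Voronoi`; any
correct Delaunay/Voronoi construction would do, and correctness is enforced
by a brute-force nearest-seed oracle in the test suite rather than by the
choice of algorithm. Three details matter:

- **Bounding.** Every seed is mirrored across planes offset by
  `delta = 1e-6 * span` *outside* each viewport edge. The bisector between a
  seed and its mirror lies outside the viewport, so the partition inside the
  viewport is exactly the unmirrored one, while every Qhull region becomes
  bounded. The offset also guarantees a seed sitting exactly on an edge
  (retained — boundaries are closed) never coincides with its own mirror.
  Cells are then clipped to the viewport rectangle (shapely) when any vertex
  exceeds the box by more than `1e-12 * span`; otherwise vertices are merely
  clamped. Clipping to the rectangle matches the on-screen semantics: the
  viewport is the universe for all area computations.
- **Coincidence quantum.** Points closer than `1e-12 * span` are collapsed
  into one seed with summed multiplicity (genomic coordinates are integers,
  so only exact duplicates collapse in practice; the quantum exists so that
  adversarial float input cannot drive Qhull into degeneracy). Degenerate
  zero-area cells are thereby impossible.
- **Viewport size guard.** Viewports with area above 2^53 bp² are rejected;
  beyond that float64 cannot represent bp² arithmetic faithfully.

Collinear inputs need no special casing: the mirror points are never
collinear with the seeds, and the resulting cells are the expected
half-plane slabs.

### Reflection and the distance filter

For on-diagonal square viewports the contact process is symmetric under
`(x, y) -> (y, x)`, so the diagram can be computed for the upper triangle
and mirrored. `reflect_upper_triangle` builds the diagram over the
symmetrized seed set, which is identical to compute-then-mirror; mirrored
cells are exact reflections. When smoothing is requested on a reflected
diagram, the Lloyd step preserves the symmetry automatically (centroids of
mirrored cells are mirrored), which resolves the order-of-operations
question in favour of "smooth and reflect commute".

The optional filter distance `d` drops intrachromosomal points whose
*perpendicular* distance to the diagonal is below `d`, i.e. keeps
`|x - y| >= d * sqrt(2)`. The along-axis reading (`|x - y| >= d`) was the
other candidate; the perpendicular one is adopted because the filter is
defined as a distance *from the x = y axis*, and is documented here as an
interpretation.

### Large inputs

Above `max_points` (default 100,000) the per-cell diagram is replaced by a
fixed grid with one bin per output pixel — cells smaller than a pixel would
be unresolvable anyway — and re-querying a smaller region that falls back
under the threshold returns a true diagram again. The threshold is strict
(`n > max_points` triggers binning), so exactly 100,000 points still get a
tessellation.

## Lloyd smoothing

One iteration replaces each seed by the area centroid of its clipped cell
(signed-area decomposition formula) and rebuilds the diagram; multiplicity
travels with the centroid (mass is conserved, never re-split). Iteration
drives the tessellation toward a centroidal one and never increases the
quantization energy `sum_i int_{C_i} |p - s_i|^2 dp` (checked numerically on
a fixed Monte-Carlo sample). Exact co-location of centroids and seeds is
unattainable in floating point, so "converged" means the largest seed
displacement fell below `1e-6 * max(viewport width, height)`. Default
smoothing for figures is one iteration; zero disables.

## High-frequency-contact calling

Intrachromosomal pairs of one chromosome at a time are tessellated over the
full chromosome square `[0, L)^2` (upper-triangle seeds, no reflection — the
density of each pair must come from its actual neighbours). From the
*unsmoothed* diagram, each pair at separation `s >= min_distance` becomes an
observation `(log s, log rho)`. Design choices:

- **Distance floor** `min_distance = 1,000 bp` (configurable): separations
  below that are dominated by self-ligation/religation artifacts and are
  excluded from fitting and scoring (they still shape the tessellation).
- **Background fit.** `log rho = a + b log s + eps`, fitted robustly. The
  estimator is an MM-type composition: Siegel repeated-median regression on
  a deterministic 2,000-point stride subsample as the high-breakdown initial
  fit (exact Siegel is O(n²)), normal-consistent MAD of its residuals as the
  fixed scale, then bisquare IRLS (`c = 4.685`, 95% efficiency at the
  Gaussian) via statsmodels RLM. The fit is deterministic given input order.
  One fit per chromosome — distance decay varies between chromosomes;
  genome-wide pooling is possible by concatenating observations.
- **Scoring.** `z = (log rho - a - b log s) / scale` with `scale` the
  normal-consistent MAD of the final residuals; `p = 1 - Phi(z)`
  (one-sided: only densities above background are interesting).
- **Selection.** Benjamini–Hochberg step-up at FDR 10% (statsmodels
  `multipletests`, cross-checked against a hand-rolled step-up in tests).
- **Binning.** Retained pairs are counted in 5,000 bp square bins anchored
  at coordinate 0 (bin k covers `[5000k, 5000(k+1))`); bins with at least 5
  retained pairs are emitted with their support and mean z. Interchromosomal
  pairs have no separation and are excluded from calling.

### Known limitation: the Gaussian tail of the z-test

For a locally Poisson point pattern the normalized Voronoi cell area is
approximately Gamma-distributed (shape ≈ 3.6), so the right tail of
`log rho` decays *exponentially*, not like a Gaussian. The one-sided normal
p-values are therefore anti-conservative far in the tail — exactly where BH
with tens of thousands of tests operates (p ≈ 1e-4 … 1e-6). The package's
null-simulation study (`voronoi3c.evaluation.null_fdp_replicate`, run by
`scripts/acceptance.py` and the test suite) quantifies this: on pure
power-law background with 50,000 pairs, BH at nominal FDR 10% retains a few
dozen pairs in every replicate, so the realized pair-level false-discovery
proportion is 1.0 rather than ≤ 0.10. The practical false-positive control
comes from the *bin-level* support filter: the spurious retained pairs are
scattered, and bins collecting ≥ 5 of them essentially never occur (0 per
replicate in the same study). Users should treat the pair-level FDR as a
ranking device, not a calibrated error rate; calibrating the tail (e.g.
Gamma-based p-values) would change the method and is deliberately out of
scope.

## Pileup and signal enrichment

The expected model is the standard cis distance-decay track computed
in-package: for each diagonal offset `d` (in 5 kb bins),
`expected(d) = (sum of counts at offset d) / (number of bin pairs at offset
d)`, so the model reproduces the total contact count exactly. No balancing
or iterative correction is applied; absolute enrichment values on real data
will therefore differ from analyses that use a balanced expected.

Each candidate bin is extended by 10 bins (50 kb) in all directions giving a
21 × 21 observed/expected matrix; pixels with zero expected are recorded as
missing and dropped from block means, never imputed. The enrichment divides
the mean of the centre 3 × 3 block (rows/cols 10–12, 1-based) by the mean
over five 3 × 3 background blocks: upper-left (1–3 × 1–3), upper-middle
(1–3 × 10–12), upper-right (1–3 × 19–21), middle-right (10–12 × 19–21) and
lower-right (19–21 × 19–21). The blocks are used exactly with these printed
coordinates (pinned by unit tests). A zero background mean yields a
distinguished infinite/excluded value; aggregates report the mean over
finite enrichments together with the finite count. Windows that would cross
the matrix edge or touch the diagonal (centre closer than 21 bins to it) are
excluded with a warning, since lower-triangle pixels would otherwise mirror
into the window.

## Synthetic data

The generator emulates three gross features of a cis micro-C map:

- **Distance decay.** The background 2D contact *intensity* at separation
  `s` is proportional to `s^-alpha` (default α = 1, floored at 1,000 bp to
  mirror the caller's distance floor). This is the field's standard meaning
  of a power-law distance decay — it is what a P(s) curve and a
  diagonal-mean expected measure, both of which normalize counts by the
  number of locus pairs at each separation. Sampling: `s` from the truncated
  power law by inverse CDF, the left end uniform on the chromosome, and the
  pair rejected when the right end falls off the chromosome; acceptance is
  proportional to `(L - s)`, so the realized marginal separation
  distribution is `s^-alpha (L - s)` while the per-locus-pair frequency is
  exactly `s^-alpha`. (Sampling the *marginal* as a pure power law instead
  would pile points into the anti-diagonal corners at 2D intensity
  `s^-alpha / (L - s)`, a background the log-linear caller model cannot
  represent near `s -> L`.)
- **TADs** as intervals with a within-block multiplier, applied by
  rejection against the maximum multiplier.
- **Loops** as anchor pairs with Gaussian positional jitter (default SD
  500 bp) and a fixed number of extra pairs; every planted loop's 5 kb bin
  (same 0-anchored grid as the caller) is written to a truth table.

Output is sorted, upper-triangle normalized, valid pairs format with
chromsize header lines; identical spec and seed give byte-identical files.
What the generator does *not* emulate: compartment checkerboards, polymer /
loop-extrusion mechanics, mappability gaps, duplicate reads and trans
contacts. Passing tests on this generator therefore demonstrate the
correctness and calibration of the pipeline's machinery under its own
background model, not performance on real micro-C libraries.

`truth_eval` reports exact-bin recall and a proximity precision proxy
(called bin within Chebyshev distance 1 of a truth bin — jitter legitimately
shifts a called bin by one); with nothing called, precision is reported as
1.0 with an explicit zero-support flag.

## Problem sizes used in the shipped studies

Evaluation studies are sized to be convincing yet quick: the null study uses
10 replicates of 50,000 pairs on a 50 Mb chromosome; planted-loop recovery
uses 5 replicates of 20 loops (15 pairs each, 500 bp jitter) over 50,000
background pairs; the enrichment study plants 50 loops over 100,000
background pairs on 25 Mb so that most loops have nonzero background blocks.
Geometry oracles run 30 random seed sets against brute-force nearest-seed
labelling of 10,000 probes each.

## I/O conventions

Pairs files: `#`-prefixed header including a `## pairs format` line and
optional `#chromsize:` lines (chromosome order of appearance defines the
order used for upper-triangle normalization); 7+ tab-separated body columns,
extra columns preserved verbatim as opaque payload. BGZF input is detected
by magic bytes and read through pysam; plain gzip falls back to the gzip
module. The tile index is a versioned JSON sidecar (`<file>.tiles.json`)
mapping `(chrom1, pos1-tile)` to byte ranges — BGZF virtual offsets for
compressed files — and requires input sorted by `(chrom1, pos1)`; an
explicit unsorted flag produces an index that forces linear scans. Indexed
region queries return exactly the multiset a linear scan returns (tested on
randomized regions). Interact files use the 18-column UCSC layout with the
exact score carried in the `value` column (the integer `score` column is
clamped to the browser's 0–1000 range), plus a minimal 5-column
intrachromosomal form `chrom  sourceStart  sourceEnd  targetStart
targetEnd` accepted on input.
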