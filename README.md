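# voronoi3c

Voronoi-diagram density estimation, visualization and high-frequency-contact
calling for chromosome conformation capture (3C / Hi-C / micro-C) read pairs.

## Why adaptive bins

A sequenced ligation product — a read pair — marks two genomic loci that were
spatially close, and plots as a point `(pos1, pos2)` in the plane spanned by
two chromosomal axes. The conventional interaction matrix counts read pairs
in fixed square bins, forcing a single resolution on data whose density
varies by orders of magnitude between the diagonal and long-range regions.
The Voronoi diagram inverts this: every read pair *i* owns the convex polygon
`C_i` of plane points nearer to it than to any other pair, and

```
rho_hat(i) = m_i / |C_i|
```

(`m_i` = number of coincident pairs collapsed onto the seed, `|C_i|` = the
polygon's area clipped to the viewport) is a local density estimate whose
bins shrink exactly where contacts cluster. Cells tile the viewport, so
`sum_i rho_hat(i) |C_i| = n` — density mass is conserved. Optional Lloyd
iteration (moving each seed to its cell centroid and retessellating) smooths
neighbouring cell areas toward local equality, making focal contacts easier
to see; figures conventionally use a single iteration.

On top of the estimator the package implements a simple loop caller: for
each chromosome the background is modelled as

```
E[log rho | s] = a + b log s        (s = |pos2 - pos1|)
```

fitted by a robust MM-type regression (bisquare, 95% Gaussian efficiency).
Each pair is scored with a one-sided z-test of its log density against this
background, Benjamini–Hochberg selection at FDR 10% retains the
significantly dense pairs, and 5,000 bp square bins holding at least 5
retained pairs are reported as high-frequency contacts. A companion pileup
module extracts 21 × 21 observed/expected windows (the candidate bin
extended by 10 bins = 50 kb in every direction) against a diagonal-mean
expected track and summarizes them by the centre-over-background signal
enrichment.

## What's in the box

- `voronoi3c.pairs` — 4DN pairs format I/O (plain text or BGZF), a JSON tile
  index for random access, UCSC interact files.
- `voronoi3c.voronoi` — viewport-clipped Voronoi diagrams, reciprocal-area
  densities, diagonal reflection, distance filtering, and a fixed-grid
  fallback above 100,000 points.
- `voronoi3c.smoothing` — centroidal (Lloyd) smoothing.
- `voronoi3c.calling` — robust distance-decay background fit, pair scoring,
  BH selection, loop-bin emission, bin-list overlap.
- `voronoi3c.pileup` — expected-by-distance model, per-loop pileups,
  aggregate signal enrichment.
- `voronoi3c.simulate` — synthetic pairs files with power-law distance
  decay, TAD blocks and planted loops, plus truth tables and an evaluator.
- `voronoi3c.render` / the `v3c` CLI — Voronoi, heatmap and triangle figure
  export (`v3c view`, `v3c index`, `v3c call-loops`, `v3c pileup`,
  `v3c simulate`).

## Worked example

```python
import voronoi3c as v3c

spec = v3c.SimSpec(chrom="chr1", length=10_000_000, n_pairs=30_000, alpha=1.0,
                   loops=(v3c.LoopSpec(2_000_000, 2_400_000, 15, 500.0),
                          v3c.LoopSpec(5_102_000, 5_700_000, 15, 500.0),
                          v3c.LoopSpec(7_253_000, 8_000_000, 15, 500.0)),
                   seed=1)
result = v3c.simulate_pairs(spec, pairs_path="example.pairs")

loops, fits = v3c.call_loops(result.records, {"chr1": spec.length})
print(fits["chr1"].summary())
print(v3c.loops_to_table(loops).to_string(index=False))

grids = v3c.bin_contacts(result.records, {"chr1": spec.length})
expected = v3c.expected_by_distance(grids["chr1"])
mean_e, n_finite = v3c.aggregate_enrichment(loops, grids["chr1"], expected)
print(f"mean signal enrichment {mean_e:.2f} over {n_finite} bins")
```

prints

```
Background distance-decay fit (robust linear model)
===================================================
estimator            mm-bisquare
n observations       30045
intercept (nat log)  -8.259862
slope (nat log)      -0.963175
residual scale        0.668103
chrom  bin_x_start  bin_y_start  support    mean_z
 chr1      1995000      2400000        5 13.316827
 chr1      5100000      5695000        7 11.244587
 chr1      5100000      5700000        5 11.294177
 chr1      7250000      7995000       11 10.964327
mean signal enrichment 65.64 over 2 bins
```

The fitted slope ≈ −0.96 recovers the simulated decay exponent (α = 1, with
a small tilt from short-range boundary effects); all three planted loops are
found — the second splits across two adjacent 5 kb bins because its jittered
pairs straddle a bin boundary — with mean z-scores of 11–13 background
scale units. Two of the four bins sit over background windows dense enough
for a finite observed/expected enrichment; their average is 65.6, the
planted dots standing far above the decay background. The same analysis
from the shell:

```sh
v3c simulate --chrom chr1 --length 10000000 --n-pairs 30000 --seed 1 \
    --loop 2000000,2400000,15,500 --out example.pairs
v3c index example.pairs
v3c view --pairs example.pairs --region chr1:1,900,000-2,500,000 \
    --mode voronoi --smooth 1 --out region.svg
v3c call-loops --pairs example.pairs --out loops.interact --table loops.tsv
v3c pileup --pairs example.pairs --loops loops.interact --figure-out agg.png
```

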