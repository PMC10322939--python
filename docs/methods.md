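# Methods

## Model

A base-resolution genomic signal `g(z)` is aligned simultaneously to an
oriented pair of landmarks — an upstream TSS `z_U` and a downstream TSS
`z_D` of the same gene — by the coordinate expansion `x = z − z_U`,
`y = z − z_D`.  Each pair places its signal on the line
`y = x + z_U − z_D`; a set of pairs at different separations covers a 2D
region of the `(x, y)` plane.  All offsets are transcription-oriented:
for a minus-strand gene, offset `+k` reads `k` bases toward smaller
genomic coordinates, and "most upstream" means the largest coordinate.
Consequently `z_U − z_D` in the formulas is the *oriented* difference,
always `−d` for pair distance `d > 0`.

The rectangular region average `R_V` over a pair set `V` is the mean of
`g` over all (pair, base) terms whose expanded coordinates fall in the
inclusive rectangle `[(x0,y0),(x1,y1)]`.  The Kronecker-delta constraint
reduces the inner double sum to the single x-interval
`[max(x0, y0+d), min(x1, y1+d)]` per pair; `N` is the summed interval
length, the average is `undefined` (not an error, and never
pseudocounted) when `N = 0`, which happens exactly when no pair
satisfies `y0−x1 ≤ −d ≤ y1−x0`.  A literal `O(|V|·area)` brute-force
twin of the computation is retained purely as a testing oracle and
refuses regions above a configurable area cap.

Densities `G(x,y)` evaluate `R_V` in moving windows centered at grid
points, with half-widths `n_X = 99` for `−500 ≤ x ≤ 1000`, `⌊x/4⌋` for
`1000 < x ≤ 20000`, and mirrored rules for `n_Y` in `y`.  The floor in
`⌊x/4⌋` keeps half-widths integral (the rule is stated as `x/4` without
a rounding convention; flooring is our choice).  Windows extending past
chromosome ends read zeros that still count in `N`, consistent with the
signal layer's boundary convention, so distal windows near contig edges
never abort a sweep.  The three-landmark extension adds `v = z − z_F`
with a second delta constraint and is implemented by direct enumeration
only; no efficiency derivation is provided because triple analyses are
exploratory.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| window half-width rules | 99 / coordinate÷4 | bp | fixed analysis constants of the method |
| analysis domain | x ∈ [−500, 20000], y ∈ [−20000, 1000] | bp | covers the seven canonical regions |
| grid spacing | 25 bp where \|coord\| ≤ 1 kb, then half-width/2 | bp | resolves 99 bp windows near TSSs without oversampling smoothed distal zones; the evaluation grid is a non-normative choice |
| `min_count` | 1 | terms | literal definition: only `N = 0` cells masked; raise to hide thinly supported cells |
| normalization mode | `all` | — | genome mean over all whitelisted bases including zeros ("average over the whole genome" read literally); `covered` mode available |
| concordance threshold | ρ > 0.8 | — | Spearman gate on replicate gene quantifications; failure warns, never aborts, because experiment selection is upstream of this tool |
| stratification | zero floor + 5 equal-count bands | — | configurable band count; an alternative scheme stratifies pairs by their own region-C average quintile |

TSS handling: transcript 5' ends (GTF `start` on plus, `end` on minus,
converted to 0-based), duplicates across transcripts collapsed before
ordering so zero-distance pairs cannot occur, enumeration from the most
upstream TSS in transcription orientation.  Genes are treated
independently even when they overlap on opposite strands.  Negative
track values (minus-strand coverage files commonly store negated
coverage) are folded to absolute values by default (`error`/`zero`
modes available).

## Derived metrics

The seven canonical rectangles and eight log2 ratios are listed in the
README.  Two conventions deserve note.  First, *persistence dominance*
is defined here as the log2 ratio of the two persistences,
`(T_Bf/T_B)/(T_Af/T_A)`; it is named alongside the persistences and
signal dominance but is not given an explicit formula in the source
material, so this definition is our own and is flagged prominently.
Second, a ratio is reported *absent* with a machine-readable reason
(`undefined:T_A`, `nonpositive:T_B`, …) whenever a constituent average
is undefined or non-positive; pseudocounts would bias exactly the small
pair sets where absences occur.  Replicate mean and noise are the
half-sum and half-difference of the two replicates' log2 values; the
reconstruction identities (mean ± noise = the replicate values) are
algebraic and hold in floating point to one unit in the last place.
Pair-position summaries report pair 1, pair 2, and the unweighted mean
of the log2 metric over pair indices 3–10 (averaging log2 metrics per
index rather than pooling pairs before averaging; a config switch pools
instead).

## Synthetic data: what it emulates, and what it does not

The generator places non-overlapping genes on both strands of a small
multi-chromosome genome (default: 300 genes, 1–6 TSSs each, ~2 Mb).
Each TSS contributes additively a transcript-body profile: an optional
initiation pulse, a plateau to the shared 3' end, and an exponential
tail beyond it (`decay_length`, truncated at six lengths).  Gene
expression is log-normal across genes (`expr_sigma = 0.75`); replicates
share all structure and differ by per-gene log-normal noise
(`noise_sigma = 0.3`).  Inter-TSS spacings come from a mixture of
uniform bands so proximal, intermediate, and distal separations are all
populated.

Two effects can be planted. *Suppression*: a TSS whose next TSS lies in
`suppression_range` (default 200–900 bp, matching the intermediate
region band) has its initiation scaled by `s`. *Cooperativity*: when
consecutive TSSs are within `coop_max_distance` (200 bp), the total
signal in the window `coop_extent` (1 kb) downstream of the downstream
TSS is scaled by `q`.  Scaling the window rather than only the
downstream TSS's own contribution is deliberate: with additive
read-through, scaling one contribution would plant a measurable
proximal-cooperativity of `log2((q+a)/(1+a))` with `a` the read-through
fraction — not a recoverable ground truth.  Window scaling plants
exactly `log2 q`.  For the same reason the recovery configuration
(`SynthConfig.recovery`) uses flat transcript bodies (pulse height 1)
and bodies long enough (21 kb past the last TSS) to cover the distal
reference regions: a concentrated profile makes region averages depend
on per-pair window area (region C windows are `201−d` wide versus 201
for region E), which would bias the planted ratio by the window-size
mismatch.  Under this design the expected recoveries are exactly
`log2 s` for upstream effects and `log2 q` for proximal cooperativity,
and the positional dominance of the generator's truth is `+1`
(read-through doubles the signal downstream of the second TSS).

What the generator does **not** emulate: splicing and intron/exon
coverage structure, RAMPAGE 5' chemistry, ChIP fragment-size effects,
mappability gaps, overlapping genes, or cell-type-specific TSS usage.
Passing recovery tests therefore demonstrates that the estimator
recovers planted interaction ratios under additive coverage with
realistic expression dispersion — not that real RNA-seq effects of a
given size will be estimated without bias from those unmodeled features.

## Problem sizes and numerical choices

Recovery experiments use 20 independent genomes of 300 two-TSS genes
per condition (suppression, cooperativity, null) and test the mean
against the planted value within three standard errors across seeds;
the whole set runs in well under a minute.  Randomized oracle
comparisons use 120 instances with signals ≤ 5 kb, ≤ 20 pairs and
rectangles ≤ 51×51, small enough for the literal double sum.  Density
grids hold per-pair prefix sums over the needed offset range (~60 MB
for 300 pairs over the full domain); larger pair sets should be
chunked.  Region averages accumulate per-pair slice sums in order, so
genome mirroring reproduces values bitwise.  Ties in Spearman
correlation use average ranks; ties in activity stratification are
broken by gene id for determinism.

## Known limitations

* `region_average_3d` is enumeration-only and impractical for wide boxes.
* The evaluation grid and low-N masking threshold are conventions, not
  part of the method definition; figures produced with different grids
  will differ in sampling, not in the underlying `R_V`.
* The genome-wide mean includes uncovered bases by default; for sparse
  tracks (e.g. RAMPAGE) the normalized values are therefore large where
  covered, which cancels in all derived ratios but matters when
  comparing absolute densities across assays.
* Landmark pairs are restricted to consecutive TSSs of one gene;
  cross-gene pairs are out of scope.
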