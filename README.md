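# tssgrid

Multi-landmark alignment of base-resolution genomic signals.

Classic metagene analysis aligns a signal track to a single reference
landmark (for instance a transcription start site) and averages over
many landmarks to obtain a 1D profile `G(x)`.  That collapses away any
dependence on *other* nearby landmarks — yet most regulatory regions
contain several, and alternative TSSs of the same gene demonstrably
influence one another.  `tssgrid` aligns a signal to **pairs** (and
triples) of landmarks simultaneously by expanding the genomic coordinate
`z` into relative coordinates

```
x = z − z_U      (offset from the upstream landmark)
y = z − z_D      (offset from the downstream landmark)
```

so each oriented landmark pair contributes signal along the line
`y = x + z_U − z_D` of the `(x, y)` plane, and many pairs at different
separations tile a two-dimensional density `G(x, y)` — the 2D analogue of
a metagene profile.  The package is aimed at epigenomics and
transcriptomics analysts working with strand-specific RNA-seq / RAMPAGE /
DNase-seq / ChIP-seq coverage tracks and Gencode-style annotations.

## What it computes

**Region averages.** For a pair set `V` and an inclusive rectangle
`[(x0,y0),(x1,y1)]`, the average signal is

```
R_V = (1/N) Σ_{{z_U,z_D}∈V} Σ_{x=x0}^{x1} Σ_{y=y0}^{y1} g(x+z_U) δ_{y, x+z_U−z_D}
```

where `δ` is the Kronecker delta and `N` counts the contributing
(pair, base) terms.  The delta collapses the double sum to one
x-interval per pair, `x ∈ [max(x0, y0−z_U+z_D), min(x1, y1−z_U+z_D)]`,
which makes genome-scale sweeps linear in the signal retrieved; a literal
brute-force twin is kept as a testing oracle.  The average is defined
only if some pair satisfies `y0−x1 ≤ z_U−z_D ≤ y1−x0`.

**Signal densities.** `G(x,y)` evaluates `R_V` in moving rectangular
windows of half-widths `n_X = 99` for `−500 ≤ x ≤ 1k` and `⌊x/4⌋` for
`1k < x ≤ 20k` (mirrored for `n_Y` in `y`), so resolution is high near
the landmarks and windows widen with distance.

**Interdependence metrics.** Seven canonical rectangles
(`T_A, T_Af, T_B, T_Bf, T_C, T_D, T_E`) probe signal just downstream of
either TSS while the partner TSS is proximal, intermediate, or distal.
Eight log2 ratios follow: proximal cooperativity `T_C/T_E`, upstream
effects `T_B/T_A`, downstream effects `T_D/T_E`, positional dominance
`T_E/T_A`, persistence with a distal / non-distal downstream TSS
`T_Af/T_A` and `T_Bf/T_B`, signal dominance `T_Bf/T_Af`, and persistence
dominance `(T_Bf/T_B)/(T_Af/T_A)`.  Replicate mean and noise are the
half-sum and half-difference of the two replicates' log2 values, and a
Spearman `ρ > 0.8` gate flags low replicate concordance.

## Worked example

Generate a synthetic genome with a planted upstream-suppression effect
(`s = 0.25` for inter-TSS distances in 200–900 bp) and recover it:

```python
from tssgrid.annotation import PairSet, consecutive_pairs
from tssgrid.metrics import metrics_panel
from tssgrid.synth import SynthConfig, generate_annotation, generate_signal

cfg = SynthConfig.recovery(s=0.25)        # 300 two-TSS genes
ann = generate_annotation(cfg, seed=1)
sig, quant = generate_signal(ann, seed=1)
sig = sig.normalize()                     # genome-wide mean -> 1 per track

pairs = PairSet(consecutive_pairs(ann.genes, 1), pair_index=1)
panel = metrics_panel(sig, pairs)
print(round(panel.derived["upstream_effects"], 3))
print(round(panel.derived["positional_dominance"], 3))
```

prints

```
-1.946
1.0
```

`upstream_effects ≈ −1.95` recovers `log2 0.25 = −2` up to sampling noise
(each seed draws 300 genes with log-normal expression): signal just
downstream of an upstream TSS with an intermediate-distance neighbor
(region B) is about four-fold lower than with a distal neighbor
(region A).  `positional_dominance = 1.0` reflects the generator's
additive read-through: downstream of the second TSS both transcripts
overlap, doubling the signal relative to region A.

The same pipeline runs from the shell on files:

```
tssgrid make-fixtures --out fx --seed 7 --n-genes 50
tssgrid metrics --config run.yaml      # region/metric tables, replicate stats
tssgrid density --config run.yaml      # G(x,y) matrices per pair index/stratum
tssgrid plot --grid out/density/pair1.all.density.tsv --out heat.png
```

where `run.yaml` names the annotation, the strand-specific tracks per
replicate, gene quantifications, pair indices, and the stratification
scheme (gene-activity quantiles or per-pair region-C quintiles).

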