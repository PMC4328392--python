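# fiberlayer

Layer-stratified quantification of fluorescently labeled axonal projections
in laminar brain sections, built around the analysis used to map raphe →
olfactory-bulb innervation: which layers of a concentrically layered
structure (granule cell layer GCL, external plexiform layer EPL, glomerular
layer GL) receive label, whether two channels mark the same fibers, and
whether an animal's projection pattern tracks where its tracer injection
actually landed.

It is aimed at anatomists quantifying anterograde/immunofluorescence label
in tissue sections, and comes with a fully ground-truthed synthetic section
generator so every stage can be validated without any real microscopy data.

## What it computes

**Signal density per layer.** Ten square samples (120 × 120 μm) are placed
per layer, at most one per 36° sector around the layer centroid, using only
the anatomy mask. Each sample is despeckled (3×3 median) and
background-subtracted (rolling ball, 30 μm radius = 210 px at the reference
calibration of 7 px/μm). For each animal the pooled pixel statistics over
all its samples define a global threshold

&nbsp;&nbsp;&nbsp;&nbsp;T = μ + k·σ, k = 6,

and the signal density of a layer is

&nbsp;&nbsp;&nbsp;&nbsp;D = 100 · (# pixels > T) / (# pixels analysed)  [μm²/100 μm²].

Layers are compared with a one-way ANOVA (animal as unit) plus Tukey HSD
post-hoc tests.

**Pixel colocalization.** The van Steensel shift correlation: Pearson's r
between two channels as a function of an integer displacement dx of one
channel. True colocalization peaks at dx = 0; the null control repeats the
curve after rotating one channel by 90°. Cohort-level inference is a paired
t-test of per-sample peak r against the rotated control.

**Marker colocalization.** One-to-one greedy matching of point annotations
by globally closest pair within a 12 μm cutoff, with mean ± SD across
manual count replicates.

**Association.** Per animal, x = log10((n_MRN + 1)/(n_DRN + 1)) infected
cells and y = log10((D_GL + c)/(D_GCL + c)) label densities; the package
reports Pearson r and p across animals, and the scatter colour encoding
RGB = (L, 0.8(1−L), 1−L) with L = y clipped to [0, 1].

## Worked example

```sh
fiberlayer synthesize --seed 13 --out runs/demo/data
fiberlayer density   --seed 13 --data runs/demo/data --out runs/demo/density
fiberlayer coloc     --seed 13 --data runs/demo/data --out runs/demo/coloc
fiberlayer associate --seed 13 --summary runs/demo/data/summary.csv --out runs/demo/assoc
```

With the default configuration (three animals at 7 px/μm, GL-dominated
fiber field at 0.014 μm²/100 μm² with sparse EPL/GCL label, full noise
model) the density stage prints

```
9 density records written to runs/demo/density
ANOVA across layers: F = 1221, p = 1.473e-08
```

and `runs/demo/density/stats.txt` holds the per-layer summary:

```
layer     mean      sem  n
  EPL 0.000397 0.000262  3
  GCL 0.000732 0.000087  3
   GL 0.015216 0.000315  3

layer_a layer_b  meandiff  p_adj   lower  upper  reject
    EPL     GCL    0.0003  0.615 -0.0007 0.0014   False
    EPL      GL    0.0148  0.000  0.0138 0.0159    True
    GCL      GL    0.0145  0.000  0.0134 0.0155    True
```

— the GL is the significantly dominant target, as generated, and the
estimated GL mean (0.0152) tracks the generated densities. The coloc stage
(channel pairs sharing 80 % of fibers) prints

```
20 samples: mean peak dx = 0.00 ± 0.00 px, paired t vs control p = 7.45e-32
```

i.e. a peak at zero displacement that the rotated control does not show,
and the associate stage prints `r = 0.996, p = 2.48e-06, n = 7`: animals
with relatively more MRN infection carry relatively more GL label.
(Exact numbers vary with the seed; these are the outputs of the commands
above with `--seed 13`.)

Each stage also works as a plain library; see the module docstrings in
`src/fiberlayer/` and the tests for usage.

## Limitations

Masks are inputs (no automatic layer segmentation from the nuclei
channel); images are 2-D (projections, not stacks); no PSF/photophysics in
the generator; no Costes/Manders-style colocalization beyond the two
methods above. See `docs/methods.md` for the model, parameter defaults,
and design rationale.
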