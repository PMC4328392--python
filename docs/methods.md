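# Methods

## The measurement model

The package quantifies where fluorescently labeled axonal projections land
within a concentrically layered structure. A section is represented by a
label mask (background, GCL, EPL, GL from inside out, sharing the image
grid) plus one or two intensity channels with a pixels-per-μm calibration.
The reference calibration is 7 px/μm; every μm↔px conversion goes through
one utility with a single rounding convention (round-half-even), so the
30 μm ball radius is always 210 px and the 120 μm ROI always 840 px at
that calibration.

The density estimator deliberately mirrors a manual-microscopy workflow
rather than a globally optimal segmentation: stratified square samples,
per-sample cleanup, one global per-animal threshold, and a pixel-fraction
density. Its virtues are simplicity and robustness to illumination
differences between animals (the threshold is fitted per animal, making
detection invariant to any positive rescaling of that animal's images);
its cost is sampling noise, quantified below.

## Stage-by-stage choices

**Sampling.** Ten ROIs per layer, at most one per 36° sector about the
layer's pixel centroid, drawn uniformly from centres whose full square
footprint lies inside the layer (rejection sampling against a summed-area
table, capped at 1000 candidate draws per sector). The angular origin is
"3 o'clock", increasing counter-clockwise; the convention is arbitrary but
fixed by tests. Placement sees only the mask — the API takes no signal
channel, so sample positions cannot be conditioned on label. "One per
sector" is enforced exactly, with failed sectors reported rather than
silently dropped; a layer band narrower than the ROI side yields an empty
placement with all sectors reported. ROI sides are rounded to even pixel
counts so the 90° rotation used by the colocalization control maps a
sample onto its own grid. Same-layer ROIs in adjacent sectors may touch or
overlap; this is permitted and visible in the ROI table.

**Preprocessing.** "Despeckle" is fixed to the 3×3 median filter (the
ImageJ definition); the window is config-exposed but defaults are part of
the study conditions. Background subtraction is grayscale opening with a
spherical-cap structuring element of the given radius. Up to 32 px radius
the opening is computed exactly; above that it runs on a block-minimum
downsampled grid (factor ≈ radius/24) with bilinear upsampling of the
background — the standard fast rolling-ball construction. The
approximation is held to ≲1 % of a typical fiber amplitude against the
exact opening in tests. Both filters replicate edges (no zero-padding
halos that would bias border ROIs), run in floating point, and compose in
a fixed order: despeckle, then subtract background. The background
estimate is additionally clamped to ≤ the image so the output is always in
[0, input].

**Detection and density.** Threshold = pooled mean + 6 × pooled population
SD over all samples of an animal; "above" is strict. Population rather
than sample SD: at ~10⁷ pooled pixels the difference is ~10⁻⁷ relative,
but fixing it keeps runs bit-reproducible. Density is 100 × detected/total
pixels — the μm² calibrations of numerator and denominator cancel, so the
μm²/100 μm² unit equals percent area; the calibration is still carried on
every record. On pure Gaussian noise the 6σ rule fires on ≲10⁻⁹ of pixels
(Gaussian tail), and the median filter thins tails further; the measured
false-positive fraction over 10 rasters of 840² is reported by the
acceptance script. A `threshold_sensitivity` sweep over k is provided as a
report; the default sweep range (k = 4…8) is a package choice, as no
canonical range exists.

**Statistics.** One observation per animal per layer; one-way ANOVA sums
of squares are computed in-package (so the degenerate all-equal case is
defined as F = 0, p = 1) with the p-value from the F distribution; Tukey
HSD comes from statsmodels. The paired colocalization test is a two-sided
paired t of per-sample peak r against the rotated control, with the
zero-variance case flagged degenerate rather than silently NaN.

**Shift correlation.** Positive dx displaces the second channel towards
+columns, so a channel translated by +s peaks at −s; the convention is
fixed by an exhaustive recovery test over shifts −10…10. r is computed
over the overlap region only; the default range D = 50 px (~7 μm) with
D < side/2 guarantees ≥ half overlap. The vertical-displacement curve is
available via `axis=0` and behaves equivalently. Per-sample peak
displacement is the integer argmax (ties resolved towards 0); sub-pixel
cohort summaries arise as means over integer per-sample peaks. The
pipeline operates on 2-D rasters (projections); per-volume correlation
over confocal stacks is out of scope.

**Marker matching.** Greedy one-to-one matching by globally smallest
cross-channel distance within the cutoff. On unambiguous configurations
(the generator enforces 3 × cutoff separation for non-partners) greedy
matching coincides with the optimal assignment — asserted in tests against
a Hungarian-algorithm oracle — and the count is invariant over cutoffs of
10–14 μm. Ambiguous clusters (a point with several candidate partners) are
flagged on the result rather than resolved silently.

**Association.** Log base 10 with pseudocounts: 1 cell for counts,
10⁻⁴ μm²/100 μm² for densities. Real cohorts contain zeros (a
granule-layer-only animal has essentially no GL label), so stabilization
is unavoidable; both stabilizers are echoed in the output. The infection
covariate defaults to the log count ratio, mirroring the abundance
covariate's form; a fractional-composition form is available via
`infection_form: fraction`. Antisymmetry (swapping GL↔GCL negates the
ratio) and scale invariance (with stabilizers rescaled alongside) are
property-tested. On linear-model cohorts y = βx + ε the estimator matches
the closed-form attenuated correlation ρ = βσx/√(β²σx² + σε²) within
Monte-Carlo error.

## The synthetic generator

What it emulates: concentric annular layer geometry; a nuclei channel with
dense small nuclei in GCL and GL and sparse nuclei in the EPL; punctate
fiber label at controllable per-layer area density; two-channel pairs with
a controllable shared-fiber fraction (second copy rigidly jittered,
default 0.3 μm); marker sets with unambiguous colocalization truth; and
additive noise — a smooth background plane, Gaussian sensor noise, and
strictly single-pixel impulse noise (no two impulses 8-adjacent), sized so
the 3×3 median removes it exactly.

Fibers are rendered without anti-aliasing as chains of constant-shape
"bouton" stamps (squares with corners removed, ~0.7 μm at default width)
along a random-walk path, so true signal area is an exact pixel count.
Two consequences drove this choice over long continuous polylines:

1. *Unbiased detection.* Stamps of 5 px and larger are exactly invariant
   under the 3×3 median, so despeckling does not erode true signal and
   density recovery measures detection fidelity, not rasterization
   artifacts. (At coarser calibrations where a bouton maps to 1–3 px the
   median does erode it — visible as near-zero recovered densities in
   low-resolution smoke runs; widen `fiber_width_um` accordingly.)
2. *Sampling-noise control.* At the default GL density of
   0.014 μm²/100 μm², ten 120 μm ROIs sample only ~1000 signal pixels. If
   that area came in a handful of long fibers, the per-animal estimate
   would be dominated by placement shot noise (tens of percent); as ~50
   independent boutons, placed from a stratified jittered grid within each
   layer, the per-animal relative sampling error is ~10 %, and the
   recovery tolerance of 25 % tests the pipeline rather than the dice.
   Punctate label is also what a presynaptic-marker fusion actually looks
   like. Beaded fibers (`fiber_length_um` > step) and continuous strokes
   (`render="stroke"`) remain available.

Target densities are met by adding whole fibers (never trimming one
mid-fiber), dropping the last fiber again if that lands closer to the
target; the recorded ground truth is always the achieved density,
recounted from the rendered raster per layer. Unreachable targets (beyond
~45 % of a layer, or no free space) raise a generation failure naming the
layer. All randomness flows from one integer seed through
`numpy.random.SeedSequence`, and identical (spec, seed) give bit-identical
rasters — the full synthesize → density → coloc → associate pipeline
re-run under one seed produces byte-identical outputs.

Default study conditions (the generator's defaults): layer radii
250/430/610 μm, 7 px/μm, per-layer densities GL 0.014, EPL 0.0007,
GCL 0.0008 μm²/100 μm², fiber amplitude 600 over a background plane of
~100–165 with Gaussian sd 30 and impulse rate 5×10⁻⁴ at amplitude 4000;
channel pairs use 1.5 μm²/100 μm² patches with shared fraction 0.8 and
0.3 μm jitter. The cohort mixing model draws per-animal infected-cell
counts from the two injection groups' reported distributions (DRN
injections: 303 ± 55 DRN / 11 ± 8 MRN cells; MRN injections: 127 ± 26 MRN
/ 57 ± 39 DRN cells) and makes each layer's density linear in the two
counts with 10 % lognormal noise, anchored so a typical MRN animal carries
~0.013 GL and a typical DRN animal ~0.012 GCL μm²/100 μm².

What the generator does *not* emulate — and hence what passing tests do
not show about real tissue: point-spread blur and axial structure,
bleaching/photophysics, autofluorescence texture, correlated background
(only smooth planes), glomerular substructure within the GL, genuinely
ambiguous marker clusters, and fiber morphology beyond punctate/beaded
walks. Recovery numbers on synthetic cohorts are validation of the
estimator's arithmetic and robustness, not of biological detectability in
any particular tissue.

## Problem sizes

Validation runs use: a 3-animal cohort at full 7 px/μm resolution
(sections of ~8600² px) for density recovery; 20 paired samples of 840² px
(plus 10–20 null cohorts of five 420² samples) for colocalization; 100
seeded 7-animal cohorts for the association; and a reduced-resolution
(2 px/μm) full-pipeline run for the determinism check. These sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
a full validation run to a few minutes on one CPU.

## Known limitations

Layer masks are inputs; no automatic segmentation of the nuclei channel.
The greedy marker matcher is not globally optimal on ambiguous clusters
(it flags them instead). The rolling-ball approximation above 32 px radius
is an approximation, held to ~1 % in tests. ANOVA/Tukey assume
approximately normal per-animal densities — reasonable for means over ten
ROIs, but n per group is small in realistic cohorts. The shift-correlation
p-values assume independent samples, which ROIs from one section only
approximate.
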