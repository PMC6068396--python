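# Methods

This note documents the models, conventions and design choices behind
`vinehsi`, and what its synthetic data does and does not establish.

## Radiometric model

A push-broom VNIR camera records counts `G(row, band)` per scanline. With a
white-reference frame `W` (diffuse panel imaged statically at the start of a
recording) and a dark-current frame `D` (lens covered), reflectance is

```
R = (G - D) / (W - D)
```

per row-pixel and band, broadcast across columns — one static frame pair per
variety-day recording; if the panel is recorded over several static columns,
`reduce_static_frames` averages them first. Absorbance is `A = log10(1/R)`,
the chemometric convention (the logarithm base is a convention choice;
base 10 is used throughout). Reflectance above 1 is allowed — canopy facets
can outshine the panel under illumination drift — and only a non-positive
denominator `W - D` is an error. Non-positive reflectance is floored at
`1e-6` before the log (far below the leaf range of roughly 0.05–0.6, so leaf
spectra are unaffected); floored cells are counted and logged. The first and
last 25 bands are discarded (300 → 250) because the spectral tails of the
sensor are noise-dominated; trimming is a slice, never a resampling.

## Segmentation

Each column of `n` pixels is processed independently. The signature leaf
spectrum and every pixel spectrum receive the same Savitzky–Golay
smoothing + derivative; a pixel is flagged as leaf when the Pearson
correlation of the two derivative spectra strictly exceeds `r_threshold`
(default 0.90). The mean spectrum of a column is the plain average of the
flagged pixels' *untransformed* absorbance — the derivative serves only the
comparison. Columns with no flagged pixel yield no mean; they are excluded
from downstream averaging but counted in the segmentation statistics.

The Savitzky–Golay settings used inside segmentation are not dictated by
the pipeline's provenance, so they are configuration with defaults: window
9, polynomial order 2, first derivative — mid-grid values of the
preprocessing grid with the conventional order. Edges use the truncated-
window polynomial fit (scipy's `interp` mode); the brute-force oracle tests
cover interior points, where the filter is exactly the local least-squares
derivative. A zero-variance spectrum cannot be correlated and is treated as
a non-match (r = −∞) rather than an error, since dark or saturated pixels
are expected in field data.

## Dataset reduction

Retained column means per variety-day are split into 40 consecutive,
exhaustive index ranges whose sizes differ by at most one; when the count
is not divisible by 40 the remainder goes to the earliest sets
(deterministic and order-preserving). Each range is averaged into one
labeled sample, giving 30 × 2 × 40 = 2,400 samples. Plants are implicit in
column order; no explicit plant axis is modeled.

## Preprocessing

Scatter correction is SNV followed by de-trending: per spectrum,
standardize to mean 0 and unit spread (sample, n−1 standard deviation; the
population convention differs only by a global scalar that correlation and
the classifiers ignore), then subtract the least-squares quadratic in band
index — degree 2 following the standard de-trending convention. Smoothing
is a Savitzky–Golay derivative (order 1 or 2; window 5, 9 or 15; polynomial
order 2 for both derivative orders, which window 5 permits). Scatter
correction precedes smoothing. All transforms are strictly per-row, so
applying them before cross-validation splitting leaks nothing across
samples.

## Classifiers and evaluation

SVM uses the native one-vs-one decomposition (n(n−1)/2 binary subproblems;
435 for 30 classes) with the configured kernel and C; the polynomial kernel
degree defaults to 3 (exposed). Probability estimates for AUC are the
standard pairwise-coupled Platt-calibrated probabilities. These are known
to be conservative — on cleanly separated data the per-class AUC can sit
visibly below 1.0 even when classification is perfect, because the internal
calibration cross-fits on small per-class counts; the decision labels, and
hence recall/F1, are unaffected.

MLP is a single hidden layer of coded size (t = attributes + classes,
a = t/2 rounded, i = attributes), trained by backpropagation with the
adam optimizer, iteration cap 500 and a fixed seed (all exposed). Warm
start re-uses the previous fit's weights across the successive folds of a
replicate. Non-convergence at the iteration cap is logged and flagged on
the result, never fatal.

Metrics are macro-averaged over classes: per-class recall tp/(tp+fn),
per-class F1 = 2·precision·recall/(precision+recall), and one-vs-rest AUC
from each class's probability column (rank/trapezoidal tie convention).
Classes absent from a test fold's truth are excluded from the macro mean;
a class with no positives or no negatives is excluded from the AUC mean and
logged. With balanced classes, macro recall coincides with micro recall
(verified numerically in the tests). Cross-validation is stratified 5-fold,
five replicates with independent seeded fold splits. One-vs-one vote ties
resolve to the lowest class index (the underlying implementation's
convention).

## The factorial experiment

The full grid is 12 preprocessing cells × 36 model configurations × 5
replicates = 2,160 rows, executed preprocess-major so each of the 12
transformed tables is built once. Results persist incrementally to CSV,
one row per completed cell; on restart completed cells are skipped and a
failing cell is logged without stopping the grid.

Factor comparisons treat replicate-level grid rows as observations, pooled
one-way per factor (the pooling used is reported with each summary). Tukey's
range test uses the studentized-range distribution on the pooled
within-group variance (scipy's implementation supplies the pairwise
p-values); the compact letter display is derived from the significant-pair
set by insert-and-absorb: start with one letter covering all levels, split
any letter containing a significantly different pair, absorb subsets.
For two groups the test reduces exactly to the pooled two-sample t-test
(q = √2·|t|), which the tests verify as a closed-form oracle.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the acquisition's *structure*: 300 bands over
400–1,000 nm, 900-pixel scanlines, ~1,800 columns and hence 1,620,000
spectra per variety-day image, 60 images, a 53.4 % Bernoulli leaf fraction
per column, a smooth solar-like white frame (~3,500 counts at peak) with
mild row-wise variation, a dark frame near 100 counts, per-column
multiplicative illumination drift (default range 0.95–1.05), and additive
Gaussian sensor noise (default sd 5 counts). Absorbance scenes are
inverted to counts through the reflectance equation, so calibration is
exactly invertible on noise-free scenes (verified to 1e-10; in practice
~1e-15).

Variety signatures are a shared leaf-like base curve — Gaussian absorption
features at the chlorophyll bands (430, 490, 620, 665 nm) and the 970 nm
water band on a 0.25 absorbance baseline — plus per-variety Gaussian bumps
whose amplitude scales with a single `separation` knob (default 0.5;
separation 0 makes varieties identical, giving exact chance-level
baselines). Background materials (soil, wood, sky) are smooth curves
without the leaf features, so their derivative spectra decorrelate from any
leaf signature.

Within-class variation of the *sample table* generator deserves a note.
Each emulated sample is the average of roughly 21,500 pixel spectra, so
i.i.d. sensor noise is almost entirely averaged away (a residual of order
`noise_sd/50`); the variation that survives averaging in real canopies is
spectrally smooth — biological differences between plants and residual
illumination structure. It is therefore modeled as per-sample random
Gaussian bumps with amplitude scale `noise_sd` (default 0.01 absorbance)
plus the small white residual. A global additive shift per measurement day
(default 0.01) emulates phenology, deliberately smaller than the default
class separation since the pooled two-day dataset must remain separable.

What passing tests on this data do **not** show: field performance. The
generator has no radiative-transfer leaf optics, no canopy geometry or
shadows, no spectral smile, and its within-variety variance is a free
parameter rather than a field-calibrated one. The end-to-end checks
establish that the pipeline's machinery is correct and that its behaviour
responds to separability the way the method intends (near-perfect recall
when classes are separable, exact chance when they are not, no spurious
factor detections on null data) — not that any particular field accuracy
would be achieved.

## Problem sizes and numerical choices

The test suite and the acceptance script run the classification checks at
the emulated study scale (30 classes × 80 samples × 250 bands) but with
one CV replicate per configuration and a handful of configurations — the
package's choice of a desk-scale experiment; the full 2,160-row grid is
supported and resumable but is a long-running job. Scenes in tests use tens
of columns and ~100 bands; the scene geometry scales linearly in memory
(an 1,800 × 900 × 300 float64 cube is ~3.9 GB, so full-size rendering
should use column-chunked processing or float32 if attempted).

Determinism: every stochastic step (signatures, scenes, sample tables,
fold splits, MLP initialization) takes an explicit seed; fixed seeds give
bit-identical generator output and identical CV results. Degenerate inputs
are defined errors (zero-variance spectrum in SNV names the sample; a class
smaller than k names the class; inconsistent ENVI headers name the field).
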