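# Methods

## The measurement model

A line-scan NIR imaging system records a cube of raw counts over rows ×
columns × 256 bands spanning 874–1734 nm. Counts are converted to relative
reflectance pixel-wise as `R = (raw − dark)/(white − dark)`, where the white
frame images a ~100%-reflectance tile and the dark frame is recorded with
the shutter closed. The implementation accepts references broadcastable from
1-D (per band) up to full 3-D, because line-scan instruments usually record
per-line references. The denominator must be strictly positive; the
calibration error names the offending bands. Reflectance is clipped to
[0, 1.5] rather than treated as an error: specular pixels routinely exceed
the white-tile level and clipping preserves them for segmentation.

ENVI-style I/O is pinned to one dialect — ASCII header with
`samples/lines/bands/interleave/data type/wavelength` keys, little-endian
binary, BIL/BIP/BSQ interleaves, uint16 or float32 samples. Wavelengths are
written at full float precision so write→read is bit-exact. A private
`cube kind` header key distinguishes raw counts from reflectance; readers of
other ENVI dialects ignore it.

## Extraction

Segmentation thresholds the band nearest 1019 nm — the wavelength of maximum
sample/background contrast for this instrument class — with Otsu's
criterion, which maximizes between-class intensity variance and therefore
matches the "maximum contrast" rationale; nearest-band ties break toward the
lower wavelength. Connected components below 20 px (default, configurable)
are discarded as speckle. The one binary mask is applied to all bands, and
each true pixel contributes one spectrum row, in raster order, with its
(row, col) provenance.

Spectra are cropped to a closed wavelength interval, default 875–1546 nm.
The instrument's leading and trailing bands are unstable, and published
descriptions of this workflow give three mutually inconsistent ranges
(874–1734, 974–1634, 875–1546); the explicit mid-wavelength statement
875–1546 nm is adopted as the default and the window is a parameter
everywhere, never hard-coded.

Denoising is wavelet shrinkage: Daubechies-6, decomposition level 3
("a primary function of 6" is read as the db6 family; the family is
configurable), soft thresholding of all detail levels at the universal
threshold σ√(2 ln n) with σ estimated from the median absolute deviation of
the finest-scale details (MAD/0.6745). Smoothing is defined per spectrum
and applied pixel-wise before averaging, with a table-level wrapper.

Whether downstream models should consume pixel-wise spectra or one mean
spectrum per sample is genuinely ambiguous in this workflow's lineage; the
package defaults to per-sample means (giving the 360-row census) and leaves
pixel-wise tables available through the same API.

## PCA

Centered, unscaled PCA (reflectance bands share units, so unit-variance
scaling would only amplify noise bands). Explained percentages are
eigenvalue shares of total variance; scores are the centered data projected
on the loadings. Sign is fixed by making the largest-magnitude loading
element of each component positive, so repeated fits are bit-identical. The
published exploratory values for the real panel (78.77% + 17.35% = 96.12%
in two components) are properties of that panel, not of synthetic data; the
package reproduces the arithmetic, not the panel.

## Discriminant models

All models share a stratified 4:1 train/test split (exact per class when
sizes divide by 5) and per-band standardization `(x − mean)/sd` with
statistics from training rows only; constant bands get sd 1 and are flagged.

**PLS-DA.** One-hot class indicators regressed by PLS (no scaling inside
PLS; standardization happens outside), class = argmax of the predicted
indicator vector — equivalent to minimizing the absolute difference to a
class indicator. The component count is selected by leave-one-out accuracy
over a 1..max grid, smallest count on ties. A 15-component default cap keeps
the LOO loop proportionate; callers can raise it.

**RBF-SVM.** Exhaustive grid search over penalty c and kernel width g,
scored by stratified 5-fold inner cross-validation on the training rows
(folds shrink to the smallest class when classes are tiny, degenerating to
resubstitution below 2). Ties resolve deterministically to the smallest c,
then the smallest g. The grid and scores are retained for reporting. Default
grids are log-spaced, c ∈ 10^[−1..3], g ∈ 10^[−4..0].

**1D CNN.** A VGG-style network over the standardized spectrum: five blocks
of [conv(kernel 3, stride 1, pad 1) → batch norm → ELU(α=1)] × 2 →
max-pool(2), with 16/32/64/128/128 filters (monotone doubling capped at
128), then flatten → dense(256) → ELU → dropout(0.5) → dense(K).
Conv→conv→pool ordering follows the VGG convention. Pooling is max (the
VGG convention) of size 2 with floor truncation of odd lengths, so a
199-band spectrum passes 99→49→24→12→6. Training is mini-batch Adam
(β₁=0.9, β₂=0.999) on softmax cross-entropy with per-epoch learning rate
η₀/(1 + k·t), defaults η₀ = 0.0005, k = 0.045, batch size 256, 800 epochs;
the parameters of the best-training-loss epoch are restored at the end.
Weights are He-normal; the classification head starts at zero so the
untrained network predicts the uniform distribution and the starting loss
is ln K — a calibration-style head initialization that removes any
dependence of the initial loss on spectrum scale.

The engine is pure NumPy: im2col convolutions via stride tricks and BLAS
matmuls, hand-derived backward passes for every layer (verified against
central finite differences in the test suite), inverted dropout, batch-norm
running statistics with momentum 0.1 for evaluation mode. All stochasticity
(init, shuffling, dropout) flows from explicit `numpy.random.Generator`
streams derived from the `CnnSpec` seed; two runs with one seed are
bit-identical. Softmax subtracts the row max before exponentiation; the
cross-entropy log is clamped at 1e−12; a non-finite loss or logit raises a
divergence error naming the epoch.

## Evaluation

Confusion rows are true classes, columns predictions. Per class, precision
TP/(TP+FP) and recall TP/(TP+FN) — the recall denominator is FN by
definition, whatever typographic variants circulate — and F is their
harmonic mean, 0 (flagged) when both vanish. Reported aggregates are macro
averages (unweighted class means), which is the only averaging consistent
with distinct precision/recall values on balanced data; accuracy
(= micro-averaged precision = micro recall) is emitted alongside so either
reading of "accuracy" can be checked. A never-predicted class gets
precision 0 and is flagged in the report.

## The synthetic generator

The generator emulates what the analysis assumes about dried-bulb NIR
reflectance, not any particular real panel:

* a gentle increasing-then-flat baseline in ≈[0.25, 0.6] reflectance
  (logistic ramp centered at 1050 nm);
* shared Gaussian features: peaks at 1100 nm (+0.12, width 60) and 1300 nm
  (+0.10, 70), valleys at 1200 nm (−0.08, 40; C–H second-overtone region)
  and 1460 nm (−0.15, 50; O–H first overtone/water);
* per-class perturbations: one Gaussian bump per class, centers spread over
  980–1500 nm, alternating sign. The default amplitude 0.035 keeps classes
  heavily overlapping; the `well_separated_config` preset raises it to 0.2
  for runs that must reach high accuracy deterministically;
* i.i.d. Gaussian pixel noise, default sd 0.01 reflectance (a realistic
  shot/readout level for line-scan NIR at this exposure), with extra edge
  noise (sd 0.028, added in quadrature, i.e. ≈3× total) outside the
  975–1646 nm clean window, motivating the wavelength crop;
* cubes: a disc of radius 10 px centered in a 64×64 frame carries the class
  spectrum, re-encoded to counts through the inverse calibration relation
  (white level 3500 counts with a mild lamp droop, dark 120); background
  reflectance 0.03. The ground-truth mask is returned for oracle tests.

Intra-class variance and SNR of real panels are unknown, so these noise
levels are free parameters chosen once, not estimates. The generator omits
scattering baselines, moisture gradients within a bulb, spatial texture,
specular highlights and instrument drift; a model that passes here has been
shown to recover the assumed structure under the assumed noise — nothing
more. Real-data accuracy claims cannot be transferred from these fixtures.

## Problem sizes and numerical choices

The test and acceptance runs use the study census (12 × 30 spectra, 199
bands after cropping) for splits and models, with the CNN capped at 40
epochs on the well-separated preset — it converges there within ~20 epochs,
and the cap keeps the three-seed median run desk-scale. Unit fixtures are
smaller (64-band spectra, 6-class pipelines). Gradient checks run on a tiny
2-channel network at tolerance 1e−5 against central differences with step
1e−6. PCA oracle comparisons use 1e−8; calibration round-trips 1e−10.

## Known limitations

* No instance splitting of multi-sample scenes; one mask = one ROI table.
* No BIP streaming, bad-band lists or geo-keys in the ENVI reader.
* PLS-DA leave-one-out is O(n · components) full refits; fine at n ≈ 300,
  slow beyond a few thousand rows.
* The NumPy CNN targets spectra-length inputs on CPU; it is not a general
  deep-learning engine (no GPU, no autograd beyond the fixed layer set).
* The scalar-regression reading of the PLS-DA decision ("absolute
  difference to the class number") is not implemented as a separate mode;
  the one-hot argmax rule is its order-consistent generalization.
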