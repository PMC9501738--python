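# herbspec

NIR hyperspectral-imaging chemometrics for discriminating varieties of
*Fritillaria thunbergii* (Zhebeimu), a medicinal bulb whose market varieties
are visually near-identical but chemically distinct. The package implements
the full discrimination workflow used in this problem domain: reflectance
calibration of hyperspectral cubes, region-of-interest spectral extraction,
wavelet denoising, PCA exploration, and three discriminant models — PLS-DA,
RBF-SVM and a one-dimensional VGG-style convolutional network — compared by
macro precision, recall and F-score.

Because real variety panels of this kind are rarely redistributable, the
package ships a first-class synthetic generator that emulates the assumed
data structure: 12 classes × 30 samples on an 874–1734 nm axis (256 bands)
with shared reflectance peaks near 1100/1300 nm, valleys near 1200/1460 nm,
small class-specific perturbations, pixel-level sensor noise, and noisy
leading/trailing bands.

## The methods at the core

**Calibration.** Raw counts become relative reflectance against white and
dark reference frames:

    R = (I_raw − I_dark) / (I_white − I_dark)

**Extraction.** Otsu thresholding of the maximum-contrast band (1019 nm)
yields a binary mask; masked pixel spectra are cropped to the stable
875–1546 nm window and smoothed with a level-3 Daubechies-6 wavelet
transform (soft universal thresholding).

**Discrimination.** With a stratified 4:1 train/test split and per-band
standardization from training statistics:

* PLS-DA — PLS regression onto one-hot responses, argmax decision,
  leave-one-out selection of the latent-component count;
* RBF-SVM — exhaustive (c, g) grid search with stratified inner CV;
* 1D CNN — five blocks of [conv(k=3,s=1,p=1) → batch norm → ELU] × 2 →
  max-pool(2) with 16/32/64/128/128 filters, a 256-wide dense + dropout(0.5)
  head, trained by Adam on softmax cross-entropy with learning rate
  η(t) = η₀/(1 + kt), η₀ = 5·10⁻⁴, k = 0.045. The network is implemented in
  NumPy (im2col convolutions, hand-derived backward passes, He
  initialization) and is fully deterministic given a seed.

**Evaluation.** K×K confusion matrices; per class, precision
TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R); macro averages and accuracy.

## Worked example

```python
import herbspec as hs
from herbspec.evaluation import format_report

cfg = hs.well_separated_config(seed=1)          # 12 x 30 preset, strong class signal
table = hs.crop_wavelengths(hs.simulate_spectra_table(cfg), 875, 1546)
split = hs.stratified_split(table.labels, (4, 1), seed=1)
Xtr, ytr = table.X[split.train_rows], table.labels[split.train_rows]
plsda = hs.train_plsda(Xtr, ytr, n_components=10)
svm = hs.train_svm_rbf(Xtr, ytr, seed=1)
print(format_report(hs.report([plsda, svm], split, table)))
pca = hs.fit_pca(table, 10)
print("PC1+PC2 variance: %.2f%%" % hs.cumulative_variance(pca, 2))
```

prints

```
Model     Set        Precision    Recall   F-Score  Accuracy
plsda     training      1.0000    1.0000    1.0000    1.0000
plsda     testing       1.0000    1.0000    1.0000    1.0000
svm_rbf   training      1.0000    1.0000    1.0000    1.0000
svm_rbf   testing       1.0000    1.0000    1.0000    1.0000
PC1+PC2 variance: 48.28%
```

On this well-separated preset both linear and kernel models discriminate all
12 classes perfectly in the held-out fifth of the data (72 spectra); the
first two principal components carry about half of the total spectral
variance, the rest living in the per-band noise. The default
`SyntheticConfig` preset instead keeps classes heavily overlapping, which is
the regime where model comparisons become interesting.

The same flow runs from the shell:

```bash
herbspec run --config pipeline.json     # simulate/ingest -> ... -> report
herbspec simulate --out data --table    # individual stages also exposed
```

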