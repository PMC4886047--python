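# Methods

This note documents the models and procedures implemented in
`msiclassify`, the assumptions behind them, the tunable parameters and
their defaults, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model

An MSI dataset is a collection of pixel spectra — strictly increasing
m/z axes (Th) with non-negative intensities and 1-based raster
coordinates — plus a per-patient metadata table (SIAPEC cytological
category THY1–THY5; histological truth Ben/PTC where available).
Patient identity is carried one-imzML-file-per-patient with a sidecar
CSV, matching per-smear acquisition. I/O is delegated to pyimzml;
continuous mode is written when all spectra share one axis, processed
mode otherwise, with 64-bit float arrays and no resampling at I/O time.

## Spectral preprocessing

Order: Savitzky–Golay smoothing → TopHat baseline subtraction → TIC
normalisation. Smoothing before baseline estimation keeps noise minima
from dragging the morphological opening down; this matches common
MALDI practice. All operators act in index space — MALDI-TOF axes are
near-uniformly sampled and morphological/polynomial filters are defined
on the sample grid.

* `savgol_half_window = 10` points, `savgol_polyorder = 3`: a 21-point
  cubic filter preserves peaks a few points wide or wider while
  suppressing white noise ≈ 4–5×. Edges are handled by evaluating the
  edge-window polynomial, not by padding. Negative outputs are
  permitted at this stage.
* `tophat_half_window = 75` points: the flat structuring element
  (width 151) must exceed the widest genuine peak — at the default
  synthetic sampling the widest planted peak spans ≈ 80 points — or
  peaks are absorbed into the baseline. The opening is anti-extensive
  (baseline ≤ signal) and idempotent; the residual is clipped at 0.
* `tic_target = 1.0`: intensities become fractions of total ion
  current, making spectra comparable across pixels and patients. A
  spectrum whose residual after baseline subtraction is at rounding
  level (≤ 1e-9 of the smoothed scale, e.g. a constant or all-zero
  spectrum) is *degenerate*: preprocessing raises, and pixel
  classification downgrades such pixels to "unclassified" rather than
  aborting.

## Peak extraction

Noise is one global scalar per spectrum: the median absolute deviation
of the intensities, scaled by 1.4826 for Gaussian consistency (the R
`mad()` convention of the original toolchain). Peaks are *strict*
local maxima within ±`halfwindow_local_max` (default 20) points whose
intensity is at least `snr_threshold` (default 3, inclusive) times the
noise. Plateaus are never peaks; an empty peak list is legal. S/N
picking is known to admit false positives; the presence filter below is
the corrective.

Alignment pools all peaks, sorts by m/z, and partitions greedily: a new
reference group opens when the gap to the previous peak exceeds
`tolerance_ppm · 1e-6 · m/z` (default 2000 ppm). Groups holding two
peaks from one source are split at their largest internal gap until
conflict-free. Each group's reference is the intensity-weighted mean
of its members (plain mean if all intensities are zero); ties in
feature scores and matching are broken deterministically (see below).
Alignment and the ≥ 25 % presence filter run over *all pixel spectra of
the dataset* — with ~10³ pixels the binomial concentrates and chance
co-occurrences of noise maxima are mostly eliminated, while at
profile level (tens of spectra) they are not. The filter boundary is
inclusive.

## Peak-list matrix and average profiles

The pixel-level matrix has one row per pixel and one column per
surviving reference; a cell is the detected peak intensity, or — since
absence of a *detected* peak does not mean absence of signal — the
pixel spectrum's maximum intensity inside the tolerance window around
the reference ("backfill", presence flag false). A patient's average
profile is the **mean of their pixel rows**. Averaging after peak
extraction keeps patient features on the same intensity scale as
single-pixel features, which is what allows one classifier to serve
both the average-profile and the pixel-by-pixel routes: the
alternative (peak-picking a mean spectrum) assigns noise-level
references values ~√n_pixels smaller than any single pixel shows, and
a classifier trained on such features misreads whole smears whenever
feature selection keeps one of them. The mean-spectrum construction
(`peaks.average_patient_profile`) remains available.

## Feature selection

RFE wrapped around a univariate-response PLS (NIPALS; class code
Ben = +1, PTC = −1, decision threshold 0, ≤ 3 latent components —
small and fixed to avoid fold-wise instability at n ≈ 20–30).
Intensities are autoscaled (training-fold mean/SD) before every PLS
fit: NIPALS weights are covariances, and without scaling the
|coefficient| ranking would reward low-variance columns rather than
class information. Within each training fold of a repeated
(2×) stratified 10-fold split, features are dropped block-wise (lowest
|coefficient| first; ties broken by m/z) down to each candidate size
{2, 5, 10, 15, 20, 25, 30, 40, 60, 80, 100, all}∩[1, p], recording each
size's held-out accuracy. The size with the best mean accuracy wins,
ties going to the smaller (more parsimonious, faster, less
overfitting-prone) subset; the final subset comes from re-running the
elimination on the full training set at that size. Everything is
driven by one seeded generator and is bitwise-reproducible.

## Classification

A soft-margin RBF SVM (scikit-learn's SVC supplies the QP core; tuning,
cross-validation, metrics, serialisation and provenance are this
package's). Features are standardised with the training mean and
*population* SD — the e1071 `svm(scale=TRUE)` convention of the
original toolchain, and population rather than sample SD so that exact
duplication of the training set leaves the fit unchanged. Decision
values are oriented benign-positive. The (cost, γ) grid
{0.1, 1, 10, 100} × {0.01, 0.11, 1.11, 1/p} is scored by repeated
stratified CV on shared seeded folds; ties prefer smaller cost, then
smaller γ. `epsilon` is recorded for fidelity with the original
tuning tables but is inert — it parametrises regression SVMs only.

Metrics use **Ben as the positive class**: sensitivity is the ability
to detect benignity, the clinically relevant question for THY3 cases.
Undefined ratios (zero denominators) are NaN, never 0. AUC is the
rank-based (Mann–Whitney, midrank ties) area when decision values are
available; from hard labels it equals (sensitivity + specificity)/2
exactly. Cross-validated metrics are pooled over all held-out
predictions (the alternative, fold-averaging, is not implemented).
With k = n the CV degenerates to leave-one-out, where stratification is
vacuous.

## Pixel-by-pixel classification

Unknown MSI data is conditioned exactly like training data; peaks are
picked per pixel, the presence filter is applied across the unknown
file's own pixels (false-positive control *for this route only* — the
average-profile route skips it), and each pixel's surviving peaks are
matched to the model's selected references: nearest within tolerance,
ties toward higher intensity, unmatched references backfilled from the
pixel's spectrum. Degenerate-TIC pixels are labelled unclassified;
every other pixel is classified — dropping pixels would bias the area
fractions that make the maps useful. Maps are rendered green
(benign) / red (malignant) / grey (unclassified) with a JSON sidecar
carrying the legend and fractions.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:
a shared panel of Gaussian peaks (default 30) plus a small set of truly
discriminative species (default 2, one up- and one down-regulated in
PTC so total ion current stays roughly class-balanced); patient-level
log-normal amplitude variation (σ_log = 0.25) and pixel-level variation
(σ_log = 0.15); an exponentially decaying baseline (amplitude 2, decay
3000 Th); additive Gaussian noise (sd 0.05); per-spectrum log-normal
TIC variation (σ = 0.3); per-spectrum multiplicative calibration jitter
(±300 ppm, well inside the 2000 ppm alignment tolerance); peak widths
of 800 ppm (σ), growing with m/z as in linear-TOF data. The axis is
uniform at 1 Th over m/z 3000–25000 (≈ 20 points across a peak at
10 kTh); peaks are planted above 6 kTh, where protein signal
realistically lives — the low-mass region of protein-mode MALDI is
matrix-cluster background — and with ≥ 8000 ppm mutual separation so
that alignment quality is measurable against truth. `effect_size` is
the standardised mean *intensity* difference of a discriminative peak
between classes at patient level; because amplitudes are log-normal the
generator solves for the log-mean gap realising it and raises if the
request exceeds the feasibility bound √(2/(e^σ² − 1)). Cohort layout
defaults mirror the study: 14 benign + 18 carcinoma training patients
and 11 THY3-like validation patients (8 truly benign), 50 pixels each.
A mixed-smear generator plants a rectangular malignant sub-region of
controllable area fraction inside an otherwise benign raster.

Not emulated: matrix crystallisation artefacts, detector saturation,
isotope envelopes, peak-shape asymmetry, spatial autocorrelation of
intensities beyond the planted region structure, and mass-dependent
resolution changes other than the constant-ppm width. Tests passing on
these cohorts therefore demonstrate the *pipeline's* correctness and
statistical behaviour under its own assumptions, not performance on
real thyroid smears.

## Statistical behaviour worth knowing

* Under permuted labels, stratified without-replacement CV of a
  majority-voting-degenerate classifier scores *below* chance on a
  balanced cohort (the held-out fold under-represents the training
  majority); on an unbalanced cohort it sits exactly at the
  majority-class rate. The permutation sanity checks use an unbalanced
  reduced cohort for this reason.
* The PLS scorer inside RFE is not a majority voter; its permuted-label
  accuracy lies between the minority and majority rates. The
  load-bearing property — no optimism beyond binomial noise — is what
  the test suite asserts for it.
* S/N-3 picking admits occasional noise references past the 25 % filter
  (windows of 2000 ppm are wide); with ~20 training patients RFE can
  keep one by chance, which degrades external validation and pixel
  maps for some random cohorts. This mirrors the false-positive
  behaviour the method's own description acknowledges and is left as
  honest stochastic variation.

## Known limitations

Binary classes only (no THY subcategory modelling); no probability
calibration; no spatial smoothing of class maps or co-registration with
optical scans; vendor raw formats are out of scope (imzML only); the
SVM decision for a pixel with an empty feature window is defined but
weakly informed — such pixels are classified, not dropped, by design.
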