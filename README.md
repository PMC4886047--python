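# msiclassify

Classification of thyroid bioptic specimens from MALDI mass-spectrometry-imaging
(MALDI-MSI) data.

Fine-needle aspiration biopsies of thyroid nodules are graded cytologically
(SIAPEC categories THY1–THY5). The troublesome category is THY3 — lesions of
undetermined malignancy potential — which are usually resected as if malignant
even though most turn out benign on histology. MALDI-MSI acquires one mass
spectrum (m/z 3000–25000, linear-TOF protein range) per 100 µm pixel of a
cytological smear, and the proteomic profile it captures carries enough signal
to separate benign lesions (Ben) from papillary thyroid carcinoma (PTC). This
package implements, end to end, a pipeline that learns that separation from
histology-confirmed cases (THY2 vs THY4/THY5) and applies it to THY3 smears —
both as one verdict per patient and as a pixel-by-pixel molecular class map.
It is written for mass-spectrometry bioinformaticians and computational
pathology researchers.

## The method

1. **Per-spectrum conditioning** — Savitzky–Golay smoothing, TopHat (grey-scale
   morphological opening) baseline subtraction, and total-ion-current (TIC)
   normalisation, so every spectrum has the same integrated area.
2. **Feature extraction** — peaks are strict local maxima with
   S/N ≥ 3, where noise is the median absolute deviation
   (MAD, scaled 1.4826); peaks are aligned across the whole dataset within a
   2000 ppm tolerance and references present in < 25 % of all spectra are
   discarded as false positives of the S/N picker.
3. **Peak-list matrix** — pixels × aligned references; a patient's *average
   profile* is the mean of their pixel rows.
4. **Feature selection** — recursive feature elimination (RFE) wrapped around a
   PLS-DA scorer (NIPALS, Ben = +1 / PTC = −1): inside each training fold of a
   2× 10-fold stratified CV, the lowest-|coefficient| features are dropped
   block-wise to each candidate subset size; the size with the best mean
   held-out accuracy wins (ties → smaller).
5. **Classifier** — a soft-margin RBF-kernel SVM, with cost *C* and kernel
   width γ tuned by repeated cross-validation over a fixed grid, trained on the
   selected features (standardised).
6. **Reporting** — accuracy, sensitivity, specificity, PPV, NPV and ROC AUC,
   with **Ben as the positive class** (the clinically relevant question is
   detecting benignity in THY3 cases); plus per-pixel classification rendered
   as a green (benign) / red (malignant) PNG map.

Because no MSI cohort is bundled, a first-class synthetic-cohort generator
(`msiclassify.synthetic`) produces imzML-compatible datasets with known ground
truth: shared and class-discriminative Gaussian peaks of controllable
standardised effect size, ppm-proportional widths, exponential baseline,
additive noise, multiplicative TIC variation, per-spectrum calibration jitter,
and spatially mixed smears.

## Worked example

The published external validation of the original study — 11 THY3 patients,
two of them (patients #20 and #41) predicted malignant but histologically
benign — ships as a fixture:

```python
from msiclassify import compute_metrics, generate_worked_example

table = generate_worked_example()
print(compute_metrics(table["predicted"], table["true"],
                      positive_class="Ben").summary())
```

```
positive class: Ben
confusion  TP=6 FN=2 FP=0 TN=3
    accuracy: 0.818
 sensitivity: 0.750
 specificity: 1.000
         ppv: 1.000
         npv: 0.600
         auc: 0.875
```

Reading: 9 of 11 THY3 patients were classified correctly; every benign call
was right (PPV 1.000), no carcinoma was called benign (specificity 1.000), and
two benign patients were over-called malignant (sensitivity 0.750). The
hard-label ROC AUC is (0.750 + 1.000)/2 = 0.875.

A full run on synthetic data, statsmodels-style:

```python
from msiclassify import (CohortSpec, MSIClassificationModel, PipelineConfig,
                         generate_cohort)

spec = CohortSpec(n_benign=6, n_malignant=6, n_validation=6,
                  n_validation_benign=4, pixels_per_patient=10,
                  mz_step=2.0, seed=21)
dataset, truth = generate_cohort(spec)
train = dataset.subset(truth["patients"].query("role=='train'")["patient_id"])
val = dataset.subset(truth["patients"].query("role=='validation'")["patient_id"])

results = MSIClassificationModel.from_dataset(train, PipelineConfig(folds=6)).fit(seed=2)
print(results.summary())
```

```
MSI average-profile classification
==============================================
training patients      12  {'Ben': 6, 'PTC': 6}
aligned peaks          70
selected features      2  (candidates [2, 5, 10, 15, 20, 25, 30, 40, 60, 70])
RFE CV accuracy        0.833  at size 2
SVM (radial)           cost=0.1  gamma=0.01
seed                   2
----------------------------------------------
repeated-CV performance (pooled held-out):
positive class: Ben
confusion  TP=12 FN=0 FP=0 TN=12
    accuracy: 1.000
 ...
----------------------------------------------
selected m/z: 13984.3, 17705.9
```

The two selected m/z values are exactly the two discriminative species this
cohort planted (see `truth["peaks"]`). Validating on the six held-out THY3-like
patients (`results.validate(val, truth=...)`) classifies all six correctly, and
`results.classify_pixels(...)` + `msiclassify.pixelmap.render_map` turn any
smear into a per-pixel class map with its benign/malignant area fractions.

The same workflow is scriptable from a shell:

```sh
msiclassify simulate --seed 1 --out sim/
msiclassify train --metadata sim/metadata.csv --out run/ --seed 1 sim/train_*.imzML
msiclassify classify-pixels --model run/model.json --out map.png sim/val_01.imzML
```

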