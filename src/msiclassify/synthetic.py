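"""Synthetic MALDI-MSI cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in a linear-TOF protein-range acquisition (m/z 3000–25000):

* a panel of Gaussian peaks shared by everyone, plus a small number of
  truly class-discriminative peaks whose patient-level log-amplitudes
  differ between the benign and carcinoma classes by a controllable
  standardised effect size (one marker up-, one down-regulated per pair,
  so total ion current stays roughly class-balanced);
* peak widths proportional to m/z (constant ppm), as in TOF data;
* a smooth exponentially decaying chemical baseline;
* additive Gaussian detector noise;
* per-spectrum multiplicative TIC variation (log-normal);
* per-spectrum multiplicative m/z miscalibration (uniform in ppm);
* optionally spatially mixed smears: a rectangular sub-region of a
  malignant patient's raster carries the malignant pattern while the
  remaining pixels look benign.

Every planted quantity is returned as ground truth so that peak
recovery, feature selection and pixel maps can be scored exactly.  The
module also packages the in-print worked example (the 11 validation
patients' predicted/true classes) and the full 43-patient study roster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import MSIDataset, Spectrum

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_patient",
    "generate_mixed_smear",
    "generate_worked_example",
    "study_cohort_table",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-class MSI cohort.

    Defaults mirror the study layout: 14 benign + 18 carcinoma training
    patients (cytology THY2 vs THY4/THY5) and 11 cytologically
    undetermined (THY3) validation patients, 8 of which are truly
    benign.  ``effect_size`` is the standardised mean *intensity*
    difference of each discriminative peak between the classes at the
    patient level (difference of class means over the pooled SD, both
    in linear intensity space); the generator solves for the log-scale
    class separation that realises it given ``amplitude_sigma_log``.
    Because amplitudes are log-normal, the achievable linear-space
    effect is bounded by ``sqrt(2 / (exp(sigma^2) - 1))``; an
    infeasible request raises at generation time.
    """

    n_benign: int = 14
    n_malignant: int = 18
    n_validation: int = 11
    n_validation_benign: int = 8
    pixels_per_patient: int = 50
    mz_range: tuple[float, float] = (3000.0, 25000.0)
    mz_step: float = 1.0
    n_shared_peaks: int = 30
    n_discriminative_peaks: int = 2
    effect_size: float = 3.0
    peak_width_ppm: float = 800.0
    min_peak_mz: float = 6000.0
    baseline_amplitude: float = 2.0
    baseline_decay: float = 3000.0
    noise_sd: float = 0.05
    tic_lognormal_sd: float = 0.3
    mz_jitter_ppm: float = 300.0
    malignant_pixel_fraction: float = 1.0
    amplitude_sigma_log: float = 0.25
    pixel_sigma_log: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not (0 < lo < hi):
            raise ValueError("mz_range must be increasing and positive")
        if not 0 <= self.malignant_pixel_fraction <= 1:
            raise ValueError("malignant_pixel_fraction must be in [0, 1]")
        for name in (
            "mz_step", "peak_width_ppm", "baseline_decay",
            "amplitude_sigma_log", "pixel_sigma_log",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "noise_sd", "tic_lognormal_sd", "mz_jitter_ppm",
            "baseline_amplitude", "effect_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_validation_benign > self.n_validation:
            raise ValueError("n_validation_benign exceeds n_validation")
        if self.pixels_per_patient < 1 or self.n_shared_peaks < 0:
            raise ValueError("counts must be positive")


def _draw_centres(rng, n, lo, hi, min_sep_ppm):
    """Peak centres with pairwise separation > min_sep_ppm (rejection)."""
    centres: list[float] = []
    for _ in range(100000):
        if len(centres) == n:
            break
        c = float(rng.uniform(lo, hi))
        if all(abs(c - o) > min_sep_ppm * 1e-6 * max(c, o) for o in centres):
            centres.append(c)
    if len(centres) < n:
        raise ValueError("could not place peaks with the requested separation")
    return np.sort(np.asarray(centres))


def _log_separation(effect_size: float, sigma_log: float) -> float:
    """Log-mean gap giving a linear-space standardised difference.

    For log-normal amplitudes ``exp(mu_i + sigma*Z)`` the class means are
    ``exp(mu_i) * exp(sigma^2/2)`` and each SD is ``mean * c`` with
    ``c = sqrt(exp(sigma^2) - 1)``.  Setting the standardised difference
    ``(m2 - m1) / (c * sqrt((m1^2 + m2^2)/2))`` equal to ``effect_size``
    gives a quadratic in the mean ratio ``r = exp(delta)``.
    """
    if effect_size == 0:
        return 0.0
    c2 = math.expm1(sigma_log**2)
    k = effect_size**2 * c2 / 2.0
    if k >= 1.0:
        raise ValueError(
            f"effect_size {effect_size} is not achievable with "
            f"amplitude_sigma_log {sigma_log} (max "
            f"{math.sqrt(2.0 / c2):.2f})"
        )
    r = (1.0 + math.sqrt(1.0 - (1.0 - k) ** 2)) / (1.0 - k)
    return math.log(r)


def _grid_coords(n):
    w = math.ceil(math.sqrt(n))
    return [(i % w + 1, i // w + 1) for i in range(n)]


class _CohortModel:
    """Frozen cohort-level draw: peak positions and class log-means."""

    def __init__(self, spec: CohortSpec, rng: np.random.Generator):
        lo, hi = spec.mz_range
        pad = 0.02 * (hi - lo)
        # peaks live above min_peak_mz: the low-mass region of protein-mode
        # MALDI is matrix-cluster background, and it keeps every planted
        # peak several axis points wide at the default sampling step
        lo_peaks = max(lo + pad, spec.min_peak_mz)
        n_total = spec.n_shared_peaks + spec.n_discriminative_peaks
        centres = _draw_centres(
            rng, n_total, lo_peaks, hi - pad, min_sep_ppm=8000.0
        )
        idx = rng.choice(n_total, size=spec.n_discriminative_peaks, replace=False)
        self.is_discriminative = np.zeros(n_total, dtype=bool)
        self.is_discriminative[np.sort(idx)] = True
        self.centres = centres
        # cohort-level base log-amplitudes
        self.base_log = rng.normal(math.log(5.0), 0.5, size=n_total)
        self.base_log[self.is_discriminative] = math.log(4.0)
        # class offsets: alternate up/down regulation in the carcinoma class
        delta = _log_separation(spec.effect_size, spec.amplitude_sigma_log)
        signs = np.array(
            [1.0 if i % 2 == 0 else -1.0
             for i in range(spec.n_discriminative_peaks)]
        )
        self.class_shift = np.zeros(n_total)
        self.class_shift[self.is_discriminative] = signs * delta / 2.0

    def class_log_mean(self, label: str) -> np.ndarray:
        sign = -1.0 if label == "Ben" else 1.0
        return self.base_log + sign * self.class_shift


def _render_spectrum(axis, centres, amps, width_ppm, spec, rng):
    """Sum of Gaussian peaks + baseline + noise, per-spectrum jittered."""
    shift = 1.0 + rng.uniform(-spec.mz_jitter_ppm, spec.mz_jitter_ppm) * 1e-6
    intensity = np.zeros_like(axis)
    step = spec.mz_step
    for c, a in zip(centres * shift, amps):
        sigma = width_ppm * 1e-6 * c
        lo = np.searchsorted(axis, c - 5 * sigma)
        hi = np.searchsorted(axis, c + 5 * sigma)
        if hi > lo:
            window = axis[lo:hi]
            intensity[lo:hi] += a * np.exp(-0.5 * ((window - c) / sigma) ** 2)
    intensity += spec.baseline_amplitude * np.exp(
        -(axis - spec.mz_range[0]) / spec.baseline_decay
    )
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=axis.size)
    tic_factor = float(np.exp(rng.normal(0.0, spec.tic_lognormal_sd)))
    return np.clip(intensity * tic_factor, 0.0, None)


def generate_patient(
    spec: CohortSpec,
    model: _CohortModel,
    patient_id: str,
    label: str,
    rng: np.random.Generator,
    malignant_pixel_fraction: float | None = None,
):
    """Spectra for one patient plus the per-pixel latent class list.

    A malignant patient's smear carries the malignant pattern in the
    first ``malignant_pixel_fraction`` of a raster-filling block of
    pixels and the benign pattern elsewhere (mixed cellularity).
    """
    frac = (
        spec.malignant_pixel_fraction
        if malignant_pixel_fraction is None
        else malignant_pixel_fraction
    )
    axis = np.arange(spec.mz_range[0], spec.mz_range[1] + spec.mz_step / 2, spec.mz_step)
    patient_amp = {
        lab: model.class_log_mean(lab)
        + rng.normal(0.0, spec.amplitude_sigma_log, size=model.centres.size)
        for lab in ("Ben", "PTC")
    }
    coords = _grid_coords(spec.pixels_per_patient)
    n_mal = round(frac * spec.pixels_per_patient) if label == "PTC" else 0
    spectra, latent = [], []
    for i, (x, y) in enumerate(coords):
        pix_label = "PTC" if (label == "PTC" and i < n_mal) else "Ben"
        log_amp = patient_amp[pix_label] + rng.normal(
            0.0, spec.pixel_sigma_log, size=model.centres.size
        )
        inten = _render_spectrum(
            axis, model.centres, np.exp(log_amp), spec.peak_width_ppm, spec, rng
        )
        spectra.append(Spectrum(axis, inten, x, y, patient_id))
        latent.append({"patient_id": patient_id, "x": x, "y": y, "class": pix_label})
    return spectra, latent


def generate_cohort(spec: CohortSpec | None = None):
    """Generate training + validation cohorts with full ground truth.

    Returns
    -------
    dataset : MSIDataset
        All patients' pixel spectra with THY-category metadata; training
        patients carry their histological class, validation (THY3)
        patients' metadata leaves histology unset (truth is in the
        ground-truth record).
    truth : dict
        ``peaks`` (every planted centre with its class log-means and a
        discriminative flag), ``patients`` (per-patient true class and
        role), ``pixels`` (per-pixel latent class), ``spec``.

    Byte-identical output for a fixed ``spec.seed``.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    model = _CohortModel(spec, rng)

    roster: list[tuple[str, str, str, str]] = []  # id, cytology, histology, role
    for i in range(spec.n_benign):
        roster.append((f"train_ben_{i+1:02d}", "THY2", "Ben", "train"))
    for i in range(spec.n_malignant):
        cyto = "THY4" if i % 2 == 0 else "THY5"
        roster.append((f"train_ptc_{i+1:02d}", cyto, "PTC", "train"))
    for i in range(spec.n_validation):
        histo = "Ben" if i < spec.n_validation_benign else "PTC"
        roster.append((f"val_{i+1:02d}", "THY3", histo, "validation"))

    spectra, pixels, patients = [], [], []
    md_rows = []
    for pid, cyto, histo, role in roster:
        s, latent = generate_patient(spec, model, pid, histo, rng)
        spectra.extend(s)
        pixels.extend(latent)
        patients.append(
            {"patient_id": pid, "cytological_class": cyto,
             "true_class": histo, "role": role}
        )
        md_rows.append(
            {
                "patient_id": pid,
                "cytological_class": cyto,
                # histology is the known truth for training patients only;
                # for THY3 cases it is what the study must predict
                "histological_class": histo if role == "train" else None,
            }
        )

    dataset = MSIDataset(spectra, pd.DataFrame(md_rows))
    truth = {
        "peaks": pd.DataFrame(
            {
                "mz": model.centres,
                "discriminative": model.is_discriminative,
                "log_mean_ben": model.class_log_mean("Ben"),
                "log_mean_ptc": model.class_log_mean("PTC"),
            }
        ),
        "patients": pd.DataFrame(patients),
        "pixels": pd.DataFrame(pixels),
        "spec": spec,
    }
    return dataset, truth


def generate_mixed_smear(
    spec: CohortSpec,
    patient_id: str = "mixed",
    malignant_pixel_fraction: float = 0.3,
    pixels: int | None = None,
    seed: int = 0,
):
    """One malignant patient whose smear is only partially malignant.

    The patient is drawn from the *same* cohort-level peak model as
    ``generate_cohort(spec)`` (peak positions and class means depend
    only on ``spec.seed``), so a classifier trained on that cohort can
    be applied to this smear and its pixel map compared against the
    returned per-pixel latent classes.
    """
    if pixels is not None:
        spec = replace(spec, pixels_per_patient=pixels)
    model = _CohortModel(spec, np.random.default_rng(spec.seed))
    rng = np.random.default_rng(seed)
    spectra, latent = generate_patient(
        spec, model, patient_id, "PTC", rng,
        malignant_pixel_fraction=malignant_pixel_fraction,
    )
    metadata = pd.DataFrame(
        [{"patient_id": patient_id, "cytological_class": "THY3",
          "histological_class": None}]
    )
    return MSIDataset(spectra, metadata), pd.DataFrame(latent)


# ---------------------------------------------------------------------------
# in-print fixtures
# ---------------------------------------------------------------------------

#: 43-patient roster: (patient id, cytological class, histological class).
_STUDY_ROSTER = [
    (1, "THY2", "Ben"), (2, "THY3", "Ben"), (3, "THY4", "PTC"),
    (4, "THY5", "PTC"), (5, "THY2", "Ben"), (6, "THY5", "PTC"),
    (7, "THY2", "Ben"), (8, "THY5", "PTC"), (9, "THY3", "PTC"),
    (10, "THY4", "PTC"), (11, "THY2", "Ben"), (12, "THY4", "PTC"),
    (13, "THY3", "Ben"), (14, "THY3", "PTC"), (15, "THY4", "PTC"),
    (16, "THY2", "Ben"), (17, "THY2", "Ben"), (18, "THY3", "PTC"),
    (19, "THY2", "Ben"), (20, "THY3", "Ben"), (21, "THY4", "PTC"),
    (22, "THY3", "Ben"), (23, "THY5", "PTC"), (24, "THY2", "Ben"),
    (25, "THY4", "PTC"), (26, "THY4", "PTC"), (27, "THY2", "Ben"),
    (28, "THY2", "Ben"), (29, "THY2", "Ben"), (30, "THY5", "PTC"),
    (31, "THY5", "PTC"), (32, "THY2", "Ben"), (33, "THY5", "PTC"),
    (34, "THY3", "Ben"), (35, "THY2", "Ben"), (36, "THY3", "Ben"),
    (37, "THY3", "Ben"), (38, "THY5", "PTC"), (39, "THY5", "PTC"),
    (40, "THY5", "PTC"), (41, "THY3", "Ben"), (42, "THY4", "PTC"),
    (43, "THY2", "Ben"),
]

#: External-validation outcome for the 11 THY3 patients:
#: patient number -> (predicted class, true histological class).
_WORKED_EXAMPLE = {
    2: ("Ben", "Ben"), 9: ("PTC", "PTC"), 13: ("Ben", "Ben"),
    14: ("PTC", "PTC"), 18: ("PTC", "PTC"), 20: ("PTC", "Ben"),
    22: ("Ben", "Ben"), 34: ("Ben", "Ben"), 36: ("Ben", "Ben"),
    37: ("Ben", "Ben"), 41: ("PTC", "Ben"),
}


def study_cohort_table() -> pd.DataFrame:
    """The published 43-patient roster as a metadata table."""
    return pd.DataFrame(
        [
            {
                "patient_id": f"Patient #{n}",
                "cytological_class": cyto,
                "histological_class": histo,
            }
            for n, cyto, histo in _STUDY_ROSTER
        ]
    )


def generate_worked_example() -> pd.DataFrame:
    """The 11 THY3 validation patients' predicted vs. true classes.

    This is the published external-validation outcome, packaged as a
    fixture: feeding its columns to
    :func:`msiclassify.model.compute_metrics` (benign-positive)
    reproduces accuracy 0.818, sensitivity 0.750, specificity 1.000,
    PPV 1.000, NPV 0.600 and hard-label ROC AUC 0.875.
    """
    return pd.DataFrame(
        [
            {"patient_id": f"Patient #{n}", "predicted": pred, "true": true}
            for n, (pred, true) in sorted(_WORKED_EXAMPLE.items())
        ]
    )
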