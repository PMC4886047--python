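"""Pixel-by-pixel classification and molecular class maps.

Instead of classifying one average profile per patient, the trained SVM
is applied to every pixel's spectrum, producing a spatial map of
predicted tissue class: green = benign, red = malignant (papillary
thyroid carcinoma), grey = unclassified (pixels with no usable signal).
Such maps can expose small malignant regions that an average profile
would dilute away.

New (unknown) MSI data is conditioned exactly like the training data:
per-pixel preprocessing, MAD/S-N peak picking, then a dataset-wide
presence filter over the unknown file's own pixels (to discard the
false-positive peaks the S/N picker is known to produce) before each
pixel's surviving peaks are matched to the model's reference m/z list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .io import MSIDataset
from .model import TrainedClassifier
from .peaks import PeakList, PeakPickConfig, align_peaks, filter_peaks, pick_peaks_pixel
from .preprocess import DegenerateSpectrumError, PreprocessConfig, preprocess_spectrum

__all__ = ["ClassMap", "align_to_model", "classify_pixels", "render_map"]

UNCLASSIFIED = "unclassified"

# RGBA legend; background (no spectrum) is fully transparent
COLORS = {
    "Ben": (0, 200, 0, 255),
    "PTC": (200, 0, 0, 255),
    UNCLASSIFIED: (128, 128, 128, 255),
}
_COLOR_TO_LABEL = {v: k for k, v in COLORS.items()}


@dataclass
class ClassMap:
    """Per-pixel classification of one patient's smear."""

    patient_id: str
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray          # {"Ben", "PTC", "unclassified"}
    decision: np.ndarray        # NaN where unclassified
    width: int = 0
    height: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=int)
        self.labels = np.asarray(self.labels, dtype=object)
        self.decision = np.asarray(self.decision, dtype=float)
        n = self.x.size
        if not (self.y.size == self.labels.size == self.decision.size == n):
            raise ValueError("coordinate/label/decision arrays must match")
        if n:
            self.width = self.width or int(self.x.max())
            self.height = self.height or int(self.y.max())

    def __len__(self) -> int:
        return self.x.size

    def fraction(self, label: str) -> float:
        if len(self) == 0:
            return float("nan")
        return float(np.mean(self.labels == label))

    @property
    def fractions(self) -> dict[str, float]:
        out = {lab: self.fraction(lab) for lab in COLORS}
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.x, "y": self.y, "label": self.labels, "decision": self.decision}
        )


def align_to_model(
    pl: PeakList, clf: TrainedClassifier, fallback_spectrum=None
) -> np.ndarray:
    """Build the model-space feature vector for one peak list.

    For each selected reference m/z, take the intensity of the nearest
    input peak within the model's ppm tolerance window (ties broken
    toward the higher intensity); references with no peak in window get
    0.  An empty peak list therefore maps to the zero vector.

    With ``fallback_spectrum`` given (average-profile prediction), an
    unmatched reference is instead backfilled with the spectrum's
    maximum intensity inside the window — the same rule the training
    matrix uses — so train and test features share one scale.
    """
    tol_ppm = float(clf.provenance.get("tolerance_ppm", 2000.0))
    vec = np.zeros(clf.selected_mz.size)
    for j, ref in enumerate(clf.selected_mz):
        half = tol_ppm * 1e-6 * ref
        dist = np.abs(pl.mz - ref) if len(pl) else np.empty(0)
        in_win = np.flatnonzero(dist <= half)
        if in_win.size:
            # nearest first; among equidistant peaks prefer the more intense
            order = np.lexsort((-pl.intensity[in_win], dist[in_win]))
            vec[j] = pl.intensity[in_win[order[0]]]
        elif fallback_spectrum is not None:
            s = fallback_spectrum
            lo, hi = np.searchsorted(s.mz, [ref - half, ref + half])
            if hi > lo:
                vec[j] = float(s.intensity[lo:hi].max())
    return vec


def classify_pixels(
    dataset: MSIDataset,
    clf: TrainedClassifier,
    preprocess_cfg: PreprocessConfig | None = None,
    peak_cfg: PeakPickConfig | None = None,
) -> dict[str, ClassMap]:
    """Classify every pixel of a raw MSI dataset; one map per patient.

    Per pixel: preprocess -> pick peaks -> (dataset-wide presence filter
    at the training ``min_presence``) -> align to the model references ->
    SVM decision.  Pixels with degenerate (zero) total ion current are
    labelled unclassified; every other pixel gets a class, even with an
    empty feature vector — silently dropping pixels would bias the area
    fractions that make these maps useful.
    """
    prov = clf.provenance
    preprocess_cfg = preprocess_cfg or PreprocessConfig(
        **prov.get("preprocess", {})
    )
    peak_cfg = peak_cfg or PeakPickConfig(**prov.get("peaks", {}))
    min_presence = float(prov.get("min_presence", 0.25))
    tol_ppm = float(prov.get("tolerance_ppm", 2000.0))

    processed, degenerate = [], []
    for s in dataset.spectra:
        try:
            processed.append(preprocess_spectrum(s, preprocess_cfg))
        except DegenerateSpectrumError:
            degenerate.append(s)

    peak_lists = [pick_peaks_pixel(s, peak_cfg) for s in processed]
    if peak_lists:
        refs, aligned = align_peaks(peak_lists, tol_ppm)
        _, aligned = filter_peaks(aligned, refs, min_presence)
    else:
        aligned = []

    rows: dict[str, list] = {}
    for s, pl in zip(processed, aligned):
        # backfill unmatched references from the pixel's own spectrum so
        # pixel features live on the same scale as the training matrix
        vec = align_to_model(pl, clf, fallback_spectrum=s)
        d = float(clf.decision_values(vec)[0])
        label = "Ben" if d > 0 else "PTC"
        rows.setdefault(s.patient_id, []).append((s.x, s.y, label, d))
    for s in degenerate:
        rows.setdefault(s.patient_id, []).append((s.x, s.y, UNCLASSIFIED, float("nan")))

    maps: dict[str, ClassMap] = {}
    for pid, entries in rows.items():
        entries.sort(key=lambda e: (e[1], e[0]))
        xs, ys, labels, decs = zip(*entries)
        maps[pid] = ClassMap(
            patient_id=pid,
            x=np.array(xs),
            y=np.array(ys),
            labels=np.array(labels, dtype=object),
            decision=np.array(decs),
        )
    return maps


def render_map(cm: ClassMap, path: str | Path) -> None:
    """Write the class map as a PNG plus a JSON legend/fraction sidecar.

    Green pixels are benign, red malignant, grey unclassified; raster
    positions without a spectrum stay transparent.  The sidecar (same
    path with ``.json`` appended) records the legend and the class
    fractions so the image is self-describing.
    """
    if len(cm) == 0:
        raise ValueError("empty class map")
    path = Path(path)
    img = Image.new("RGBA", (cm.width, cm.height), (0, 0, 0, 0))
    px = img.load()
    for x, y, lab in zip(cm.x, cm.y, cm.labels):
        px[int(x) - 1, int(y) - 1] = COLORS[str(lab)]
    img.save(path, format="PNG")
    sidecar = {
        "patient_id": cm.patient_id,
        "legend": {k: list(v) for k, v in COLORS.items()},
        "fractions": cm.fractions,
        "n_pixels": len(cm),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_map_labels(path: str | Path) -> dict[tuple[int, int], str]:
    """Invert a rendered PNG back to a {(x, y): label} mapping."""
    img = Image.open(path).convert("RGBA")
    out: dict[tuple[int, int], str] = {}
    for yy in range(img.height):
        for xx in range(img.width):
            color = img.getpixel((xx, yy))
            if color in _COLOR_TO_LABEL:
                out[(xx + 1, yy + 1)] = _COLOR_TO_LABEL[color]
    return out
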