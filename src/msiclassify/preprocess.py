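"""Per-spectrum signal conditioning.

Three operators, applied in a fixed order by :func:`preprocess_spectrum`:

1. **Savitzky–Golay smoothing** — local least-squares polynomial fits
   remove high-frequency noise while preserving peak shape.
2. **TopHat baseline subtraction** — the baseline (chemical background +
   electrical noise floor) is estimated as the grey-scale morphological
   opening of the intensity trace with a flat structuring element and
   subtracted, bringing the spectrum down onto the x-axis.
3. **TIC normalisation** — every intensity is divided by the spectrum's
   total ion current so that all spectra share the same integrated area,
   making intensities comparable across pixels and patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import grey_dilation, grey_erosion
from scipy.signal import savgol_filter

from .io import Spectrum

__all__ = [
    "PreprocessConfig",
    "DegenerateSpectrumError",
    "smooth_savitzky_golay",
    "subtract_baseline_tophat",
    "normalize_tic",
    "preprocess_spectrum",
    "preprocess_dataset",
]


class DegenerateSpectrumError(ValueError):
    """The spectrum has no usable signal (zero or negative total ion current)."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    Attributes
    ----------
    savgol_half_window : int
        Smoothing half-window in points; the filter window is
        ``2*half_window + 1``.
    savgol_polyorder : int
        Degree of the local polynomial; must be smaller than the window.
    tophat_half_window : int
        Half-width in points of the flat structuring element.  Must be
        wider than the widest genuine peak, or peaks are eaten into the
        baseline.  The element acts in index space: MALDI-TOF axes are
        near-uniformly sampled, and morphological operators are defined
        on the sample grid.
    tic_target : float
        Total ion current after normalisation (the common integrated
        area); the default 1.0 makes intensities read as fractions.
    """

    savgol_half_window: int = 10
    savgol_polyorder: int = 3
    tophat_half_window: int = 75
    tic_target: float = 1.0

    def __post_init__(self) -> None:
        if self.tophat_half_window < 1:
            raise ValueError("tophat_half_window must be >= 1")
        if self.savgol_polyorder < 0:
            raise ValueError("savgol_polyorder must be >= 0")
        if 2 * self.savgol_half_window + 1 <= self.savgol_polyorder:
            raise ValueError("savgol window must exceed the polynomial order")
        if not self.tic_target > 0:
            raise ValueError("tic_target must be positive")


def smooth_savitzky_golay(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Savitzky–Golay smoothing of the intensity trace.

    Interior points get the value of a least-squares polynomial of degree
    ``savgol_polyorder`` fitted over ``2*savgol_half_window+1`` samples;
    edges are handled by evaluating the edge-window polynomial fit rather
    than by padding.  Negative outputs are allowed at this stage (the
    baseline step clips the final result).
    """
    window = 2 * cfg.savgol_half_window + 1
    if window > len(s):
        raise ValueError(
            f"smoothing window ({window}) longer than spectrum ({len(s)})"
        )
    smoothed = savgol_filter(
        s.intensity, window_length=window, polyorder=cfg.savgol_polyorder,
        mode="interp",
    )
    return s.replace_intensity(smoothed)


def subtract_baseline_tophat(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """TopHat baseline subtraction.

    The baseline is the morphological opening of the intensity sequence:
    grey-scale erosion followed by dilation with a flat structuring
    element of width ``2*tophat_half_window+1`` (windows truncated at the
    spectrum edges).  The opening is anti-extensive, so the residual
    ``intensity - baseline`` is non-negative up to rounding; it is clipped
    at zero.
    """
    width = 2 * cfg.tophat_half_window + 1
    if width > len(s):
        raise ValueError(
            f"structuring element ({width}) wider than spectrum ({len(s)})"
        )
    eroded = grey_erosion(s.intensity, size=width, mode="nearest")
    baseline = grey_dilation(eroded, size=width, mode="nearest")
    return s.replace_intensity(np.clip(s.intensity - baseline, 0.0, None))


def normalize_tic(s: Spectrum, cfg: PreprocessConfig) -> Spectrum:
    """Scale intensities so the total ion current equals ``tic_target``."""
    total = s.intensity.sum()
    if not total > 0:
        raise DegenerateSpectrumError(
            f"pixel ({s.x},{s.y}) of {s.patient_id}: total ion current "
            f"{total} is not positive"
        )
    return s.replace_intensity(s.intensity * (cfg.tic_target / total))


def preprocess_spectrum(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full conditioning chain: smooth, baseline-subtract, TIC-normalise.

    Raises :class:`DegenerateSpectrumError` when nothing but baseline was
    present (callers classifying pixels downgrade such pixels to
    "unclassified" instead of aborting).
    """
    cfg = cfg or PreprocessConfig()
    smoothed = smooth_savitzky_golay(s, cfg)
    residual = subtract_baseline_tophat(smoothed, cfg)
    # baseline removed essentially everything (e.g. a constant spectrum):
    # what is left is rounding noise, not signal
    scale = float(np.abs(smoothed.intensity).max())
    if residual.intensity.max() <= 1e-9 * max(scale, 1e-300):
        raise DegenerateSpectrumError(
            f"pixel ({s.x},{s.y}) of {s.patient_id}: no signal above baseline"
        )
    return normalize_tic(residual, cfg)


def preprocess_dataset(dataset, cfg: PreprocessConfig | None = None):
    """Preprocess every spectrum of an :class:`~msiclassify.io.MSIDataset`.

    Degenerate pixels are dropped (with their count returned via the
    second element of the tuple) rather than propagated as errors.
    """
    cfg = cfg or PreprocessConfig()
    kept, dropped = [], 0
    for s in dataset.spectra:
        try:
            kept.append(preprocess_spectrum(s, cfg))
        except DegenerateSpectrumError:
            dropped += 1
    from .io import MSIDataset

    return MSIDataset(kept, dataset.metadata), dropped
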