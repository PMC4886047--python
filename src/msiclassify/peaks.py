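"""Feature extraction: peak picking, ppm alignment, filtering, matrices.

Peak picking uses a robust global noise estimate — the median absolute
deviation (MAD) of the preprocessed intensities — and keeps strict local
maxima whose intensity reaches ``snr_threshold`` times that noise level
(threshold inclusive).  Peaks pooled across spectra are then aligned with
a relative (ppm) tolerance so that small analytical m/z shifts do not
masquerade as distinct molecular species, filtered by how many spectra
they appear in (false-positive control), and tabulated into the
samples x peaks "peak-list matrix" that feeds the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d

from .io import MSIDataset, PeakMatrix, Spectrum

__all__ = [
    "PeakPickConfig",
    "PeakList",
    "ReferencePeaks",
    "estimate_noise_mad",
    "pick_peaks",
    "align_peaks",
    "filter_peaks",
    "build_peak_matrix",
    "average_patient_profile",
]


@dataclass(frozen=True)
class PeakPickConfig:
    """Peak-picking parameters.

    ``snr_threshold`` — minimum signal-to-noise ratio (inclusive).
    ``halfwindow_local_max`` — a peak must be the unique maximum within
    this many points on either side.
    ``mad_scale`` — 1.4826 makes the MAD consistent with the standard
    deviation under Gaussian noise (the convention of R's ``mad()``).
    """

    snr_threshold: float = 3.0
    halfwindow_local_max: int = 20
    mad_scale: float = 1.4826

    def __post_init__(self) -> None:
        if not self.snr_threshold > 0:
            raise ValueError("snr_threshold must be positive")
        if self.halfwindow_local_max < 1:
            raise ValueError("halfwindow_local_max must be >= 1")


@dataclass
class PeakList:
    """Detected peaks of one sample (pixel or average profile)."""

    source_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be matching 1-D arrays")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("peak m/z must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class ReferencePeaks:
    """Consensus peak positions merged across spectra.

    ``support[j]`` counts the distinct source spectra contributing to
    reference ``mz[j]``.
    """

    mz: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        if self.mz.shape != self.support.shape:
            raise ValueError("mz and support must match")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("reference m/z must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size


def estimate_noise_mad(s: Spectrum, cfg: PeakPickConfig | None = None) -> float:
    """Global spectrum noise: ``mad_scale * median(|I - median(I)|)``."""
    cfg = cfg or PeakPickConfig()
    if len(s) == 0:
        raise ValueError("empty spectrum")
    med = np.median(s.intensity)
    return float(cfg.mad_scale * np.median(np.abs(s.intensity - med)))


def pick_peaks(s: Spectrum, cfg: PeakPickConfig | None = None) -> PeakList:
    """Select strict local maxima with signal-to-noise >= threshold.

    A point qualifies when it is strictly greater than every other point
    within ``halfwindow_local_max`` on each side and its intensity is at
    least ``snr_threshold`` times the MAD noise.  An empty peak list is a
    legal outcome.
    """
    cfg = cfg or PeakPickConfig()
    noise = estimate_noise_mad(s, cfg)
    intensity = s.intensity
    w = 2 * cfg.halfwindow_local_max + 1
    local_max = maximum_filter1d(intensity, size=w, mode="nearest")
    floor = cfg.snr_threshold * noise
    candidates = np.flatnonzero(
        (intensity >= floor) & (intensity == local_max) & (intensity > 0)
    )
    keep = []
    hw = cfg.halfwindow_local_max
    for i in candidates:
        lo, hi = max(0, i - hw), min(intensity.size, i + hw + 1)
        window = intensity[lo:hi]
        # strictness: the candidate must be the *unique* maximum
        if np.count_nonzero(window == intensity[i]) == 1:
            keep.append(i)
    idx = np.asarray(keep, dtype=int)
    return PeakList(f"{s.patient_id}", s.mz[idx], intensity[idx])


def _pixel_source_id(s: Spectrum) -> str:
    return f"{s.patient_id}:{s.x}:{s.y}"


def pick_peaks_pixel(s: Spectrum, cfg: PeakPickConfig | None = None) -> PeakList:
    """Like :func:`pick_peaks` but keyed by ``patient:x:y`` for pixel work."""
    pl = pick_peaks(s, cfg)
    pl.source_id = _pixel_source_id(s)
    return pl


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _split_same_source(groups: list[np.ndarray], mz: np.ndarray, source: np.ndarray):
    """Split any group holding two peaks from one source at its widest gap."""
    out: list[np.ndarray] = []
    stack = list(groups)
    while stack:
        g = stack.pop()
        srcs = source[g]
        if len(np.unique(srcs)) == len(srcs) or len(g) == 1:
            out.append(g)
            continue
        gaps = np.diff(mz[g])
        cut = int(np.argmax(gaps)) + 1
        stack.append(g[:cut])
        stack.append(g[cut:])
    out.sort(key=lambda g: mz[g[0]])
    return out


def align_peaks(
    lists: Sequence[PeakList], tolerance_ppm: float = 2000.0
) -> tuple[ReferencePeaks, list[PeakList]]:
    """Cluster pooled peaks into consensus references within a ppm window.

    Pooled peaks sorted by m/z are partitioned by single-pass greedy gap
    clustering: a new reference group opens whenever the gap to the
    previous peak exceeds ``tolerance_ppm * 1e-6 * mz``.  Groups that end
    up holding two peaks from the same source are split at their largest
    internal gap until conflict-free.  Each group's reference m/z is the
    intensity-weighted mean of its members; every input peak is relabelled
    to its group's reference.
    """
    if not tolerance_ppm > 0:
        raise ValueError("tolerance_ppm must be positive")
    n_lists = len(lists)
    if n_lists == 0:
        return ReferencePeaks(np.empty(0), np.empty(0, dtype=int)), []

    mz_all, int_all, src_all, pos_all = [], [], [], []
    for si, pl in enumerate(lists):
        mz_all.append(pl.mz)
        int_all.append(pl.intensity)
        src_all.append(np.full(len(pl), si))
        pos_all.append(np.arange(len(pl)))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    source = np.concatenate(src_all)

    order = np.lexsort((source, mz))
    mz_s, int_s, src_s = mz[order], inten[order], source[order]

    groups: list[np.ndarray] = []
    if mz_s.size:
        gaps = np.diff(mz_s)
        breaks = np.flatnonzero(gaps > tolerance_ppm * 1e-6 * mz_s[1:]) + 1
        groups = [np.asarray(g) for g in np.split(np.arange(mz_s.size), breaks)]
    groups = _split_same_source(groups, mz_s, src_s)

    ref_mz = np.empty(len(groups))
    support = np.empty(len(groups), dtype=int)
    assign = np.empty(mz_s.size, dtype=int)
    for j, g in enumerate(groups):
        weights = int_s[g]
        total = weights.sum()
        ref_mz[j] = (
            float(np.average(mz_s[g], weights=weights)) if total > 0
            else float(mz_s[g].mean())
        )
        support[j] = len(np.unique(src_s[g]))
        assign[g] = j

    refs = ReferencePeaks(ref_mz, support)

    aligned: list[PeakList] = []
    group_of = np.empty(mz.size, dtype=int)
    group_of[order] = assign
    offset = 0
    for pl in lists:
        k = len(pl)
        gids = group_of[offset : offset + k]
        offset += k
        order_k = np.argsort(ref_mz[gids], kind="stable")
        aligned.append(
            PeakList(pl.source_id, ref_mz[gids][order_k], pl.intensity[order_k])
        )
    return refs, aligned


def filter_peaks(
    aligned: Sequence[PeakList],
    references: ReferencePeaks,
    min_presence: float = 0.25,
) -> tuple[ReferencePeaks, list[PeakList]]:
    """Drop references present in fewer than ``min_presence`` of spectra.

    The boundary is inclusive: a reference found in exactly
    ``min_presence * n_spectra`` spectra survives.
    """
    if not 0 < min_presence <= 1:
        raise ValueError("min_presence must be in (0, 1]")
    n = len(aligned)
    if n == 0:
        return references, []
    keep = references.support / n >= min_presence
    kept_refs = ReferencePeaks(references.mz[keep], references.support[keep])
    kept_set = set(kept_refs.mz.tolist())
    out = []
    for pl in aligned:
        mask = np.isin(pl.mz, kept_refs.mz)
        out.append(PeakList(pl.source_id, pl.mz[mask], pl.intensity[mask]))
    del kept_set
    return kept_refs, out


def match_to_references(
    pl: PeakList, references: ReferencePeaks, tolerance_ppm: float = 2000.0
) -> PeakList:
    """Relabel a peak list onto an existing reference grid.

    Each reference takes the nearest input peak within the ppm window
    (ties toward the higher intensity); unmatched references are simply
    absent from the returned list.  This is how peaks from *new* data —
    patient average profiles or unknown pixels — are mapped onto the
    consensus references established on the full training dataset.
    """
    mz_out, int_out = [], []
    for ref in references.mz:
        half = tolerance_ppm * 1e-6 * ref
        dist = np.abs(pl.mz - ref) if len(pl) else np.empty(0)
        in_win = np.flatnonzero(dist <= half)
        if in_win.size:
            order = np.lexsort((-pl.intensity[in_win], dist[in_win]))
            mz_out.append(float(ref))
            int_out.append(float(pl.intensity[in_win[order[0]]]))
    return PeakList(pl.source_id, np.asarray(mz_out), np.asarray(int_out))


def build_peak_matrix(
    aligned: Sequence[PeakList],
    references: ReferencePeaks,
    spectra: Mapping[str, Spectrum] | None = None,
    backfill: bool = False,
    tolerance_ppm: float = 2000.0,
) -> PeakMatrix:
    """Tabulate aligned peak lists into the samples x references matrix.

    Where a sample has no detected peak at a reference, the cell is 0 —
    or, with ``backfill`` on, the sample's preprocessed-spectrum maximum
    intensity inside the ppm window around the reference (its presence
    flag stays ``False`` either way).
    """
    ref_mz = references.mz
    n, p = len(aligned), ref_mz.size
    values = np.zeros((n, p))
    presence = np.zeros((n, p), dtype=bool)
    sample_ids = [pl.source_id for pl in aligned]
    col_of = {m: j for j, m in enumerate(ref_mz.tolist())}
    for i, pl in enumerate(aligned):
        for m, h in zip(pl.mz.tolist(), pl.intensity.tolist()):
            j = col_of.get(m)
            if j is not None:
                values[i, j] = h
                presence[i, j] = True
    if backfill:
        if spectra is None:
            raise ValueError("backfill requested but no spectra supplied")
        for i, sid in enumerate(sample_ids):
            if sid not in spectra:
                raise ValueError(f"no spectrum available for sample {sid!r}")
            s = spectra[sid]
            for j in np.flatnonzero(~presence[i]):
                ref = ref_mz[j]
                half = tolerance_ppm * 1e-6 * ref
                lo, hi = np.searchsorted(s.mz, [ref - half, ref + half + 1e-12])
                if hi > lo:
                    values[i, j] = float(s.intensity[lo:hi].max())
    return PeakMatrix(sample_ids, ref_mz, values, presence)


def average_patient_profile(dataset: MSIDataset, patient_id: str) -> Spectrum:
    """Pointwise mean spectrum over a patient's pixels.

    All pixels of a continuous-mode acquisition share one axis; with
    per-pixel axes the others are linearly interpolated onto the first
    pixel's axis before averaging.  Peak picking on the returned mean
    spectrum yields the patient's representative peak list.
    """
    spectra = dataset.spectra_for(patient_id)
    if not spectra:
        raise ValueError(f"patient {patient_id!r} has no spectra")
    axis = spectra[0].mz
    rows = np.empty((len(spectra), axis.size))
    for i, s in enumerate(spectra):
        if s.mz.size == axis.size and np.array_equal(s.mz, axis):
            rows[i] = s.intensity
        else:
            rows[i] = np.interp(axis, s.mz, s.intensity)
    return Spectrum(axis, rows.mean(axis=0), 0, 0, patient_id)
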