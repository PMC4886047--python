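"""Data model and file formats for MALDI-MSI classification.

A mass-spectrometry-imaging (MSI) acquisition is a "data cube": one mass
spectrum per pixel of a rastered tissue section.  This module defines the
in-memory containers shared by the whole pipeline — :class:`Spectrum`,
:class:`MSIDataset` and :class:`PeakMatrix` — together with readers and
writers for the community-standard imzML format (via :mod:`pyimzml`) and
for the tabular artifacts (patient metadata, peak matrices, predictions).

Conventions
-----------
* m/z axes are strictly increasing, in thomson (Th).
* Pixel coordinates are 1-based integers, as in the imzML standard.
* Patient identity is carried one-imzML-file-per-patient; a sidecar CSV
  holds the per-patient cytological and histological classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "MSIDataset",
    "PeakMatrix",
    "FormatError",
    "MetadataError",
    "CYTOLOGICAL_CLASSES",
    "HISTOLOGICAL_CLASSES",
    "read_imzml",
    "write_imzml",
    "read_metadata",
    "write_table",
    "concat_datasets",
]

#: SIAPEC cytological categories (THY1 = inadequate ... THY5 = malignant).
CYTOLOGICAL_CLASSES = ("THY1", "THY2", "THY3", "THY4", "THY5")
#: Histological ground-truth labels: benign lesion / papillary thyroid carcinoma.
HISTOLOGICAL_CLASSES = ("Ben", "PTC")

METADATA_COLUMNS = ("patient_id", "cytological_class", "histological_class")


class FormatError(ValueError):
    """A file violates the expected on-disk format."""


class MetadataError(ValueError):
    """A metadata table contains unknown class tokens or is malformed."""


@dataclass
class Spectrum:
    """One pixel's mass spectrum.

    Parameters
    ----------
    mz : ndarray
        Strictly increasing m/z axis (Th).
    intensity : ndarray
        Intensities, same length as ``mz``, all finite.
    x, y : int
        1-based raster coordinates of the pixel.
    patient_id : str
        Opaque identifier linking the pixel to a patient record.
    """

    mz: np.ndarray
    intensity: np.ndarray
    x: int
    y: int
    patient_id: str

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if self.mz.size != self.intensity.size:
            raise ValueError(
                f"mz ({self.mz.size}) and intensity ({self.intensity.size}) "
                "differ in length"
            )
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz axis must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size

    def replace_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Return a copy with a new intensity array (metadata preserved)."""
        return Spectrum(self.mz, intensity, self.x, self.y, self.patient_id)

    @property
    def tic(self) -> float:
        """Total ion current: the sum of all intensities."""
        return float(self.intensity.sum())


def _validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    if metadata.empty:
        raise MetadataError("metadata table is empty")
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise MetadataError(f"metadata missing columns: {missing}")
    md = metadata.copy()
    md["patient_id"] = md["patient_id"].astype(str)
    if md["patient_id"].duplicated().any():
        dups = md.loc[md["patient_id"].duplicated(), "patient_id"].tolist()
        raise MetadataError(f"duplicate patient ids: {dups}")
    for col, vocab in (
        ("cytological_class", CYTOLOGICAL_CLASSES),
        ("histological_class", HISTOLOGICAL_CLASSES),
    ):
        values = md[col]
        bad = values.notna() & ~values.isin(vocab)
        if bad.any():
            rows = md.index[bad].tolist()
            tokens = sorted(set(values[bad]))
            raise MetadataError(
                f"unknown {col} token(s) {tokens} in rows {rows}; "
                f"allowed: {list(vocab)}"
            )
    return md


@dataclass
class MSIDataset:
    """An ordered collection of pixel spectra plus per-patient metadata.

    Invariants: every spectrum's ``patient_id`` appears in ``metadata``,
    and ``(x, y, patient_id)`` triples are unique.
    """

    spectra: list[Spectrum]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        self.metadata = _validate_metadata(self.metadata)
        known = set(self.metadata["patient_id"])
        seen: set[tuple[int, int, str]] = set()
        for s in self.spectra:
            if s.patient_id not in known:
                raise ValueError(
                    f"spectrum at ({s.x},{s.y}) references unknown patient "
                    f"{s.patient_id!r}"
                )
            key = (s.x, s.y, s.patient_id)
            if key in seen:
                raise ValueError(f"duplicate pixel {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def patient_ids(self) -> list[str]:
        """Patients that have at least one spectrum, in metadata order."""
        present = {s.patient_id for s in self.spectra}
        return [p for p in self.metadata["patient_id"] if p in present]

    def spectra_for(self, patient_id: str) -> list[Spectrum]:
        return [s for s in self.spectra if s.patient_id == patient_id]

    def subset(self, patient_ids: Iterable[str]) -> "MSIDataset":
        """Restrict the dataset to the given patients."""
        wanted = [str(p) for p in patient_ids]
        md = self.metadata[self.metadata["patient_id"].isin(wanted)]
        spectra = [s for s in self.spectra if s.patient_id in set(wanted)]
        return MSIDataset(spectra, md.reset_index(drop=True))

    def map_intensities(self, func) -> "MSIDataset":
        """Apply ``func(Spectrum) -> Spectrum`` to every pixel."""
        return MSIDataset([func(s) for s in self.spectra], self.metadata)


@dataclass
class PeakMatrix:
    """Samples x aligned-peaks intensity table (the peak-list matrix).

    Rows are samples (patient average profiles, or individual pixels);
    columns are consensus reference m/z values.  ``presence`` records
    whether the peak was actually detected in that sample (``True``) or
    the value was backfilled/zero (``False``).
    """

    sample_ids: list[str]
    reference_mz: np.ndarray
    values: np.ndarray
    presence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        self.reference_mz = np.asarray(self.reference_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.presence is None:
            self.presence = np.ones_like(self.values, dtype=bool)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.values.shape != (len(self.sample_ids), self.reference_mz.size):
            raise ValueError("values shape does not match labels")
        if self.presence.shape != self.values.shape:
            raise ValueError("presence shape does not match values")
        if self.reference_mz.size and np.any(np.diff(self.reference_mz) <= 0):
            raise ValueError("reference_mz must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def restrict(self, mz_subset: Sequence[float]) -> "PeakMatrix":
        """Column-restrict to the given reference m/z values (exact match)."""
        idx = []
        for mz in mz_subset:
            hits = np.flatnonzero(np.isclose(self.reference_mz, mz, rtol=0, atol=1e-9))
            if hits.size != 1:
                raise ValueError(f"reference m/z {mz} not found in matrix")
            idx.append(int(hits[0]))
        idx = sorted(idx)
        return PeakMatrix(
            self.sample_ids,
            self.reference_mz[idx],
            self.values[:, idx],
            self.presence[:, idx],
        )

    def to_dataframe(self, mz_decimals: int = 4) -> pd.DataFrame:
        cols = [f"{mz:.{mz_decimals}f}" for mz in self.reference_mz]
        return pd.DataFrame(self.values, index=self.sample_ids, columns=cols)


# ---------------------------------------------------------------------------
# imzML I/O
# ---------------------------------------------------------------------------

def read_imzml(
    path: str | Path,
    patient_id: str | None = None,
    metadata: pd.DataFrame | None = None,
) -> MSIDataset:
    """Read one imzML file (one patient) into an :class:`MSIDataset`.

    The companion ``.ibd`` binary must sit next to the XML file.  Spectra
    are returned sorted by ``(patient_id, y, x)``; an unsorted m/z axis is
    sorted together with its intensities, and an axis with duplicate m/z
    values raises :class:`FormatError`.

    Parameters
    ----------
    patient_id
        Defaults to the file stem.
    metadata
        Optional patient table; a minimal single-row table (classes
        unknown) is synthesised when omitted.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(
            f"missing companion binary {ibd} for imzML file {path}"
        )
    pid = patient_id if patient_id is not None else path.stem

    parser = ImzMLParser(str(path))
    spectra: list[Spectrum] = []
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz, inten = mz[order], inten[order]
        if np.any(np.diff(mz) <= 0):
            raise FormatError(
                f"pixel ({x},{y}) in {path.name}: m/z axis has duplicate "
                "values and cannot be sorted consistently"
            )
        spectra.append(Spectrum(mz, inten, int(x), int(y), pid))
    spectra.sort(key=lambda s: (s.patient_id, s.y, s.x))

    if metadata is None:
        metadata = pd.DataFrame(
            [{"patient_id": pid, "cytological_class": None, "histological_class": None}]
        )
    return MSIDataset(spectra, metadata)


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as imzML (+ .ibd), 64-bit float arrays.

    Continuous mode is used when every spectrum shares one m/z axis,
    processed mode otherwise (per-pixel axes preserved losslessly).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    if not dataset.spectra:
        raise ValueError("cannot write an empty dataset")
    path = Path(path)
    first = dataset.spectra[0].mz
    shared = all(
        s.mz.size == first.size and np.array_equal(s.mz, first)
        for s in dataset.spectra
    )
    mode = "continuous" if shared else "processed"
    with ImzMLWriter(
        str(path), mode=mode, mz_dtype=np.float64, intensity_dtype=np.float64
    ) as writer:
        for s in dataset.spectra:
            writer.addSpectrum(s.mz, s.intensity, (s.x, s.y, 1))


def concat_datasets(datasets: Sequence[MSIDataset]) -> MSIDataset:
    """Merge per-patient datasets; metadata rows are deduplicated by id."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    spectra = [s for ds in datasets for s in ds.spectra]
    md = pd.concat([ds.metadata for ds in datasets], ignore_index=True)
    md = md.drop_duplicates(subset="patient_id").reset_index(drop=True)
    return MSIDataset(spectra, md)


# ---------------------------------------------------------------------------
# tabular artifacts
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-patient metadata CSV.

    Required columns: ``patient_id``, ``cytological_class`` (THY1..THY5),
    ``histological_class`` (Ben/PTC; may be empty for unresolved cases).
    """
    df = pd.read_csv(path, dtype=str).replace({"": None})
    return _validate_metadata(df)


def write_table(
    obj: "PeakMatrix | pd.DataFrame", path: str | Path, mz_decimals: int = 4
) -> None:
    """Serialise a peak matrix (m/z column headers at fixed precision) or
    any tabular artifact (metadata, predictions) to CSV."""
    if isinstance(obj, PeakMatrix):
        df = obj.to_dataframe(mz_decimals=mz_decimals)
        df.index.name = "sample_id"
        df.to_csv(path)
    else:
        obj.to_csv(path, index=False)
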