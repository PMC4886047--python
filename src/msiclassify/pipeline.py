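"""End-to-end workflow: average-profile training, validation, pixel maps.

The central objects follow the model/results idiom of statistical
packages: :class:`MSIClassificationModel` is built from data (an
:class:`~msiclassify.io.MSIDataset`, via :meth:`from_dataset`, or a
ready peak matrix) and holds the *design* — the peak-list matrix, the
class labels and the preprocessing/alignment provenance.  Its
:meth:`~MSIClassificationModel.fit` runs feature selection, SVM tuning
and repeated cross-validation and returns a
:class:`MSIClassificationResults` carrying the trained classifier, the
selection/tuning record and the CV diagnostics, with ``summary()``,
``predict``, ``validate`` and ``classify_pixels`` methods.

Training labels collapse cytology to the histology-backed binary
classes (THY2 -> Ben; THY4/THY5 -> PTC); explicit histology in the
metadata takes precedence.  Cytologically undetermined (THY3) patients
cannot be used for training and belong in the validation set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .featsel import RFEResult, rfe
from .io import MSIDataset, PeakMatrix, read_imzml, read_metadata, write_table
from .model import (
    PerformanceReport,
    SVMConfig,
    TrainedClassifier,
    compute_metrics,
    cross_validate,
    train_svm,
    tune_svm,
)
from .peaks import (
    PeakPickConfig,
    align_peaks,
    build_peak_matrix,
    filter_peaks,
    pick_peaks_pixel,
)
from .pixelmap import ClassMap, align_to_model, classify_pixels
from .preprocess import PreprocessConfig, preprocess_dataset

__all__ = [
    "PipelineConfig",
    "MSIClassificationModel",
    "MSIClassificationResults",
    "run_training",
    "run_validation",
    "training_labels",
]

_CYTO_TO_CLASS = {"THY2": "Ben", "THY4": "PTC", "THY5": "PTC"}


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration of the whole workflow."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    peaks: PeakPickConfig = field(default_factory=PeakPickConfig)
    tolerance_ppm: float = 2000.0
    min_presence: float = 0.25
    rfe_sizes: tuple[int, ...] | None = None
    folds: int = 10
    repeats: int = 2
    svm_grid: tuple[tuple[float, float], ...] | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "preprocess" in kwargs:
            kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
        if "peaks" in kwargs:
            kwargs["peaks"] = PeakPickConfig(**kwargs["peaks"])
        if "rfe_sizes" in kwargs and kwargs["rfe_sizes"] is not None:
            kwargs["rfe_sizes"] = tuple(kwargs["rfe_sizes"])
        if "svm_grid" in kwargs and kwargs["svm_grid"] is not None:
            kwargs["svm_grid"] = tuple(tuple(g) for g in kwargs["svm_grid"])
        return cls(**kwargs)

    def as_dict(self) -> dict:
        d = asdict(self)
        return d

    @property
    def hash(self) -> str:
        text = json.dumps(self.as_dict(), sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def training_labels(metadata: pd.DataFrame) -> dict[str, str]:
    """Histology-backed binary label per patient; THY3-without-histology
    raises (such cases are validation material, not training material)."""
    labels: dict[str, str] = {}
    for _, row in metadata.iterrows():
        pid = str(row["patient_id"])
        histo = row.get("histological_class")
        if isinstance(histo, str) and histo:
            labels[pid] = histo
            continue
        cyto = row.get("cytological_class")
        mapped = _CYTO_TO_CLASS.get(cyto if isinstance(cyto, str) else "")
        if mapped is None:
            raise ValueError(
                f"patient {pid!r}: no histology and cytology {cyto!r} does "
                "not determine a training class"
            )
        labels[pid] = mapped
    return labels


class MSIClassificationModel:
    """Average-profile classification model (unfitted design).

    Parameters
    ----------
    peak_matrix : PeakMatrix
        Patients x aligned-reference intensity table.
    labels : mapping or sequence
        Histological class per sample (aligned with the matrix rows when
        given as a sequence).
    config : PipelineConfig
    profile_spectra : optional
        The preprocessed average-profile spectra, kept for provenance.
    """

    def __init__(
        self,
        peak_matrix: PeakMatrix,
        labels,
        config: PipelineConfig | None = None,
        profile_spectra: dict | None = None,
    ):
        self.config = config or PipelineConfig()
        self.peak_matrix = peak_matrix
        if isinstance(labels, dict):
            labels = [labels[s] for s in peak_matrix.sample_ids]
        self.labels = np.asarray([str(v) for v in labels])
        if self.labels.size != len(peak_matrix.sample_ids):
            raise ValueError("one label per matrix row required")
        self.profile_spectra = profile_spectra or {}

    # -- construction from raw data ----------------------------------------

    @classmethod
    def from_dataset(
        cls, dataset: MSIDataset, config: PipelineConfig | None = None
    ) -> "MSIClassificationModel":
        """Run the full conditioning chain on a raw training dataset.

        preprocess every pixel -> pick peaks on every pixel spectrum ->
        align across the whole dataset (ppm tolerance) -> presence
        filter over *all* pixel spectra (false-positive control; the
        denominator is the pixel count) -> pixel-level peak-list matrix
        (undetected references backfilled from each pixel's spectrum)
        -> average profile per patient as the mean of the patient's
        pixel rows.

        Averaging *after* peak extraction keeps the patient features on
        the same intensity scale as single-pixel features, which is
        what lets one classifier serve both the average-profile and the
        pixel-by-pixel routes.
        """
        config = config or PipelineConfig()
        processed, _ = preprocess_dataset(dataset, config.preprocess)
        if not processed.patient_ids:
            raise ValueError("no usable spectra in the training dataset")
        # only patients actually present in the data need training labels
        # (the metadata table may also list validation patients)
        present = processed.metadata["patient_id"].isin(processed.patient_ids)
        labels = training_labels(processed.metadata[present])

        pixel_lists = [
            pick_peaks_pixel(s, config.peaks) for s in processed.spectra
        ]
        refs, aligned_pixels = align_peaks(pixel_lists, config.tolerance_ppm)
        refs, aligned_pixels = filter_peaks(
            aligned_pixels, refs, config.min_presence
        )
        pixel_spectra = {
            f"{s.patient_id}:{s.x}:{s.y}": s for s in processed.spectra
        }
        pixel_matrix = build_peak_matrix(
            aligned_pixels, refs, spectra=pixel_spectra, backfill=True,
            tolerance_ppm=config.tolerance_ppm,
        )

        patient_of = [sid.rsplit(":", 2)[0] for sid in pixel_matrix.sample_ids]
        rows, presence, ids = [], [], []
        for pid in processed.patient_ids:
            mask = np.asarray([p == pid for p in patient_of])
            rows.append(pixel_matrix.values[mask].mean(axis=0))
            # a peak counts as present for the patient when detected in
            # at least the filter fraction of the patient's own pixels
            presence.append(
                pixel_matrix.presence[mask].mean(axis=0) >= config.min_presence
            )
            ids.append(pid)
        matrix = PeakMatrix(
            ids, refs.mz, np.vstack(rows), np.vstack(presence)
        )
        return cls(
            matrix,
            {pid: labels[pid] for pid in matrix.sample_ids},
            config,
        )

    @property
    def n_samples(self) -> int:
        return len(self.peak_matrix.sample_ids)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int | None = None) -> "MSIClassificationResults":
        """Feature selection, hyperparameter tuning, training and CV."""
        cfg = self.config
        if cfg.folds > self.n_samples:
            raise ValueError(
                f"folds={cfg.folds} exceeds the {self.n_samples} training "
                "patients; reduce folds"
            )
        seed = cfg.seed if seed is None else int(seed)
        rng = np.random.default_rng(seed)
        rfe_seed, tune_seed, cv_seed = (
            int(rng.integers(0, 2**31 - 1)) for _ in range(3)
        )

        rfe_result = rfe(
            self.peak_matrix.values,
            self.labels,
            mz=self.peak_matrix.reference_mz,
            sizes=cfg.rfe_sizes,
            k=cfg.folds,
            repeats=cfg.repeats,
            seed=rfe_seed,
        )
        X_sel = self.peak_matrix.values[:, rfe_result.selected_idx]
        grid = list(cfg.svm_grid) if cfg.svm_grid else None
        svm_cfg = tune_svm(
            X_sel, self.labels, grid=grid, k=cfg.folds,
            repeats=cfg.repeats, seed=tune_seed,
        )
        provenance = {
            "preprocess": asdict(cfg.preprocess),
            "peaks": asdict(cfg.peaks),
            "tolerance_ppm": cfg.tolerance_ppm,
            "min_presence": cfg.min_presence,
            "reference_mz": self.peak_matrix.reference_mz.tolist(),
            "config_hash": cfg.hash,
            "seed": seed,
        }
        classifier = train_svm(
            X_sel, self.labels, svm_cfg,
            selected_mz=rfe_result.selected_mz, provenance=provenance,
        )
        cv_report = cross_validate(
            X_sel, self.labels, svm_cfg, k=cfg.folds,
            repeats=cfg.repeats, seed=cv_seed,
        )
        return MSIClassificationResults(
            self, rfe_result, svm_cfg, classifier, cv_report, seed
        )


class MSIClassificationResults:
    """Fitted pipeline: selected features, tuned SVM, CV diagnostics."""

    def __init__(
        self,
        model: MSIClassificationModel,
        rfe_result: RFEResult,
        svm_config: SVMConfig,
        classifier: TrainedClassifier,
        cv_report: PerformanceReport,
        seed: int,
    ):
        self.model = model
        self.rfe_result = rfe_result
        self.svm_config = svm_config
        self.classifier = classifier
        self.cv_report = cv_report
        self.seed = seed

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        m, r = self.model, self.rfe_result
        class_counts = pd.Series(m.labels).value_counts().to_dict()
        lines = [
            "MSI average-profile classification",
            "=" * 46,
            f"training patients      {m.n_samples}  {class_counts}",
            f"aligned peaks          {m.peak_matrix.reference_mz.size}",
            f"selected features      {r.chosen_size}"
            f"  (candidates {list(r.sizes)})",
            f"RFE CV accuracy        {r.cv_profile[r.chosen_size]:.3f}"
            f"  at size {r.chosen_size}",
            f"SVM (radial)           cost={self.svm_config.cost:g}"
            f"  gamma={self.svm_config.gamma:g}",
            f"seed                   {self.seed}",
            "-" * 46,
            "repeated-CV performance (pooled held-out):",
            self.cv_report.summary(),
            "-" * 46,
            "selected m/z: "
            + ", ".join(f"{v:.1f}" for v in r.selected_mz),
        ]
        return "\n".join(lines)

    # -- prediction on new raw data ------------------------------------------

    def predict(self, dataset: MSIDataset) -> pd.DataFrame:
        """Average-profile prediction for every patient in ``dataset``.

        Each patient's pixels are preprocessed and peak-picked, every
        pixel's peaks are matched to the model's selected references
        (unmatched references backfilled from the pixel's spectrum,
        exactly as in training), and the patient's average feature
        vector is scored by the SVM.  No presence filter is applied on
        the way to an average-profile verdict — filtering is reserved
        for the pixel-by-pixel route, where single-spectrum false
        positives actually matter.  Returns a table of
        (patient_id, predicted, decision).
        """
        cfg = self.model.config
        processed, _ = preprocess_dataset(dataset, cfg.preprocess)
        if not processed.patient_ids:
            raise ValueError("no usable spectra in the dataset")
        skipped = [
            p for p in dataset.metadata["patient_id"]
            if p not in set(processed.patient_ids)
        ]
        if skipped:
            import warnings

            warnings.warn(
                f"patients without usable spectra excluded: {skipped}",
                stacklevel=2,
            )
        rows = []
        for pid in processed.patient_ids:
            vecs = [
                align_to_model(
                    pick_peaks_pixel(s, cfg.peaks), self.classifier,
                    fallback_spectrum=s,
                )
                for s in processed.spectra_for(pid)
            ]
            vec = np.vstack(vecs).mean(axis=0)
            d = float(self.classifier.decision_values(vec)[0])
            rows.append(
                {"patient_id": pid, "predicted": "Ben" if d > 0 else "PTC",
                 "decision": d}
            )
        return pd.DataFrame(rows)

    def validate(
        self, dataset: MSIDataset, truth: dict | pd.Series | None = None
    ) -> tuple[pd.DataFrame, PerformanceReport]:
        """External validation: per-patient predictions plus metrics.

        ``truth`` maps patient_id -> class; defaults to the dataset's
        ``histological_class`` metadata column.
        """
        preds = self.predict(dataset)
        if truth is None:
            md = dataset.metadata.set_index("patient_id")["histological_class"]
            truth = md.to_dict()
        preds = preds.assign(true=[truth[p] for p in preds["patient_id"]])
        missing = preds["true"].isna()
        if missing.any():
            raise ValueError(
                f"no ground truth for patients "
                f"{preds.loc[missing, 'patient_id'].tolist()}"
            )
        report = compute_metrics(
            preds["predicted"], preds["true"],
            decision_values=preds["decision"],
        )
        return preds, report

    def classify_pixels(self, dataset: MSIDataset) -> dict[str, ClassMap]:
        """Pixel-by-pixel classification of a raw MSI dataset."""
        return classify_pixels(
            dataset, self.classifier,
            self.model.config.preprocess, self.model.config.peaks,
        )

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist the trained classifier (with provenance) as JSON."""
        payload = json.loads(self.classifier.to_json())
        payload["rfe"] = {
            "chosen_size": self.rfe_result.chosen_size,
            "cv_profile": {str(k): v for k, v in self.rfe_result.cv_profile.items()},
            "selected_mz": self.rfe_result.selected_mz.tolist(),
            "ranking": self.rfe_result.ranking.tolist(),
            "sizes": list(self.rfe_result.sizes),
        }
        payload["cv_report"] = self.cv_report.as_dict()
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# file-level orchestration (CLI backend)
# ---------------------------------------------------------------------------

def _load_cohort(imzml_paths: Sequence[str | Path], metadata_path: str | Path):
    from .io import concat_datasets

    metadata = read_metadata(metadata_path)
    datasets = [read_imzml(p, metadata=metadata) for p in imzml_paths]
    spectra = [s for ds in datasets for s in ds.spectra]
    return MSIDataset(spectra, metadata)


def run_training(
    imzml_paths: Sequence[str | Path],
    metadata_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> MSIClassificationResults:
    """Train from per-patient imzML files + metadata CSV; persist artifacts."""
    config = config or PipelineConfig()
    dataset = _load_cohort(imzml_paths, metadata_path)
    model = MSIClassificationModel.from_dataset(dataset, config)
    results = model.fit(seed=seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.save(out / "model.json")
        write_table(model.peak_matrix, out / "peak_matrix.csv")
        (out / "summary.txt").write_text(results.summary() + "\n")
    return results


def run_validation(
    results_or_model: "MSIClassificationResults | TrainedClassifier",
    imzml_paths: Sequence[str | Path],
    metadata_path: str | Path,
    out_dir: str | Path | None = None,
):
    """Validate a trained model on held-out patients (e.g. THY3 cases)."""
    dataset = _load_cohort(imzml_paths, metadata_path)
    if isinstance(results_or_model, MSIClassificationResults):
        preds, report = results_or_model.validate(dataset)
    else:
        raise TypeError("pass the MSIClassificationResults from run_training")
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(preds, out / "validation_predictions.csv")
        (out / "validation_report.txt").write_text(report.summary() + "\n")
    return preds, report
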