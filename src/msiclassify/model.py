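"""RBF-SVM training, tuning, cross-validation and diagnostic metrics.

The classifier is a soft-margin support vector machine with a radial
basis function kernel, the standard choice for small-n / moderate-p
proteomic feature tables.  The quadratic-programming core is delegated
to scikit-learn's SVC; everything around it — grid tuning by repeated
stratified cross-validation, pooled performance reporting, the
decision-value convention, and JSON (de)serialisation of the trained
state with its preprocessing/alignment provenance — lives here.

Metric semantics: the *positive class is "Ben"* (benign).  Sensitivity
is therefore the ability to detect benignity — the clinically relevant
question for cytologically undetermined (THY3) cases, which would
otherwise all be resected as if malignant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "TrainedClassifier",
    "PerformanceReport",
    "DEFAULT_TUNING_GRID",
    "train_svm",
    "tune_svm",
    "cross_validate",
    "predict",
    "compute_metrics",
]

LABELS = ("Ben", "PTC")


def default_grid(n_features: int | None = None) -> list[tuple[float, float]]:
    """Default (cost, gamma) tuning grid; includes 1/n_features when known."""
    costs = (0.1, 1.0, 10.0, 100.0)
    gammas = [0.01, 0.11, 1.11]
    if n_features:
        gammas.append(1.0 / n_features)
    return [(c, g) for c in costs for g in sorted(set(gammas))]


DEFAULT_TUNING_GRID = default_grid()


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters.

    ``epsilon`` parametrises regression SVMs only; it is recorded for
    fidelity with the original toolchain's tuning tables but has no
    effect on classification.
    """

    kernel: str = "radial"
    cost: float = 10.0
    gamma: float = 0.11
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        if self.kernel != "radial":
            raise ValueError("only the radial (RBF) kernel is supported")
        if not self.cost > 0 or not self.gamma > 0:
            raise ValueError("cost and gamma must be positive")


@dataclass
class PerformanceReport:
    """Diagnostic performance with its 2x2 confusion matrix.

    ``confusion`` rows are true (positive first), columns predicted.
    Ratios with a zero denominator are reported as NaN, never as 0.
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float
    positive_class: str = "Ben"

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }

    def summary(self) -> str:
        tp, fn = self.confusion[0]
        fp, tn = self.confusion[1]
        lines = [
            f"positive class: {self.positive_class}",
            f"confusion  TP={tp} FN={fn} FP={fp} TN={tn}",
        ]
        for k, v in self.as_dict().items():
            lines.append(f"{k:>12s}: {v:.3f}" if math.isfinite(v) else f"{k:>12s}: NA")
        return "\n".join(lines)


def compute_metrics(
    predicted: Sequence[str],
    truth: Sequence[str],
    positive_class: str = "Ben",
    decision_values: Sequence[float] | None = None,
) -> PerformanceReport:
    """Confusion matrix and derived diagnostics.

    AUC is the rank-based (Mann–Whitney) area under the ROC computed
    from ``decision_values`` (oriented so larger means more
    positive-class) when given; from hard labels otherwise, in which
    case it equals ``(sensitivity + specificity) / 2`` exactly.
    """
    predicted = [str(v) for v in predicted]
    truth = [str(v) for v in truth]
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth differ in length")
    bad = sorted(set(predicted) | set(truth) - set(LABELS))
    bad = [b for b in bad if b not in LABELS]
    if bad:
        raise ValueError(f"labels outside vocabulary {LABELS}: {bad}")

    pos = positive_class
    tp = sum(p == pos and t == pos for p, t in zip(predicted, truth))
    fn = sum(p != pos and t == pos for p, t in zip(predicted, truth))
    fp = sum(p == pos and t != pos for p, t in zip(predicted, truth))
    tn = sum(p != pos and t != pos for p, t in zip(predicted, truth))

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    if decision_values is not None:
        d = np.asarray(decision_values, dtype=float)
        t = np.asarray([v == pos for v in truth])
        n_pos, n_neg = int(t.sum()), int((~t).sum())
        if n_pos and n_neg:
            # Mann-Whitney U via midranks (ties contribute 1/2)
            order = np.argsort(d, kind="stable")
            ranks = np.empty(d.size)
            sorted_d = d[order]
            i = 0
            while i < d.size:
                j = i
                while j + 1 < d.size and sorted_d[j + 1] == sorted_d[i]:
                    j += 1
                ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
                i = j + 1
            auc = (ranks[t].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        else:
            auc = float("nan")
    else:
        auc = (sens + spec) / 2

    return PerformanceReport(
        confusion=np.array([[tp, fn], [fp, tn]]),
        accuracy=ratio(tp + tn, tp + tn + fp + fn),
        sensitivity=sens,
        specificity=spec,
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        auc=float(auc),
        positive_class=pos,
    )


@dataclass
class TrainedClassifier:
    """A fitted RBF-SVM plus everything needed to score raw MSI data.

    Decision values are oriented *benign-positive*: ``decision > 0``
    predicts "Ben".  Features are standardised (training mean/SD, the
    convention of R's e1071 ``svm(scale=TRUE)``) before entering the
    kernel; the centring and scaling vectors travel with the model.
    ``provenance`` carries the preprocessing, peak picking and alignment
    parameters and the full reference m/z list so new spectra can be
    conditioned and aligned exactly like the training data.
    """

    selected_mz: np.ndarray
    config: SVMConfig
    support_vectors: np.ndarray  # already standardised
    dual_coef: np.ndarray  # benign-positive orientation
    intercept: float
    x_center: np.ndarray
    x_scale: np.ndarray
    classes: tuple[str, str] = LABELS
    provenance: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.selected_mz.size:
            raise ValueError(
                f"feature dimension {X.shape[1]} != |selected_mz| "
                f"{self.selected_mz.size}; model features: "
                f"{np.round(self.selected_mz, 4).tolist()}"
            )
        X = (X - self.x_center) / self.x_scale
        sq = (
            (X**2).sum(axis=1)[:, None]
            + (self.support_vectors**2).sum(axis=1)[None, :]
            - 2.0 * X @ self.support_vectors.T
        )
        K = np.exp(-self.config.gamma * np.clip(sq, 0.0, None))
        return K @ self.dual_coef + self.intercept

    def predict_labels(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = self.decision_values(X)
        labels = np.where(d > 0, "Ben", "PTC")
        return labels, d

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "format": "msiclassify.TrainedClassifier.v1",
            "selected_mz": self.selected_mz.tolist(),
            "config": {
                "kernel": self.config.kernel,
                "cost": self.config.cost,
                "gamma": self.config.gamma,
                "epsilon": self.config.epsilon,
            },
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "x_center": self.x_center.tolist(),
            "x_scale": self.x_scale.tolist(),
            "classes": list(self.classes),
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedClassifier":
        text = (
            Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists())
            else str(source)
        )
        d = json.loads(text)
        return cls(
            selected_mz=np.asarray(d["selected_mz"], dtype=float),
            config=SVMConfig(**d["config"]),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            x_center=np.asarray(d["x_center"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            classes=tuple(d["classes"]),
            provenance=d.get("provenance", {}),
        )


def train_svm(
    X: np.ndarray,
    y: Sequence[str],
    cfg: SVMConfig | None = None,
    selected_mz: np.ndarray | None = None,
    provenance: dict | None = None,
) -> TrainedClassifier:
    """Fit the soft-margin RBF-SVM at fixed (cost, gamma).

    Deterministic given the input order.  ``y`` must contain both
    classes.
    """
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    # e1071-style feature standardisation (population SD so that exact
    # sample duplication leaves the fit unchanged); constant features
    # pass through unscaled
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Xs = (X - center) / scale
    svc = SVC(kernel="rbf", C=cfg.cost, gamma=cfg.gamma)
    svc.fit(Xs, y)
    # sklearn orients decision_function toward classes_[1] (== "PTC" after
    # lexical sort); flip so positive decisions mean benign.
    flip = -1.0 if tuple(svc.classes_) == ("Ben", "PTC") else 1.0
    if selected_mz is None:
        selected_mz = np.arange(X.shape[1], dtype=float)
    return TrainedClassifier(
        selected_mz=np.asarray(selected_mz, dtype=float),
        config=cfg,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=flip * svc.dual_coef_[0],
        intercept=flip * float(svc.intercept_[0]),
        x_center=center,
        x_scale=scale,
        provenance=provenance or {},
    )


def predict(clf: TrainedClassifier, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (label, decision value); positive decisions mean benign."""
    return clf.predict_labels(X)


def _repeated_cv_predictions(X, y, cfg, k, repeats, seed, max_retries=5):
    """Pooled held-out (predicted, truth, decision) over repeats x k folds."""
    rng = np.random.default_rng(seed)
    preds, truths, decs = [], [], []
    if k == len(y):
        # k = n is leave-one-out; stratification is vacuous there
        for _ in range(repeats):
            for i in range(len(y)):
                tr = np.arange(len(y)) != i
                clf = train_svm(X[tr], y[tr], cfg)
                labels, d = clf.predict_labels(X[i])
                preds.append(labels[0])
                truths.append(y[i])
                decs.append(float(d[0]))
        return preds, truths, decs
    for _ in range(repeats):
        for attempt in range(max_retries):
            state = int(rng.integers(0, 2**31 - 1))
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=state)
            folds = list(splitter.split(X, y))
            if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
                break
        else:
            raise ValueError(
                f"could not stratify {len(y)} samples into {k} folds with "
                "both classes present in every training fold"
            )
        for tr, te in folds:
            clf = train_svm(X[tr], y[tr], cfg)
            labels, d = clf.predict_labels(X[te])
            preds.extend(labels.tolist())
            truths.extend(y[te].tolist())
            decs.extend(d.tolist())
    return preds, truths, decs


def cross_validate(
    X: np.ndarray,
    y: Sequence[str],
    cfg: SVMConfig | None = None,
    k: int = 10,
    repeats: int = 2,
    seed: int = 0,
) -> PerformanceReport:
    """Repeated stratified k-fold CV; metrics pooled over held-out folds."""
    cfg = cfg or SVMConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    if len(y) < k:
        raise ValueError(f"need at least k={k} samples, got {len(y)}")
    preds, truths, decs = _repeated_cv_predictions(X, y, cfg, k, repeats, seed)
    return compute_metrics(preds, truths, decision_values=decs)


def tune_svm(
    X: np.ndarray,
    y: Sequence[str],
    grid: Sequence[tuple[float, float]] | None = None,
    k: int = 10,
    repeats: int = 2,
    seed: int = 0,
    epsilon: float = 0.1,
) -> SVMConfig:
    """Grid-search (cost, gamma) by repeated-CV accuracy.

    All grid points are evaluated on the same seeded folds; ties are
    broken toward the smaller cost, then the smaller gamma.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y])
    if grid is None:
        grid = default_grid(X.shape[1])
    if not len(grid):
        raise ValueError("empty tuning grid")
    best = None
    for cost, gamma in sorted(grid):
        cfg = SVMConfig(cost=float(cost), gamma=float(gamma), epsilon=epsilon)
        preds, truths, _ = _repeated_cv_predictions(X, y, cfg, k, repeats, seed)
        acc = float(np.mean([p == t for p, t in zip(preds, truths)]))
        if best is None or acc > best[0]:
            best = (acc, cfg)
    return best[1]
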