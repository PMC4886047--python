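"""Recursive feature elimination scored by a PLS-DA model.

With ~144 aligned peaks and a few dozen patients, the feature table is
wide and collinear; partial least squares handles that regime natively.
Feature subsets are evaluated wrapper-style: within every training fold
of a repeated stratified k-fold split, features are recursively
eliminated (refit PLS, drop the lowest-|coefficient| features down to
the next candidate size) and each size's held-out accuracy is recorded.
The size with the best mean cross-validated accuracy wins (ties go to
the smaller, more parsimonious subset) and the final subset is obtained
by re-running the elimination on the full training set at that size.

Peak intensities are autoscaled (centred, unit variance — computed on
the training fold only) before every PLS fit: NIPALS weights are
covariances, so without scaling the elimination ranking would be
dominated by high-variance columns rather than by class information,
and |coefficient| would not be the scale-free importance it is meant
to be.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PLSModel",
    "RFEResult",
    "pls_fit",
    "pls_predict",
    "pls_feature_scores",
    "rfe",
    "DEFAULT_SIZES",
    "encode_labels",
    "CLASS_CODE",
]

#: Two-class PLS-DA coding: benign = +1, carcinoma = -1; threshold 0.
CLASS_CODE = {"Ben": 1.0, "PTC": -1.0}

#: Default candidate subset sizes (clipped to the feature count at run time).
DEFAULT_SIZES = (2, 5, 10, 15, 20, 25, 30, 40, 60, 80, 100)


def encode_labels(y) -> np.ndarray:
    """Map Ben/PTC labels to the +1/-1 PLS-DA code."""
    try:
        return np.asarray([CLASS_CODE[str(v)] for v in y], dtype=float)
    except KeyError as exc:
        raise ValueError(f"unknown class label {exc.args[0]!r}") from exc


@dataclass
class PLSModel:
    """A fitted univariate-response PLS regression (NIPALS).

    ``coef`` maps *centred* X to the centred class code; predictions are
    ``(X - x_mean) @ coef + y_mean``.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # p x a
    loadings: np.ndarray     # p x a
    y_loadings: np.ndarray   # a
    scores: np.ndarray       # n x a latent scores (training)
    coef: np.ndarray         # p


def pls_fit(X: np.ndarray, y, n_components: int = 3) -> PLSModel:
    """Fit PLS1 by NIPALS (exact power iteration for univariate y).

    X is mean-centred internally; the centring vector is stored on the
    model.  ``n_components`` is clipped (with a warning) to
    ``min(n_samples - 1, n_features)``.  Deterministic for fixed input.
    """
    X = np.asarray(X, dtype=float)
    ycode = y if np.asarray(y).dtype.kind == "f" else encode_labels(y)
    ycode = np.asarray(ycode, dtype=float)
    if X.ndim != 2 or ycode.shape != (X.shape[0],):
        raise ValueError("X must be 2-D with one y value per row")
    if np.unique(ycode).size < 2:
        raise ValueError("y contains a single class; PLS-DA needs two")
    n, p = X.shape
    max_a = min(n - 1, p)
    if n_components > max_a:
        warnings.warn(
            f"n_components={n_components} clipped to {max_a}", stacklevel=2
        )
        n_components = max_a

    x_mean = X.mean(axis=0)
    y_mean = float(ycode.mean())
    Xc = X - x_mean
    yc = ycode - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    Xr, yr = Xc.copy(), yc.copy()
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm < 1e-14:  # residual carries no covariance with y
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_components = a
            break
        w /= norm
        t = Xr @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
            n_components = a
            break
        pvec = Xr.T @ t / tt
        qa = float(yr @ t / tt)
        Xr = Xr - np.outer(t, pvec)
        yr = yr - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pvec, qa, t
    if n_components == 0:
        raise ValueError("no usable PLS component (X has no covariance with y)")
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_components, x_mean, y_mean, W, P, q, T, coef)


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Continuous class-code predictions for new rows."""
    X = np.asarray(X, dtype=float)
    return (X - model.x_mean) @ model.coef + model.y_mean


def pls_feature_scores(model: PLSModel) -> np.ndarray:
    """Per-feature importance: |regression coefficient| (scale-free rank)."""
    return np.abs(model.coef)


@dataclass
class RFEResult:
    """Outcome of PLS-scored recursive feature elimination.

    ``ranking`` gives each feature's elimination order (1 = eliminated
    first; surviving features share the top rank ``n_features -
    chosen_size + 1``).  ``cv_profile`` maps every candidate size to its
    mean cross-validated accuracy.
    """

    ranking: np.ndarray
    selected_idx: np.ndarray
    selected_mz: np.ndarray
    chosen_size: int
    cv_profile: dict[int, float]
    seed: int
    sizes: tuple[int, ...] = field(default_factory=tuple)


def _eliminate(X, ycode, feat, target_size, mz, n_components, eliminated=None):
    """Recursively drop lowest-score features until ``len(feat) == target_size``.

    Block elimination: one PLS fit per candidate-size step, dropping all
    surplus features at once.  Score ties are broken deterministically by
    m/z (lower m/z dropped first among equals).
    """
    feat = np.asarray(feat)
    while feat.size > target_size:
        model = pls_fit(X[:, feat], ycode, min(n_components, feat.size))
        scores = pls_feature_scores(model)
        order = np.lexsort((mz[feat], scores))  # ascending score, then m/z
        n_drop = feat.size - target_size
        drop_local = order[:n_drop]
        if eliminated is not None:
            # record worst-first so ranking is reproducible
            for j in drop_local[np.argsort(scores[drop_local], kind="stable")]:
                eliminated.append(int(feat[j]))
        keep = np.ones(feat.size, dtype=bool)
        keep[drop_local] = False
        feat = feat[keep]
    return feat


def rfe(
    X: np.ndarray,
    y,
    mz: np.ndarray | None = None,
    sizes=None,
    k: int = 10,
    repeats: int = 2,
    seed: int = 0,
    n_components: int = 3,
) -> RFEResult:
    """PLS-scored recursive feature elimination with repeated k-fold CV.

    Parameters
    ----------
    X : (n_samples, n_features)
        Training peak matrix (patient average profiles).
    y : sequence of {"Ben", "PTC"}
        Histology-backed class labels.
    mz : optional
        Feature labels (reference m/z); defaults to column indices.
    sizes : optional
        Candidate subset sizes; defaults to :data:`DEFAULT_SIZES` plus
        the full feature count, clipped to the data.
    k, repeats, seed
        Stratified cross-validation layout; fully reproducible per seed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = np.asarray([str(v) for v in y])
    ycode = encode_labels(y)
    if mz is None:
        mz = np.arange(p, dtype=float)
    mz = np.asarray(mz, dtype=float)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    if sizes is None:
        sizes = [s for s in DEFAULT_SIZES if s < p] + [p]
    sizes = sorted({int(s) for s in sizes}, reverse=True)
    if sizes[0] > p or sizes[-1] < 1:
        raise ValueError("candidate sizes must lie in [1, n_features]")

    def autoscale(train, test=None):
        mu = train.mean(axis=0)
        sd = train.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        if test is None:
            return (train - mu) / sd
        return (train - mu) / sd, (test - mu) / sd

    rng = np.random.default_rng(seed)
    hits = {s: 0 for s in sizes}
    totals = {s: 0 for s in sizes}
    for _ in range(repeats):
        splitter = StratifiedKFold(
            n_splits=k, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        for train_idx, test_idx in splitter.split(X, y):
            Xtr, Xte = autoscale(X[train_idx], X[test_idx])
            feat = np.arange(p)
            for s in sizes:
                feat = _eliminate(
                    Xtr, ycode[train_idx], feat, s, mz, n_components
                )
                model = pls_fit(
                    Xtr[:, feat], ycode[train_idx],
                    min(n_components, feat.size),
                )
                pred = pls_predict(model, Xte[:, feat])
                pred_code = np.where(pred >= 0, 1.0, -1.0)
                hits[s] += int(np.sum(pred_code == ycode[test_idx]))
                totals[s] += test_idx.size

    cv_profile = {s: hits[s] / totals[s] for s in sizes}
    best = max(cv_profile.values())
    chosen = min(s for s, acc in cv_profile.items() if acc == best)

    eliminated: list[int] = []
    Xfull = autoscale(X)
    feat = np.arange(p)
    for s in sizes:
        if s < chosen:
            break
        feat = _eliminate(Xfull, ycode, feat, s, mz, n_components, eliminated)
    feat = _eliminate(Xfull, ycode, feat, chosen, mz, n_components, eliminated)

    ranking = np.full(p, p - chosen + 1, dtype=int)
    for order, j in enumerate(eliminated, start=1):
        ranking[j] = order
    selected = np.sort(feat)
    return RFEResult(
        ranking=ranking,
        selected_idx=selected,
        selected_mz=mz[selected],
        chosen_size=chosen,
        cv_profile=dict(sorted(cv_profile.items())),
        seed=seed,
        sizes=tuple(sorted(sizes)),
    )
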