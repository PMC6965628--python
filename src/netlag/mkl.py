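"""Multiple kernel learning over electrode x frequency-band features.

Correct-omission (target) vs correct-commission (baseline) trials are
classified from one scalar feature per (electrode, band): the mean
normalized power amplitude 0..1500 ms post-onset.  Each (electrode, band)
contributes one linear kernel (trace-normalized and mean-centered using
training-fold statistics only), and a support-vector machine is trained on
the convex combination K(d) = sum_m d_m K_m with kernel weights d on the
probability simplex.  The weights are learned by alternating SVM solves
with projected-gradient updates of d (SimpleMKL-style reduced gradient on
the dual objective).  Nested, stratified 10-fold cross-validation selects
the soft-margin parameter C from {0.01, 0.1, 1, 10, 100, 1000}; summing
d_m over electrodes within each band, averaged across outer folds, gives
each band's contribution to classification (the contributions sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = ["KernelStack", "MKLModel", "trial_features", "balance_classes",
           "build_kernels", "fit_mkl", "band_contributions"]

C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
FEATURE_WINDOW_MS = (0.0, 1500.0)


@dataclass
class KernelStack:
    """Per-(electrode, band) scalar trial features backing rank-1 kernels."""

    features: np.ndarray           # (n_kernels, n_trials)
    names: list[tuple[str, str]]   # (electrode, band) per kernel
    labels: np.ndarray             # (n_trials,) in {0, 1}; 1 = target
    bands: tuple[str, ...]

    @property
    def n_kernels(self) -> int:
        return self.features.shape[0]

    @property
    def n_trials(self) -> int:
        return self.features.shape[1]

    def full_kernels(self) -> np.ndarray:
        """Centered, trace-normalized kernels over all trials (inspection
        only; model fitting re-centers per training fold)."""
        out = np.empty((self.n_kernels, self.n_trials, self.n_trials))
        for m in range(self.n_kernels):
            f = self.features[m] - self.features[m].mean()
            norm = np.sqrt(np.sum(f ** 2))
            f = f / norm if norm > 0 else f
            out[m] = np.outer(f, f)
        return out


@dataclass
class MKLModel:
    """Fitted nested-CV multiple kernel learning model."""

    fold_weights: np.ndarray       # (n_folds, n_kernels) rows on the simplex
    fold_C: np.ndarray             # chosen C per outer fold
    predictions: np.ndarray        # pooled held-out predictions per trial
    labels: np.ndarray
    balanced_accuracy: float
    class_accuracy: dict[str, float]
    names: list[tuple[str, str]] = field(default_factory=list)
    bands: tuple[str, ...] = ()
    converged: bool = True


# ---------------------------------------------------------------------------
# feature and kernel construction


def trial_features(band_data: np.ndarray, times_ms: np.ndarray,
                   window_ms: tuple[float, float] = FEATURE_WINDOW_MS
                   ) -> np.ndarray:
    """Scalar per-trial feature: mean power in the closed window.

    ``band_data`` is (..., n_trials, n_times) with matching ``times_ms``;
    returns (..., n_trials).
    """
    sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not np.any(sel):
        raise ValueError("feature window contains no samples")
    return np.asarray(band_data)[..., sel].mean(axis=-1)


def balance_classes(labels: np.ndarray, seed: int = 0) -> np.ndarray:
    """Indices of a class-balanced subset (seeded subsample of the majority).

    Emulates random subsampling of the more frequent correct-commission
    trials to match the correct-omission count.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        if len(idx) > n_min:
            idx = np.sort(rng.choice(idx, size=n_min, replace=False))
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def build_kernels(features_by_electrode: dict[str, np.ndarray],
                  bands: tuple[str, ...],
                  labels: np.ndarray, seed: int = 0,
                  balance: bool = True) -> KernelStack:
    """Assemble the kernel stack from per-electrode feature arrays.

    ``features_by_electrode[ch]`` has shape (n_bands, n_trials).  Labels are
    1 for targets (correct omissions) and 0 for baselines.  With
    ``balance=True`` the majority class is subsampled (seeded) first.
    """
    labels = np.asarray(labels).astype(int)
    idx = balance_classes(labels, seed) if balance else np.arange(len(labels))
    feats, names = [], []
    for ch, arr in features_by_electrode.items():
        arr = np.asarray(arr)
        if arr.shape[0] != len(bands):
            raise ValueError(f"electrode {ch}: expected {len(bands)} band rows")
        for bi, band in enumerate(bands):
            feats.append(arr[bi, idx])
            names.append((ch, band))
    return KernelStack(features=np.vstack(feats), names=names,
                       labels=labels[idx], bands=tuple(bands))


# ---------------------------------------------------------------------------
# the MKL solver


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > (css - 1.0))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def _fold_kernels(features: np.ndarray, train: np.ndarray) -> np.ndarray:
    """Center/scale features on the training fold; return (M, n, n) kernels
    over all trials (rank-1, so materialization is cheap)."""
    f = features - features[:, train].mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(f[:, train] ** 2, axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    f = f / norms
    return np.einsum("mi,mj->mij", f, f)


def _solve_mkl(kernels: np.ndarray, y: np.ndarray, train: np.ndarray,
               C: float, max_iter: int = 30, tol: float = 1e-3
               ) -> tuple[np.ndarray, SVC, bool]:
    """Alternating SVM / projected-gradient optimization of kernel weights.

    ``kernels`` is (M, n, n) over all trials; only ``train`` rows/cols are
    used for fitting.  Returns (d, fitted SVC on K(d)[train, train],
    converged flag).
    """
    m = kernels.shape[0]
    ktr = kernels[np.ix_(np.arange(m), train, train)]
    ytr = y[train]
    d = np.full(m, 1.0 / m)
    step = 0.5
    svc = None
    j_prev = np.inf
    converged = False
    for _ in range(max_iter):
        kd = np.tensordot(d, ktr, axes=1)
        svc = SVC(C=C, kernel="precomputed")
        svc.fit(kd, ytr)
        a = np.zeros(len(ytr))
        a[svc.support_] = svc.dual_coef_[0]
        alpha_sum = float(a @ ytr)
        j = alpha_sum - 0.5 * float(a @ kd @ a)
        grad = -0.5 * np.einsum("i,mij,j->m", a, ktr, a)
        if j > j_prev + 1e-10:
            step *= 0.5
        j_prev = j
        scale = np.max(np.abs(grad - grad.mean()))
        if scale <= 0:
            converged = True
            break
        d_new = _project_simplex(d - step * grad / scale)
        if np.abs(d_new - d).sum() < tol:
            d = d_new
            converged = True
            break
        d = d_new
    # final SVM at the converged weights
    kd = np.tensordot(d, ktr, axes=1)
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(kd, ytr)
    return d, svc, converged


def _predict(kernels: np.ndarray, d: np.ndarray, svc: SVC,
             train: np.ndarray, test: np.ndarray) -> np.ndarray:
    kd = np.tensordot(d, kernels, axes=1)
    return svc.predict(kd[np.ix_(test, train)])


def _balanced_acc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = []
    for cls in np.unique(y_true):
        sel = y_true == cls
        accs.append(np.mean(y_pred[sel] == cls))
    return float(np.mean(accs))


def fit_mkl(stack: KernelStack, n_folds: int = 10,
            C_grid: tuple[float, ...] = C_GRID, seed: int = 0,
            inner_folds: int = 5, max_iter: int = 30,
            tol: float = 1e-3) -> MKLModel:
    """Nested stratified cross-validation of the MKL classifier.

    Outer ``n_folds`` folds estimate held-out accuracy; an inner
    ``inner_folds`` CV on each training split picks C (ties to the smaller
    C).  Kernel weights are refit per outer fold on its full training split.
    """
    y = np.asarray(stack.labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("need at least n_folds trials per class")
    outer = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n = len(y)
    preds = np.full(n, -1)
    fold_w = np.empty((n_folds, stack.n_kernels))
    fold_c = np.empty(n_folds)
    fold_acc = []
    all_converged = True
    for fi, (train, test) in enumerate(outer.split(np.zeros(n), y)):
        best_c, best_score = 1.0, -np.inf
        n_inner = int(min(inner_folds, np.bincount(y[train]).min()))
        for c in C_grid if n_inner >= 2 else ():
            inner = StratifiedKFold(n_splits=n_inner, shuffle=True,
                                    random_state=seed + 1)
            scores = []
            for itr, ival in inner.split(np.zeros(len(train)), y[train]):
                tr_idx, va_idx = train[itr], train[ival]
                k_in = _fold_kernels(stack.features, tr_idx)
                d, svc, _ = _solve_mkl(k_in, y, tr_idx, c,
                                       max_iter=max_iter, tol=tol)
                yp = _predict(k_in, d, svc, tr_idx, va_idx)
                scores.append(_balanced_acc(y[va_idx], yp))
            score = float(np.mean(scores))
            if score > best_score + 1e-12:
                best_score, best_c = score, c
        k_out = _fold_kernels(stack.features, train)
        d, svc, conv = _solve_mkl(k_out, y, train, best_c,
                                  max_iter=max_iter, tol=tol)
        all_converged &= conv
        preds[test] = _predict(k_out, d, svc, train, test)
        fold_w[fi] = d
        fold_c[fi] = best_c
        fold_acc.append(_balanced_acc(y[test], preds[test]))
    class_acc = {}
    for cls, label in zip(classes, ("baseline", "target")):
        sel = y == cls
        class_acc[label] = float(np.mean(preds[sel] == cls))
    return MKLModel(fold_weights=fold_w, fold_C=fold_c, predictions=preds,
                    labels=y, balanced_accuracy=float(np.mean(fold_acc)),
                    class_accuracy=class_acc, names=list(stack.names),
                    bands=stack.bands, converged=all_converged)


def band_contributions(model: MKLModel) -> dict[str, float]:
    """Per-band contribution: mean over folds of the summed kernel weights
    of that band's electrodes.  Contributions sum to 1."""
    out = {}
    for band in model.bands:
        cols = [i for i, (_, b) in enumerate(model.names) if b == band]
        out[band] = float(model.fold_weights[:, cols].sum(axis=1).mean())
    return out
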