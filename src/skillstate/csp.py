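"""Microstate-conditioned regularized common spatial patterns (CSP) with
LDA classification.

For two classes with scatter matrices ``C1`` (expert) and ``C2`` (novice),
the discriminative spatial filters are the eigenvectors of the regularized
problems::

    M1 = (C2 + alpha K)^-1 C1      M2 = (C1 + alpha K)^-1 C2

with ``K`` the identity.  Filters maximize the variance ratio between the
classes (eigenvalue = ratio of class-1 to regularized class-2 variance of
the projection).  Features are log-variances of the projections on the
leading filters of each problem; classification is a linear discriminant.
Conditioning the scatter estimation on the samples of a single microstate
(the state active at task onset) is what turns plain CSP into the
microstate-based variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .evaluate import ClassifierReport, confusion, kappa, metrics
from .io import ValidationError
from .microstate import MicrostateModel, Segmentation, gfp

__all__ = [
    "CSPModel",
    "LDAModel",
    "class_scatter",
    "microstate_condition",
    "fit_regularized_csp",
    "default_alpha",
    "csp_features",
    "lda_fit",
    "lda_predict",
    "crossvalidate_csp_lda",
    "kappa",
]


@dataclass
class CSPModel:
    """Fitted regularized CSP: both eigenproblems' filters and patterns."""

    C1: np.ndarray
    C2: np.ndarray
    alpha: float
    filters1: np.ndarray   # columns: eigenvectors of (C2+aI)^-1 C1, desc
    filters2: np.ndarray   # columns: eigenvectors of (C1+aI)^-1 C2, desc
    patterns1: np.ndarray  # corresponding scalp patterns (columns)
    patterns2: np.ndarray
    eigvals1: np.ndarray
    eigvals2: np.ndarray
    n_pairs: int = 1

    @property
    def n_channels(self) -> int:
        return self.C1.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in (
                "C1", "C2", "filters1", "filters2",
                "patterns1", "patterns2", "eigvals1", "eigvals2",
            ):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["alpha"] = self.alpha
            f.attrs["n_pairs"] = self.n_pairs

    @classmethod
    def load(cls, path) -> "CSPModel":
        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][()]
                for name in (
                    "C1", "C2", "filters1", "filters2",
                    "patterns1", "patterns2", "eigvals1", "eigvals2",
                )
            }
            return cls(
                alpha=float(f.attrs["alpha"]),
                n_pairs=int(f.attrs["n_pairs"]),
                **kw,
            )


def _as_epoch_list(epochs) -> list[np.ndarray]:
    if isinstance(epochs, np.ndarray) and epochs.ndim == 3:
        return [epochs[i] for i in range(epochs.shape[0])]
    return [np.asarray(e, float) for e in epochs]


def class_scatter(epochs, trace_normalize: bool = False) -> np.ndarray:
    """Sum over epochs of X^T X (optionally per-epoch trace-normalized)."""
    eps = _as_epoch_list(epochs)
    if not eps:
        raise ValidationError("no epochs")
    n_ch = eps[0].shape[1]
    S = np.zeros((n_ch, n_ch))
    for X in eps:
        scatter = X.T @ X
        if trace_normalize:
            tr = np.trace(scatter)
            if tr > 0:
                scatter = scatter / tr
        S += scatter
    return S


def microstate_condition(
    epochs,
    segmentations: list[Segmentation],
    state: int | str = "auto",
    gfp_weighting: bool = False,
) -> list[np.ndarray]:
    """Retain only the samples labelled ``state`` in each epoch.

    ``state="auto"`` uses the first active state of each epoch (the
    microstate at task onset); ``state="modal"`` uses the epoch's most
    frequent state, which reads the same intent robustly when the first
    few samples are noisy.  With ``gfp_weighting`` the retained samples
    are scaled by their GFP, emphasizing high-signal topographies.
    """
    eps = _as_epoch_list(epochs)
    if len(eps) != len(segmentations):
        raise ValidationError("one segmentation per epoch required")
    out = []
    for X, seg in zip(eps, segmentations):
        labels = np.asarray(seg.labels)
        if labels.shape[0] != X.shape[0]:
            raise ValidationError("segmentation does not cover the epoch")
        if state == "auto":
            target = int(labels[0])
        elif state == "modal":
            target = int(np.bincount(labels[labels >= 0]).argmax())
        else:
            target = int(state)
        mask = labels == target
        if not mask.any():
            raise ValidationError(
                f"state {target} never occurs in epoch"
            )
        sel = X[mask]
        if gfp_weighting:
            sel = sel * gfp(sel)[:, None]
        out.append(sel)
    return out


def default_alpha(C2: np.ndarray) -> float:
    """Regularization weight 0.1 * mean eigenvalue of the denominator."""
    return 0.1 * float(np.trace(C2)) / C2.shape[0]


def _eig_sorted(Cnum: np.ndarray, Cden: np.ndarray):
    vals, vecs = scipy.linalg.eigh(Cnum, Cden)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    # unit-norm filters, sign fixed by the largest-magnitude entry
    vecs = vecs / np.linalg.norm(vecs, axis=0, keepdims=True)
    signs = np.sign(vecs[np.abs(vecs).argmax(axis=0), np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    if np.iscomplexobj(vecs):
        if np.abs(vecs.imag).max() > 1e-8:
            raise ValidationError("complex-valued spatial filters")
        vecs = vecs.real
    return vals, vecs


def fit_regularized_csp(
    C1: np.ndarray, C2: np.ndarray, alpha: float | None = None, n_pairs: int = 1
) -> CSPModel:
    """Solve both regularized CSP eigenproblems.

    ``alpha=None`` uses :func:`default_alpha`.  The filters of each
    problem are sorted by decreasing eigenvalue; the leading one of each
    is the discriminative pattern pair.
    """
    C1 = np.asarray(C1, float)
    C2 = np.asarray(C2, float)
    for name, C in (("C1", C1), ("C2", C2)):
        if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-9):
            raise ValidationError(f"{name} must be symmetric")
    if alpha is None:
        alpha = default_alpha(C2)
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    I = np.eye(C1.shape[0])
    try:
        vals1, vecs1 = _eig_sorted(C1, C2 + alpha * I)
        vals2, vecs2 = _eig_sorted(C2, C1 + alpha * I)
    except scipy.linalg.LinAlgError as exc:
        raise ValidationError(
            f"singular denominator covariance ({exc}); use alpha > 0"
        ) from exc
    patterns1 = (C2 + alpha * I) @ vecs1
    patterns2 = (C1 + alpha * I) @ vecs2
    return CSPModel(
        C1, C2, float(alpha), vecs1, vecs2, patterns1, patterns2,
        vals1, vals2, n_pairs,
    )


def csp_features(epoch: np.ndarray, model: CSPModel, n_pairs: int | None = None
                 ) -> np.ndarray:
    """Log-variance of the epoch projected on the top filters of each
    eigenproblem (2 * n_pairs features)."""
    n_pairs = model.n_pairs if n_pairs is None else n_pairs
    X = np.asarray(epoch, float)
    feats = []
    for W in (model.filters1, model.filters2):
        proj = X @ W[:, :n_pairs]
        feats.append(np.log(proj.var(axis=0, ddof=0) + 1e-300))
    return np.concatenate(feats)


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    priors: np.ndarray
    shrinkage: float | str | None
    classes: np.ndarray
    _sk: LinearDiscriminantAnalysis | None = None


def lda_fit(features: np.ndarray, labels, shrinkage=None) -> LDAModel:
    """Fisher linear discriminant with optional pooled-covariance shrinkage."""
    X = np.asarray(features, float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("need two classes to fit an LDA")
    if shrinkage is None:
        clf = LinearDiscriminantAnalysis(solver="svd")
    else:
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    clf.fit(X, y)
    return LDAModel(
        weights=clf.coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        priors=clf.priors_.copy(),
        shrinkage=shrinkage,
        classes=clf.classes_.copy(),
        _sk=clf,
    )


def lda_predict(model: LDAModel, features: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(features, float))
    scores = X @ model.weights + model.bias
    return model.classes[(scores > 0).astype(int)]


# --------------------------------------------------------------------------
# cross-validated pipeline
# --------------------------------------------------------------------------

def crossvalidate_csp_lda(
    epochs,
    labels,
    folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    n_pairs: int = 1,
    shrinkage=None,
    positive: str = "expert",
) -> ClassifierReport:
    """K-fold cross-validation with CSP and LDA re-fit inside every
    training fold (no leakage); fold predictions are pooled into one
    report.  Pass microstate-conditioned epochs to get the
    microstate-based variant.
    """
    eps = _as_epoch_list(epochs)
    y = np.asarray([str(l) for l in labels])
    if len(eps) != len(y):
        raise ValidationError("one label per epoch required")
    if folds > len(eps):
        raise ValidationError(f"folds={folds} exceeds {len(eps)} epochs")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError("exactly two classes required")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValidationError(
            f"need >= {folds} epochs per class, got {counts}"
        )
    neg = [c for c in classes if c != positive][0]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true, y_pred = [], []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        S1 = class_scatter([eps[i] for i in train_idx if y[i] == positive])
        S2 = class_scatter([eps[i] for i in train_idx if y[i] == neg])
        model = fit_regularized_csp(S1, S2, alpha, n_pairs)
        F_train = np.array([csp_features(eps[i], model) for i in train_idx])
        lda = lda_fit(F_train, y[train_idx], shrinkage)
        F_test = np.array([csp_features(eps[i], model) for i in test_idx])
        y_true.extend(y[test_idx])
        y_pred.extend(lda_predict(lda, F_test))
    return metrics(confusion(y_true, y_pred, positive))
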