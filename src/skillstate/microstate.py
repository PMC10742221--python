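"""EEG microstate analysis: polarity-invariant modified K-means prototype
clustering, model selection by global explained variance (GEV) and the
cross-validation (CV) criterion, and backfitting with temporal smoothing.

A microstate prototype is a unit-norm, zero-mean (average-referenced) scalp
map.  Similarity between a sample map ``x`` and prototype ``a`` is the
squared spatial Pearson correlation — the sign of the map is ignored, so a
prototype and its negation describe the same state.  Global field power
(GFP) is the per-sample population standard deviation across channels;
GFP peaks mark the high-signal-to-noise topographies used for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import scipy.signal

from .io import ValidationError

__all__ = [
    "MicrostateModel",
    "Segmentation",
    "gfp",
    "pick_gfp_peaks",
    "modified_kmeans",
    "gev",
    "cv_criterion",
    "select_model",
    "backfit",
]


@dataclass
class MicrostateModel:
    """K prototype topographies with their goodness-of-fit summaries."""

    prototypes: np.ndarray        # (K, n_channels), unit-norm, zero-mean
    gev_total: float
    gev_per_state: np.ndarray     # (K,), sums to gev_total
    cv: float
    sorted: bool = False

    @property
    def K(self) -> int:
        return self.prototypes.shape[0]

    @property
    def n_channels(self) -> int:
        return self.prototypes.shape[1]

    def sort_by_gev(self) -> "MicrostateModel":
        order = np.argsort(self.gev_per_state)[::-1]
        return MicrostateModel(
            self.prototypes[order],
            self.gev_total,
            self.gev_per_state[order],
            self.cv,
            sorted=True,
        )

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("prototypes", data=self.prototypes)
            f.create_dataset("gev", data=self.gev_per_state)
            f.attrs["gev_total"] = self.gev_total
            f.attrs["cv"] = self.cv
            f.attrs["sorted"] = self.sorted

    @classmethod
    def load(cls, path) -> "MicrostateModel":
        with h5py.File(path, "r") as f:
            return cls(
                f["prototypes"][()],
                float(f.attrs["gev_total"]),
                f["gev"][()],
                float(f.attrs["cv"]),
                bool(f.attrs["sorted"]),
            )


@dataclass
class Segmentation:
    """Per-sample microstate labels (polarity recorded separately)."""

    labels: np.ndarray            # (T,), int, -1 = unassigned
    polarity: np.ndarray          # (T,), sign of the spatial projection
    smoothing: dict | None = None


# --------------------------------------------------------------------------
# GFP and peak picking
# --------------------------------------------------------------------------

def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: per-sample population SD across channels."""
    data = np.atleast_2d(np.asarray(data, float))
    return data.std(axis=1, ddof=0)


def pick_gfp_peaks(
    gfp_series: np.ndarray,
    fs: float,
    min_distance_ms: float = 10.0,
    n_peaks: int = 1000,
    reject_sd: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Indices of GFP local maxima used for clustering.

    Peaks closer than ``min_distance_ms`` keep only the larger; peaks whose
    GFP exceeds ``mean + reject_sd * SD`` of the peak GFPs are rejected as
    likely artifacts; at most ``n_peaks`` survive by seeded subsampling.
    """
    g = np.asarray(gfp_series, float)
    distance = max(1, int(round(min_distance_ms * 1e-3 * fs)))
    peaks, _ = scipy.signal.find_peaks(g, distance=distance)
    if peaks.size == 0:
        raise ValidationError("no GFP peaks found")
    vals = g[peaks]
    thresh = vals.mean() + reject_sd * vals.std(ddof=0)
    peaks = peaks[vals <= thresh]
    if peaks.size == 0:
        raise ValidationError("all GFP peaks rejected by the SD criterion")
    if peaks.size > n_peaks:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        peaks = np.sort(rng.choice(peaks, size=n_peaks, replace=False))
    return peaks


# --------------------------------------------------------------------------
# modified K-means
# --------------------------------------------------------------------------

def _normalize_maps(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


def _kpp_seed(Xn: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ style seeding with the polarity-invariant distance
    d(x, a) = 2 - 2|x . a| (squared Euclidean after optimal sign flip)."""
    n = Xn.shape[0]
    idx = [int(rng.integers(n))]
    for _ in range(1, K):
        A = Xn[idx]
        d = 2 - 2 * np.abs(Xn @ A.T).max(axis=1)
        d = np.clip(d, 0, None)
        total = d.sum()
        if total <= 0:
            idx.append(int(rng.integers(n)))
        else:
            idx.append(int(rng.choice(n, p=d / total)))
    return Xn[idx].copy()


def _fit_once(
    Xn: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    A = _kpp_seed(Xn, K, rng)
    prev_sigma = np.inf
    labels = np.zeros(len(Xn), dtype=int)
    for _ in range(max_iter):
        proj = Xn @ A.T
        labels = np.argmax(proj**2, axis=1)
        for k in range(K):
            members = Xn[labels == k]
            if len(members) == 0:
                # re-seed an empty state at the worst-fit map
                worst = np.argmin(np.max((Xn @ A.T) ** 2, axis=1))
                A[k] = Xn[worst]
                continue
            S = members.T @ members
            w, v = np.linalg.eigh(S)
            a = v[:, -1]
            a = a - a.mean()
            A[k] = a / np.linalg.norm(a)
        best = np.take_along_axis(Xn @ A.T, labels[:, None], axis=1)[:, 0]
        sigma = 1.0 - float(np.mean(best**2))
        if abs(prev_sigma - sigma) <= tol * max(prev_sigma, 1e-300):
            break
        prev_sigma = sigma
    return A, labels


def modified_kmeans(
    maps: np.ndarray,
    K: int,
    n_init: int = 100,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
) -> MicrostateModel:
    """Polarity-invariant modified K-means on (n_maps, n_channels) data.

    Each state's prototype is the dominant eigenvector of its members'
    outer-product sum; assignment maximizes squared spatial correlation.
    The best of ``n_init`` k-means++-seeded runs by GEV is returned,
    deterministic under a fixed seed.
    """
    X = np.atleast_2d(np.asarray(maps, float))
    if K > X.shape[0]:
        raise ValidationError(f"K={K} exceeds {X.shape[0]} maps")
    Xn = _normalize_maps(X)
    Xc = X - X.mean(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_init):
        A, labels = _fit_once(Xn, K, rng, max_iter, tol)
        g = gev(Xc, A, labels)
        if best is None or g > best[0]:
            best = (g, A, labels)
    g_total, A, labels = best
    g_states = gev_per_state(Xc, A, labels)
    cv = cv_criterion(Xc, A, labels)
    model = MicrostateModel(A, g_total, g_states, cv)
    return model.sort_by_gev()


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

def _prototypes_of(model) -> np.ndarray:
    return model.prototypes if isinstance(model, MicrostateModel) else np.asarray(model)


def _gev_terms(data: np.ndarray, A: np.ndarray, labels: np.ndarray):
    X = np.asarray(data, float)
    X = X - X.mean(axis=1, keepdims=True)
    g = X.std(axis=1, ddof=0)
    Xn = _normalize_maps(X)
    labels = np.asarray(labels)
    valid = labels >= 0
    corr = np.zeros(len(X))
    corr[valid] = np.take_along_axis(
        Xn[valid] @ A.T, labels[valid][:, None], axis=1
    )[:, 0]
    num = (g * corr) ** 2 * valid
    den = float((g**2).sum())
    return num, den, labels, valid


def gev(data: np.ndarray, model, labels: np.ndarray) -> float:
    """Global explained variance of a labelled segmentation, in [0, 1].

    GEV = sum_t (GFP_t * corr(x_t, a_{L_t}))^2 / sum_t GFP_t^2 with the
    polarity-invariant squared spatial correlation.
    """
    A = _prototypes_of(model)
    num, den, _, _ = _gev_terms(data, A, labels)
    return float(num.sum() / den) if den > 0 else 0.0


def gev_per_state(data: np.ndarray, model, labels: np.ndarray) -> np.ndarray:
    A = _prototypes_of(model)
    num, den, labels, valid = _gev_terms(data, A, labels)
    out = np.zeros(A.shape[0])
    for k in range(A.shape[0]):
        out[k] = num[(labels == k) & valid].sum() / den if den > 0 else 0.0
    return out


def cv_criterion(data: np.ndarray, model, labels: np.ndarray | None = None) -> float:
    """Predictive residual variance with the small-sample correction
    ((C-1)/(C-1-K))^2; its minimum over K marks the best model."""
    A = _prototypes_of(model)
    X = np.asarray(data, float)
    X = X - X.mean(axis=1, keepdims=True)
    if labels is None:
        labels = np.argmax((_normalize_maps(X) @ A.T) ** 2, axis=1)
    C = X.shape[1]
    K = A.shape[0]
    if C - 1 - K <= 0:
        return np.inf
    proj = np.take_along_axis(X @ A.T, np.asarray(labels)[:, None], axis=1)[:, 0]
    sigma2 = float(np.mean((X**2).sum(axis=1) - proj**2)) / (C - 1)
    return sigma2 * ((C - 1) / (C - 1 - K)) ** 2


def select_model(
    data: np.ndarray,
    fs: float,
    K_range=range(2, 9),
    n_init: int = 20,
    max_iter: int = 1000,
    tol: float = 1e-6,
    seed: int = 0,
    peak_kwargs: dict | None = None,
) -> MicrostateModel:
    """Fit every K in ``K_range`` on GFP-peak maps and return the
    CV-minimizing model (prototypes sorted by decreasing GEV)."""
    Ks = list(K_range)
    if not Ks:
        raise ValidationError("empty K range")
    X = np.asarray(data, float)
    peaks = pick_gfp_peaks(gfp(X), fs, seed=seed, **(peak_kwargs or {}))
    peak_maps = X[peaks]
    best = None
    for K in Ks:
        m = modified_kmeans(peak_maps, K, n_init, max_iter, tol, seed)
        cv_full = cv_criterion(X, m)
        m.cv = cv_full
        if best is None or cv_full < best.cv:
            best = m
    return best


# --------------------------------------------------------------------------
# backfitting
# --------------------------------------------------------------------------

def backfit(
    epoch: np.ndarray,
    model: MicrostateModel | np.ndarray,
    smooth: dict | None = None,
    fs: float | None = None,
) -> Segmentation:
    """Label every sample with its best-correlated prototype.

    With ``smooth={"window_ms": w}`` (requires ``fs``), contiguous runs
    shorter than ``w`` are re-assigned to the better-correlated
    neighbouring state (small-segment rejection), iterated to a fixed
    point.
    """
    A = _prototypes_of(model)
    X = np.asarray(epoch, float)
    if X.shape[1] != A.shape[1]:
        raise ValidationError(
            f"epoch has {X.shape[1]} channels, model {A.shape[1]}"
        )
    Xn = _normalize_maps(X)
    proj = Xn @ A.T
    labels = np.argmax(proj**2, axis=1)
    polarity = np.sign(
        np.take_along_axis(proj, labels[:, None], axis=1)[:, 0]
    ).astype(int)
    if smooth:
        if fs is None:
            raise ValidationError("fs required for temporal smoothing")
        min_len = max(1, int(round(smooth.get("window_ms", 30) * 1e-3 * fs)))
        labels = _reject_small_segments(labels, proj**2, min_len)
        polarity = np.sign(
            np.take_along_axis(proj, labels[:, None], axis=1)[:, 0]
        ).astype(int)
    return Segmentation(labels, polarity, smoothing=smooth)


def _segments(labels: np.ndarray):
    edges = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(labels)]])
    return list(zip(starts, ends))


def _reject_small_segments(
    labels: np.ndarray, sim: np.ndarray, min_len: int, max_pass: int = 100
) -> np.ndarray:
    """EEGLab-style small-segment rejection on a (T,) label sequence.

    Repeatedly reassigns the shortest sub-threshold run to whichever
    neighbouring state fits its samples better (mean squared correlation),
    until all runs reach ``min_len`` or only one run remains.
    """
    labels = labels.copy()
    for _ in range(max_pass):
        segs = _segments(labels)
        if len(segs) <= 1:
            break
        short = [
            (e - s, i) for i, (s, e) in enumerate(segs) if (e - s) < min_len
        ]
        if not short:
            break
        _, i = min(short)
        s, e = segs[i]
        candidates = []
        if i > 0:
            candidates.append(labels[segs[i - 1][0]])
        if i < len(segs) - 1:
            candidates.append(labels[segs[i + 1][0]])
        scores = [sim[s:e, c].mean() for c in candidates]
        labels[s:e] = candidates[int(np.argmax(scores))]
    return labels
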