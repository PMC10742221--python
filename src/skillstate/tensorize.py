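"""Topography-preserving tensorization of multichannel EEG.

Each 3-second window of 120 Hz EEG becomes a 16 x 16 x 360 tensor: the
montage is flattened by an azimuthal equidistant projection centred at the
vertex (radial grid distance proportional to polar angle, azimuth
preserved), and each time sample's channel vector is spread over the grid
by biharmonic (Green's-function) scattered-data interpolation — exact at
the electrode coordinates.  Grid cells outside the electrodes' convex hull
are zero-filled, since the biharmonic interpolant diverges when
extrapolated toward the grid corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.spatial import Delaunay

from .io import Montage, ValidationError

__all__ = [
    "GridProjection",
    "EEGTensorDataset",
    "project_montage",
    "biharmonic_kernel",
    "interpolate_frame",
    "window_segments",
    "build_dataset",
]

TENSOR_FS = 120.0
WINDOW_S = 3.0
STEP_S = 1.0
PRE_TRIGGER_S = 2.0


@dataclass
class GridProjection:
    """Electrode coordinates on the image grid plus the interpolation
    operator mapping channel vectors to in-hull grid cells."""

    coords: np.ndarray      # (n_channels, 2) continuous (row, col)
    grid: int
    mask: np.ndarray        # (grid, grid) bool, inside electrode hull
    _operator: np.ndarray = field(repr=False, default=None)  # (cells, n_ch)

    def interpolate(self, values: np.ndarray) -> np.ndarray:
        """One 16x16 frame (or a stack) from channel values.

        ``values`` may be (n_channels,) or (n_samples, n_channels); the
        result is (grid, grid) or (n_samples, grid, grid).
        """
        v = np.asarray(values, float)
        single = v.ndim == 1
        flat = self._operator @ np.atleast_2d(v).T  # (cells, n_samples)
        out = np.zeros((self.grid, self.grid, flat.shape[1]))
        out[self.mask] = flat
        out = np.moveaxis(out, -1, 0)
        return out[0] if single else out

    def evaluate_at(self, points: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Evaluate the interpolant at arbitrary (row, col) points."""
        op = _biharmonic_operator(self.coords, np.atleast_2d(points))
        return op @ np.asarray(values, float)


def biharmonic_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Green's function of the 2-D biharmonic operator between point sets:
    G(r) = r^2 (log r - 1), with G(0) = 0."""
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    r = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * (np.log(r[nz]) - 1.0)
    return out


def _biharmonic_operator(coords: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Dense linear map from electrode values to interpolant values.

    Collocation on the biharmonic Green's function augmented with a
    constant term (so spatially uniform fields are reproduced exactly
    everywhere, and all data exactly at the nodes)::

        [[G, 1], [1^T, 0]] [w; a] = [v; 0],  f(x) = sum_j w_j G(|x-x_j|) + a
    """
    n = coords.shape[0]
    G = biharmonic_kernel(coords, coords)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"degenerate electrode layout: {exc}") from exc
    K = np.column_stack([biharmonic_kernel(targets, coords),
                         np.ones(targets.shape[0])])
    return K @ Ainv[:, :n]


def project_montage(
    montage: Montage, grid: int = 16, margin: float = 1.0
) -> GridProjection:
    """Azimuthal equidistant projection of the montage onto the grid.

    The projection is centred at the vertex (0, 0, 1): radial distance on
    the plane equals the polar angle, azimuth is preserved, and the layout
    is scaled isotropically to fit the grid with a one-cell margin.
    Anterior electrodes map to low row indices; left-hemisphere electrodes
    to low column indices.
    """
    pos = montage.positions
    z = np.clip(pos[:, 2], -1.0, 1.0)
    theta = np.arccos(z)
    if np.any(theta > np.pi - 1e-6):
        raise ValidationError("electrode at the antipode of the projection centre")
    azim = np.arctan2(pos[:, 1], pos[:, 0])
    x2d = theta * np.cos(azim)   # +x: right
    y2d = theta * np.sin(azim)   # +y: anterior
    rmax = float(np.sqrt(x2d**2 + y2d**2).max())
    if rmax == 0:
        rmax = 1.0
    half = (grid - 1) / 2 - margin
    scale = half / rmax
    centre = (grid - 1) / 2
    rows = centre - scale * y2d
    cols = centre + scale * x2d
    coords = np.column_stack([rows, cols])

    # injectivity on the rounded grid
    cells = {tuple(np.round(c).astype(int)) for c in coords}
    if len(cells) != len(coords):
        raise ValidationError("two electrodes share a rounded grid cell")

    rr, cc = np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    hull = Delaunay(coords)
    mask = (hull.find_simplex(pts) >= 0).reshape(grid, grid)

    if len({tuple(c) for c in np.round(coords, 9)}) < len(coords):
        raise ValidationError("duplicate electrode coordinates")
    operator = _biharmonic_operator(coords, pts[mask.ravel()])
    return GridProjection(coords, grid, mask, operator)


def interpolate_frame(values: np.ndarray, proj: GridProjection) -> np.ndarray:
    """Biharmonic-spline interpolation of one channel vector to the grid."""
    v = np.asarray(values, float)
    if v.shape[-1] != proj.coords.shape[0]:
        raise ValidationError("channel count does not match projection")
    return proj.interpolate(v)


def window_segments(
    epoch: np.ndarray,
    fs: float = TENSOR_FS,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> list[np.ndarray]:
    """Maximal list of full sliding windows (3 s / 1 s step by default).

    A span of S seconds yields floor(S - window) / step + 1 windows; an
    epoch shorter than one window yields an empty list.
    """
    X = np.asarray(epoch, float)
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if X.shape[0] < win:
        import warnings

        warnings.warn("epoch shorter than one window; no segments")
        return []
    starts = range(0, X.shape[0] - win + 1, step)
    return [X[s : s + win] for s in starts]


@dataclass
class EEGTensorDataset:
    """N tensors of shape (grid, grid, depth) with cohort annotations."""

    tensors: np.ndarray          # (N, 16, 16, 360)
    labels: np.ndarray           # "expert" / "novice"
    subject: np.ndarray
    trial: np.ndarray
    window: np.ndarray
    fs: float = TENSOR_FS

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=np.float32)
        self.labels = np.asarray(self.labels)
        if self.tensors.ndim != 4:
            raise ValidationError("tensors must be (N, h, w, depth)")
        if not set(np.unique(self.labels)) <= {"expert", "novice"}:
            if len(self.labels):
                raise ValidationError("labels must be expert/novice")
        if np.isnan(self.tensors).any():
            raise ValidationError("NaN in tensor data")

    def __len__(self) -> int:
        return self.tensors.shape[0]

    @property
    def y(self) -> np.ndarray:
        """Integer targets: expert (positive) = 1, novice = 0."""
        return (self.labels == "expert").astype(int)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("tensors", data=self.tensors)
            f.create_dataset(
                "labels", data=np.char.encode(self.labels.astype(str))
            )
            f.create_dataset(
                "subject", data=np.char.encode(self.subject.astype(str))
            )
            f.create_dataset("trial", data=np.asarray(self.trial, int))
            f.create_dataset("window", data=np.asarray(self.window, int))
            f.attrs["fs"] = self.fs

    @classmethod
    def load(cls, path) -> "EEGTensorDataset":
        with h5py.File(path, "r") as f:
            return cls(
                f["tensors"][()],
                np.char.decode(f["labels"][()]),
                np.char.decode(f["subject"][()]),
                f["trial"][()],
                f["window"][()],
                float(f.attrs["fs"]),
            )

    def subset(self, idx) -> "EEGTensorDataset":
        idx = np.asarray(idx)
        return EEGTensorDataset(
            self.tensors[idx], self.labels[idx], self.subject[idx],
            self.trial[idx], self.window[idx], self.fs,
        )


def build_dataset(
    cohort_epochs: list[tuple[str, str, int, np.ndarray]],
    montage: Montage,
    grid: int = 16,
    fs: float = TENSOR_FS,
    window_s: float = WINDOW_S,
    step_s: float = STEP_S,
) -> EEGTensorDataset:
    """Tensorize a cohort of task epochs.

    ``cohort_epochs`` holds (subject, group, trial, epoch) tuples where
    each epoch is a (n_samples, n_channels) matrix already at the tensor
    sampling rate (120 Hz) spanning from 2 s before the task trigger.
    """
    proj = project_montage(montage, grid)
    tensors, labels, subjects, trials, windows = [], [], [], [], []
    for subject, group, trial, epoch in cohort_epochs:
        for w_idx, seg in enumerate(
            window_segments(epoch, fs, window_s, step_s)
        ):
            frames = proj.interpolate(seg)          # (depth, grid, grid)
            tensors.append(np.moveaxis(frames, 0, -1))
            labels.append(group)
            subjects.append(subject)
            trials.append(trial)
            windows.append(w_idx)
    depth = int(round(window_s * fs))
    if not tensors:
        return EEGTensorDataset(
            np.zeros((0, grid, grid, depth), dtype=np.float32),
            np.array([], dtype=str), np.array([], dtype=str),
            np.array([], dtype=int), np.array([], dtype=int), fs,
        )
    return EEGTensorDataset(
        np.array(tensors, dtype=np.float32),
        np.array(labels), np.array(subjects),
        np.array(trials), np.array(windows), fs,
    )
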