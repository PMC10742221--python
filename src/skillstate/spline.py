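"""Spherical-spline machinery shared by channel interpolation and the
surface Laplacian (current source density).

Implements the classic spherical-spline model of the scalp potential: the
potential at a point ``x`` on the unit sphere is

    v(x) = c0 + sum_i c_i g(cos(x, x_i))

with the spline kernel

    g(t) = 1/(4 pi) sum_{n=1}^{N} (2n+1) / (n (n+1))^m  P_n(t)

(Legendre polynomials ``P_n``, stiffness order ``m``).  The coefficients
solve a regularized collocation system under the charge-neutrality
constraint ``sum_i c_i = 0``.  Because the Laplace–Beltrami operator has
the spherical harmonics as eigenfunctions (eigenvalue ``-n(n+1)``), the
surface Laplacian of the fitted potential is available in closed form via
the companion kernel with exponent ``m - 1``.  The CSD sign convention is
used: the returned Laplacian is ``-lap(v)`` scaled by ``1/r^2``, so a
degree-n harmonic topography maps to ``+n(n+1)`` times itself on the unit
sphere.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre

__all__ = [
    "spline_kernel",
    "interpolation_matrix",
    "laplacian_matrix",
]

DEFAULT_ORDER = 4          # Perrin's m
DEFAULT_REG = 1e-5         # ridge added to the collocation diagonal
DEFAULT_TERMS = 50         # Legendre series truncation


def spline_kernel(
    cosang: np.ndarray, order: int = DEFAULT_ORDER, n_terms: int = DEFAULT_TERMS
) -> np.ndarray:
    """Evaluate g(t) (or h(t) with ``order=m-1``) on cosine-angle values."""
    t = np.clip(np.asarray(cosang, dtype=float), -1.0, 1.0)
    out = np.zeros_like(t)
    for n in range(1, n_terms + 1):
        out += (2 * n + 1) / (n * (n + 1)) ** order * eval_legendre(n, t)
    return out / (4 * np.pi)


def _solve_coefficients(
    pos_from: np.ndarray, order: int, reg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (Ginv-like solve operator pieces) for the constrained system.

    Solves ``[ [G + reg I, 1], [1^T, 0] ] [c; c0] = [v; 0]`` for arbitrary
    right-hand sides; returns the full inverse of the bordered matrix.
    """
    n = pos_from.shape[0]
    G = spline_kernel(pos_from @ pos_from.T, order=order)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + reg * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    Ainv = np.linalg.inv(A)
    return Ainv[:n, :n], Ainv[n, :n]  # map v -> c, v -> c0


def interpolation_matrix(
    pos_from: np.ndarray,
    pos_to: np.ndarray,
    order: int = DEFAULT_ORDER,
    reg: float = DEFAULT_REG,
) -> np.ndarray:
    """Linear operator taking potentials at ``pos_from`` to ``pos_to``.

    Both position arrays are (n, 3) unit vectors.  ``W @ v`` evaluates the
    fitted spline (including the constant term) at the target electrodes.
    """
    pos_from = np.asarray(pos_from, float)
    pos_to = np.asarray(pos_to, float)
    C, c0_row = _solve_coefficients(pos_from, order, reg)
    Gt = spline_kernel(pos_to @ pos_from.T, order=order)
    return Gt @ C + np.ones((pos_to.shape[0], 1)) @ c0_row[None, :]


def laplacian_matrix(
    pos: np.ndarray,
    order: int = DEFAULT_ORDER,
    reg: float = DEFAULT_REG,
    head_radius_m: float = 1.0,
) -> np.ndarray:
    """Linear operator computing the spherical-spline surface Laplacian.

    ``L @ v`` gives the current-source-density-convention Laplacian at the
    electrode sites (units of v per ``head_radius_m`` squared).  On the
    unit sphere a pure degree-n spherical-harmonic topography is mapped to
    ``n(n+1)`` times itself (up to the small ridge regularization).
    """
    pos = np.asarray(pos, float)
    C, _ = _solve_coefficients(pos, order, reg)
    # companion kernel: Laplace-Beltrami multiplies the degree-n term by
    # -n(n+1); CSD flips the sign
    H = spline_kernel(pos @ pos.T, order=order - 1)
    return (H @ C) / head_radius_m**2
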