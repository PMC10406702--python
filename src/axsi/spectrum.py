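"""Non-negative Tikhonov-regularized inversion of the predictor library.

Per voxel we solve

    min_w ||A w - y||^2 + lambda^2 ||L w||^2   s.t.  w >= 0

where A is the predictor library, y the b0-normalized measured signal, and
L a second-difference operator acting on the restricted (diameter) columns
only: the regularization expresses the prior that the axon diameter
distribution is smooth, while the compartment fractions themselves are not
penalized. Fractions are obtained by normalizing the solution to unit sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls as _nnls

from axsi.library import DiameterGrid

log = logging.getLogger(__name__)

#: restricted fractions below this leave eMAD undefined (NaN), preventing
#: noise-driven diameters in CSF-dominated voxels
DEFAULT_A_R_FLOOR = 0.05

#: default regularization: this factor times the largest singular value of
#: the restricted block of the library
DEFAULT_LAMBDA_FACTOR = 0.1


@dataclass
class SpectrumFit:
    """Fitted diameter spectrum and compartment fractions for one voxel."""

    pi: np.ndarray           # K non-negative restricted weights, unit-sum scale
    a_f: float               # CSF fraction
    a_h: float               # hindered fraction
    a_r: float               # restricted (axonal) fraction, sum(pi)
    emad: float              # estimated mean axon diameter, um (NaN if undefined)
    residual_norm: float
    lambda_used: float
    empty: bool = False      # solver returned the zero vector


def smoothness_operator(n_columns: int, n_restricted: int) -> np.ndarray:
    """Second differences over adjacent restricted columns.

    Returns an (n_restricted - 2) x n_columns matrix whose rows apply
    [1, -2, 1] across consecutive diameter predictors; the leading
    compartment columns carry zeros.
    """
    n_comp = n_columns - n_restricted
    n_rows = max(n_restricted - 2, 0)
    L = np.zeros((n_rows, n_columns))
    for i in range(n_rows):
        L[i, n_comp + i:n_comp + i + 3] = (1.0, -2.0, 1.0)
    return L


def default_lambda(matrix: np.ndarray, n_restricted: int,
                   factor: float = DEFAULT_LAMBDA_FACTOR) -> float:
    """Regularization weight scaled to the restricted block's top singular value."""
    block = matrix[:, matrix.shape[1] - n_restricted:]
    return factor * float(np.linalg.norm(block, 2))


def gcv_lambda(matrix: np.ndarray, signal: np.ndarray, n_restricted: int,
               candidates: np.ndarray | None = None) -> float:
    """Generalized-cross-validation choice of lambda (optional, not default).

    Evaluates the GCV function of the unconstrained Tikhonov problem on a
    log-spaced candidate grid and returns the minimizer. Uses the ridge
    influence matrix; the non-negativity constraint is ignored for the
    purpose of selecting lambda, which keeps the rule closed-form.
    """
    A = np.asarray(matrix, dtype=float)
    y = np.asarray(signal, dtype=float)
    L = smoothness_operator(A.shape[1], n_restricted)
    if candidates is None:
        s_max = np.linalg.norm(A[:, A.shape[1] - n_restricted:], 2)
        candidates = s_max * np.logspace(-3, 0, 16)
    best, best_g = candidates[0], np.inf
    n = A.shape[0]
    ata = A.T @ A
    ltl = L.T @ L
    for lam in candidates:
        H = A @ np.linalg.solve(ata + lam ** 2 * ltl, A.T)
        resid = y - H @ y
        denom = (n - np.trace(H)) ** 2
        g = n * float(resid @ resid) / max(denom, 1e-30)
        if g < best_g:
            best, best_g = lam, g
    return float(best)


def tikhonov_nnls(matrix: np.ndarray, signal: np.ndarray,
                  lam: float | None = None,
                  operator: np.ndarray | None = None,
                  n_restricted: int | None = None) -> tuple[np.ndarray, float]:
    """Solve min ||A w - y||^2 + lam^2 ||L w||^2, w >= 0.

    Implemented as plain NNLS on the augmented system [A; lam L] w = [y; 0],
    which is exactly equivalent and inherits the active-set solver's
    deterministic, sparse solutions. Returns (weights, residual_norm) where
    the residual is the unregularized data misfit ||A w - y||.
    """
    A = np.asarray(matrix, dtype=float)
    y = np.asarray(signal, dtype=float)
    if y.ndim != 1 or y.shape[0] != A.shape[0]:
        raise ValueError("signal length must match matrix rows")
    if np.isnan(y).any():
        raise ValueError("NaN in signal")
    if n_restricted is None:
        n_restricted = A.shape[1] - 2
    if lam is None:
        lam = default_lambda(A, n_restricted)
    if operator is None:
        operator = smoothness_operator(A.shape[1], n_restricted)
    if lam > 0 and operator.size:
        A_aug = np.vstack([A, lam * operator])
        y_aug = np.concatenate([y, np.zeros(operator.shape[0])])
    else:
        A_aug, y_aug = A, y
    try:
        w, _ = _nnls(A_aug, y_aug)
    except Exception:  # rank deficiency: fall back to a bounded least-norm solve
        log.warning("NNLS failed; solving rank-deficient system in "
                    "least-norm sense")
        from scipy.optimize import lsq_linear
        res = lsq_linear(A_aug, y_aug, bounds=(0, np.inf),
                         lsmr_tol="auto", method="bvls"
                         if A_aug.shape[0] >= A_aug.shape[1] else "trf")
        w = np.maximum(res.x, 0.0)
    return w, float(np.linalg.norm(A @ w - y))


def compute_fractions(raw_weights: np.ndarray) -> tuple[float, float, np.ndarray, bool]:
    """Normalize raw weights to compartment fractions (A_f, A_h, pi_k).

    The weight vector is scaled to unit sum so A_f + A_h + sum(pi) = 1.
    Returns (a_f, a_h, pi, empty); an all-zero input is flagged empty.
    """
    w = np.asarray(raw_weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("raw weights must be non-negative")
    s = w.sum()
    if s <= 0:
        return np.nan, np.nan, np.full(w.size - 2, np.nan), True
    w = w / s
    return float(w[0]), float(w[1]), w[2:], False


def emad(pi: np.ndarray, grid: DiameterGrid) -> float:
    """Estimated mean axon diameter: the pi-weighted mean of the grid, um."""
    pi = np.asarray(pi, dtype=float)
    total = pi.sum()
    if not total > 0:
        return float("nan")
    return float((pi * grid.diameters).sum() / total)


def emad_volume_weighted(pi: np.ndarray, grid: DiameterGrid) -> float:
    """Variant weighting each diameter by pi_k R_k^2 (cross-sectional volume)."""
    pi = np.asarray(pi, dtype=float)
    w = pi * grid.diameters ** 2
    total = w.sum()
    if not total > 0:
        return float("nan")
    return float((w * grid.diameters).sum() / total)


def fit_spectrum(matrix: np.ndarray, signal: np.ndarray,
                 grid: DiameterGrid,
                 lam: float | None = None,
                 a_r_floor: float = DEFAULT_A_R_FLOOR) -> SpectrumFit:
    """Full per-voxel inversion: solve, normalize, derive fractions and eMAD."""
    n_restricted = len(grid)
    if lam is None:
        lam = default_lambda(matrix, n_restricted)
    w, resid = tikhonov_nnls(matrix, signal, lam, n_restricted=n_restricted)
    a_f, a_h, pi, empty = compute_fractions(w)
    a_r = float(np.nan) if empty else float(pi.sum())
    mad = float("nan")
    if not empty and a_r >= a_r_floor:
        mad = emad(pi, grid)
    return SpectrumFit(pi=pi, a_f=a_f, a_h=a_h, a_r=a_r, emad=mad,
                       residual_norm=resid, lambda_used=float(lam),
                       empty=empty)
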