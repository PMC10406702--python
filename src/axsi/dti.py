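"""Diffusion tensor fit supplying the hindered-compartment prior.

The tensor serves two roles downstream: its full 3x3 form generates the
hindered (extra-axonal) predictor, and its principal eigenvector defines the
cylinder axis against which gradient directions are decomposed for the
restricted predictors. Only low-b shells enter the fit because the decay at
high b is visibly non-monoexponential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from axsi.io import DwiDataset

log = logging.getLogger(__name__)

#: eigenvalue floor, mm^2/s
EIGVAL_FLOOR = 1e-7

#: shells above this (s/mm^2) are excluded from the tensor fit by default
DEFAULT_MAX_B = 1500.0


class ConditioningError(ValueError):
    """Too few independent gradient directions for a tensor fit."""


@dataclass
class TensorField:
    """Per-voxel tensor fit results over a 3-D grid.

    tensor : (x, y, z, 3, 3) symmetric diffusion tensors, mm^2/s
    principal_direction : (x, y, z, 3) unit eigenvector of the largest
        eigenvalue (sign fixed so the first nonzero component is >= 0)
    md, fa, axial_diffusivity, s0 : scalar maps; NaN outside the mask
    mask : voxels that were fitted
    n_clamped : eigenvalues clamped to the positivity floor
    """

    tensor: np.ndarray
    principal_direction: np.ndarray
    md: np.ndarray
    fa: np.ndarray
    axial_diffusivity: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx, -b * gy * gy, -b * gz * gz,
        -2 * b * gx * gy, -2 * b * gx * gz, -2 * b * gy * gz,
    ])


def _coef_to_tensor(coef: np.ndarray) -> np.ndarray:
    """(..., 7) log-linear coefficients -> (..., 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = (coef[..., i] for i in range(1, 7))
    T = np.empty(coef.shape[:-1] + (3, 3))
    T[..., 0, 0] = dxx
    T[..., 1, 1] = dyy
    T[..., 2, 2] = dzz
    T[..., 0, 1] = T[..., 1, 0] = dxy
    T[..., 0, 2] = T[..., 2, 0] = dxz
    T[..., 1, 2] = T[..., 2, 1] = dyz
    return T


def _fix_sign(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvectors so the first nonzero component is non-negative."""
    v = vecs.copy()
    sign = np.where(v[..., 0] != 0, np.sign(v[..., 0]),
                    np.where(v[..., 1] != 0, np.sign(v[..., 1]),
                             np.where(v[..., 2] != 0, np.sign(v[..., 2]), 1.0)))
    return v * sign[..., None]


def fit_tensor(dwi: DwiDataset, max_b: float = DEFAULT_MAX_B) -> TensorField:
    """Weighted log-linear least-squares tensor per masked voxel.

    An ordinary least-squares pass on log-signal is followed by one weighted
    pass with weights equal to the squared predicted signal, the standard
    correction for the log transform's noise distortion. Deterministic:
    no robust reweighting iterations.
    """
    scheme = dwi.scheme
    sel = scheme.bvals <= max_b
    if sel.sum() < 7 or not (scheme.b0_mask & sel).any():
        raise ConditioningError(
            f"need >= 7 volumes with b <= {max_b} including a b0; have "
            f"{int(sel.sum())}")
    B = _design_matrix(scheme.bvals[sel], scheme.bvecs[sel])
    if np.linalg.matrix_rank(B) < 7:
        raise ConditioningError(
            "gradient table has fewer than 6 independent directions")

    shape = dwi.shape
    mask = dwi.mask.copy()
    sig = dwi.signal[..., sel]
    dead = mask & ~(sig.max(axis=-1) > 0)
    if dead.any():
        log.warning("excluding %d all-zero voxels from tensor fit",
                    int(dead.sum()))
        mask &= ~dead

    y = sig[mask]  # (n_vox, n_sel)
    floor = 1e-10
    n_floored = int((y <= 0).sum())
    if n_floored:
        log.warning("floored %d non-positive signal samples", n_floored)
    lny = np.log(np.maximum(y, floor))

    # OLS pass
    coef, *_ = np.linalg.lstsq(B, lny.T, rcond=None)
    coef = coef.T  # (n_vox, 7)
    # one weighted pass, weights = predicted signal squared
    w = np.exp(2.0 * (coef @ B.T))
    btwb = np.einsum("nj,vn,nk->vjk", B, w, B)
    rhs = np.einsum("nj,vn,vn->vj", B, w, lny)
    coef = np.linalg.solve(btwb, rhs[..., None])[..., 0]

    tensors = _coef_to_tensor(coef)
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    n_clamped = int((evals < EIGVAL_FLOOR).sum())
    if n_clamped:
        log.info("clamped %d eigenvalues to %.1e mm^2/s", n_clamped,
                 EIGVAL_FLOOR)
    evals = np.maximum(evals, EIGVAL_FLOOR)

    md = evals.mean(axis=-1)
    dev = evals - md[..., None]
    denom = (evals ** 2).sum(axis=-1)
    fa = np.sqrt(1.5 * (dev ** 2).sum(axis=-1) / np.where(denom > 0, denom, 1.0))
    fa = np.clip(fa, 0.0, 1.0)
    ad = evals[..., -1]
    v1 = _fix_sign(evecs[..., -1])
    # rebuild the tensor from clamped eigenvalues so it is PSD by construction
    tensors = np.einsum("...ij,...j,...kj->...ik", evecs, evals, evecs)

    def full(values, fill=np.nan, extra=()):
        out = np.full(shape + tuple(extra), fill)
        out[mask] = values
        return out

    return TensorField(
        tensor=full(tensors, extra=(3, 3)),
        principal_direction=full(v1, extra=(3,)),
        md=full(md),
        fa=full(fa),
        axial_diffusivity=full(ad),
        s0=full(np.exp(coef[:, 0])),
        mask=mask,
        n_clamped=n_clamped,
    )
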