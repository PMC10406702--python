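"""Whole-volume voxel loop and derived map assembly.

Runs the chain tensor prior -> predictor library -> regularized inversion in
every masked voxel and collects the eMAD, compartment-fraction and
extra-axonal diffusivity volumes. Unfitted voxels carry NaN (not zero) so
that downstream averaging can exclude them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from axsi.dti import DEFAULT_MAX_B, TensorField, fit_tensor
from axsi.io import DwiDataset
from axsi.library import (DEFAULT_D_CSF, DEFAULT_HINDERED_AXIAL,
                          DEFAULT_HINDERED_RADIAL,
                          DEFAULT_PARALLEL_DIFFUSIVITY, FA_FLOOR,
                          DiameterGrid, build_library, prolate_tensor)
from axsi.spectrum import DEFAULT_A_R_FLOOR, fit_spectrum

log = logging.getLogger(__name__)

#: default exclusion floor for streamline ADD values entering density maps, um
DEFAULT_MIN_ADD = 0.3

# fit_flags codes
FLAG_OUTSIDE_MASK = -1
FLAG_OK = 0
FLAG_SKIPPED_B0 = 1       # non-positive mean b0 signal
FLAG_EMPTY_SOLUTION = 2   # solver returned all-zero weights
FLAG_DIRECTION_FALLBACK = 3


@dataclass
class AxsiMaps:
    """Derived 3-D volumes from a whole-dataset fit.

    emad_map is NaN wherever the restricted fraction fell below the floor or
    the voxel was skipped; fraction maps are in [0, 1] where fitted; md_map
    is the mean diffusivity of the hindered tensor prior, exported as the
    extra-axonal diffusivity.
    """

    emad_map: np.ndarray
    a_r_map: np.ndarray
    a_h_map: np.ndarray
    a_f_map: np.ndarray
    md_map: np.ndarray
    fit_flags: np.ndarray
    affine: np.ndarray
    grid: DiameterGrid
    tensor_field: TensorField | None = None


def fit_dataset(dwi: DwiDataset,
                grid: DiameterGrid | None = None,
                lam: float | None = None,
                d_csf: float = DEFAULT_D_CSF,
                a_r_floor: float = DEFAULT_A_R_FLOOR,
                max_b_dti: float = DEFAULT_MAX_B,
                parallel_diffusivity: float = DEFAULT_PARALLEL_DIFFUSIVITY,
                hindered_axial: float = DEFAULT_HINDERED_AXIAL,
                hindered_radial: float = DEFAULT_HINDERED_RADIAL) -> AxsiMaps:
    """Fit the full spectrum model in every masked voxel.

    The tensor fit supplies the per-voxel fiber axis; the hindered predictor
    is an axially symmetric tensor about that axis with the fixed
    ``hindered_axial`` / ``hindered_radial`` diffusivities, and the
    restricted predictors use the fixed intra-axonal
    ``parallel_diffusivity``. The measured signal is divided by its mean
    over b0 volumes before the inversion; voxels whose mean b0 is
    non-positive are skipped and flagged. Per-voxel failures are recorded
    in ``fit_flags`` and never abort the volume. Output is independent of
    voxel iteration order.
    """
    grid = grid or DiameterGrid()
    tf = fit_tensor(dwi, max_b=max_b_dti)
    shape = dwi.shape
    emad_map = np.full(shape, np.nan)
    a_r_map = np.full(shape, np.nan)
    a_h_map = np.full(shape, np.nan)
    a_f_map = np.full(shape, np.nan)
    flags = np.full(shape, FLAG_OUTSIDE_MASK, dtype=np.int16)

    b0_mask = dwi.scheme.b0_mask
    voxels = np.argwhere(tf.mask)
    n_done = 0
    for ix, iy, iz in voxels:
        vox = (int(ix), int(iy), int(iz))
        sig = dwi.signal[vox]
        s0 = sig[b0_mask].mean()
        if not s0 > 0:
            flags[vox] = FLAG_SKIPPED_B0
            continue
        v1 = tf.principal_direction[vox]
        if not np.isfinite(v1).all() or np.linalg.norm(v1) < 1e-12:
            v1 = np.array([1.0, 0.0, 0.0])
        hindered_prior = prolate_tensor(v1, hindered_axial, hindered_radial)
        lib = build_library(dwi.scheme, v1, hindered_prior,
                            parallel_diffusivity,
                            grid=grid, d_csf=d_csf, fa=float(tf.fa[vox]))
        fit = fit_spectrum(lib.matrix, sig / s0, grid, lam=lam,
                           a_r_floor=a_r_floor)
        if fit.empty:
            flags[vox] = FLAG_EMPTY_SOLUTION
            continue
        flags[vox] = (FLAG_DIRECTION_FALLBACK if lib.direction_fallback
                      else FLAG_OK)
        emad_map[vox] = fit.emad
        a_r_map[vox] = fit.a_r
        a_h_map[vox] = fit.a_h
        a_f_map[vox] = fit.a_f
        n_done += 1
        if n_done % 2000 == 0:
            log.info("fitted %d / %d voxels", n_done, len(voxels))
    log.info("fit complete: %d voxels", n_done)
    return AxsiMaps(emad_map=emad_map, a_r_map=a_r_map, a_h_map=a_h_map,
                    a_f_map=a_f_map, md_map=tf.md, fit_flags=flags,
                    affine=dwi.affine, grid=grid, tensor_field=tf)


def streamline_voxels(points_mm: np.ndarray, affine: np.ndarray,
                      shape: tuple) -> np.ndarray:
    """Unique in-volume voxel indices visited by a world-mm polyline.

    Nearest-voxel lookup through the inverse affine; each streamline
    contributes each voxel at most once, which removes step-length bias.
    """
    inv = np.linalg.inv(affine)
    pts = np.asarray(points_mm, dtype=float)
    ijk = (pts @ inv[:3, :3].T) + inv[:3, 3]
    ijk = np.round(ijk).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
    if not inside.any():
        return np.empty((0, 3), dtype=int)
    return np.unique(ijk[inside], axis=0)


def streamline_density_add_map(streamlines,
                               per_streamline_add: np.ndarray,
                               affine: np.ndarray,
                               shape: tuple,
                               min_add: float = DEFAULT_MIN_ADD) -> np.ndarray:
    """Mean streamline ADD over each traversed voxel.

    Streamlines with ADD below ``min_add`` (default 0.3 um) or with
    undefined ADD are excluded; voxels traversed by no surviving streamline
    are NaN.
    """
    per_streamline_add = np.asarray(per_streamline_add, dtype=float)
    if len(streamlines) != per_streamline_add.size:
        raise ValueError("one ADD value per streamline required")
    if not len(streamlines):
        log.warning("empty streamline set; density map is all-NaN")
        return np.full(shape, np.nan)
    acc = np.zeros(shape)
    cnt = np.zeros(shape, dtype=int)
    for sl, add in zip(streamlines, per_streamline_add):
        if not np.isfinite(add) or add < min_add:
            continue
        vox = streamline_voxels(sl, affine, shape)
        if vox.size:
            acc[vox[:, 0], vox[:, 1], vox[:, 2]] += add
            cnt[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    out = np.full(shape, np.nan)
    hit = cnt > 0
    out[hit] = acc[hit] / cnt[hit]
    return out
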