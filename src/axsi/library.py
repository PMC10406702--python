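"""Per-voxel predictor library: CSF, hindered, and restricted-cylinder signals.

The library is an n_volumes x (K + 2) design matrix. Column 0 is the free
(CSF) predictor exp(-b D_csf); column 1 is the hindered predictor
exp(-b g^T D g) from the voxel's tensor prior; columns 2..K+1 are restricted
cylinder predictors exp(-q_perp^2 R_k^2) over K candidate diameters R_k,
each multiplied by a Gaussian parallel term exp(-b_par * lambda1) so that
gradients aligned with the fiber still see intra-axonal decay.

Every predictor is normalized to the non-weighted signal, so all columns are
exactly 1 on b0 rows and the measured signal is divided by its b0 mean before
fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from axsi.scheme import GradientScheme

log = logging.getLogger(__name__)

#: free-water diffusivity at body temperature, mm^2/s
DEFAULT_D_CSF = 3.0e-3

#: intra-axonal parallel diffusivity used for the restricted predictors'
#: Gaussian parallel term, mm^2/s. A fixed model constant rather than the
#: voxel's fitted axial diffusivity: the composite tensor's eigenvalues
#: absorb restricted decay, and feeding them back into the restricted
#: predictors couples the compartments and destroys identifiability.
DEFAULT_PARALLEL_DIFFUSIVITY = 1.7e-3

#: hindered (extra-axonal) prior tensor shape, mm^2/s: axially symmetric
#: about the fiber axis with these fixed axial/radial diffusivities. Only
#: the axis is taken per voxel (from the tensor fit); the eigenvalues are
#: model constants because the composite tensor's radial eigenvalue is
#: contaminated by restricted decay.
DEFAULT_HINDERED_AXIAL = 1.7e-3
DEFAULT_HINDERED_RADIAL = 0.5e-3

#: default candidate diameter grid, um
DEFAULT_DIAMETER_MIN = 0.1
DEFAULT_DIAMETER_MAX = 16.0
DEFAULT_N_DIAMETERS = 160

#: voxels with FA below this get a fallback restricted axis
FA_FLOOR = 0.05


@dataclass(frozen=True)
class DiameterGrid:
    """Ordered candidate axon diameters R_k (um) spanning the CNS range.

    The default is 160 linearly spaced diameters from 0.1 to 16.0 um
    (0.1 um steps); reported CNS axon calibers fall well inside this span.
    """

    diameters: np.ndarray = field(
        default_factory=lambda: np.linspace(
            DEFAULT_DIAMETER_MIN, DEFAULT_DIAMETER_MAX, DEFAULT_N_DIAMETERS))
    #: interpret R in the cylinder attenuation as the diameter (the package
    #: default) or as the radius (R_eff = R_k / 2), kept for sensitivity runs
    radius_interpretation: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters, dtype=float)
        if d.ndim != 1 or d.size < 1:
            raise ValueError("diameters must be a 1-D vector")
        if np.any(d <= 0) or np.any(np.diff(d) <= 0):
            raise ValueError("diameters must be strictly increasing and > 0")
        object.__setattr__(self, "diameters", d)

    def __len__(self) -> int:
        return int(self.diameters.size)

    @property
    def effective_size(self) -> np.ndarray:
        """Size parameter entering the attenuation exponent, um."""
        return self.diameters / 2.0 if self.radius_interpretation \
            else self.diameters

    @property
    def step(self) -> float:
        return float(np.diff(self.diameters).mean())


def prolate_tensor(direction: np.ndarray,
                   axial: float = DEFAULT_HINDERED_AXIAL,
                   radial: float = DEFAULT_HINDERED_RADIAL) -> np.ndarray:
    """Axially symmetric 3x3 tensor with the given principal axis (mm^2/s)."""
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    return radial * np.eye(3) + (axial - radial) * np.outer(v, v)


@dataclass
class PredictorLibrary:
    """Design matrix for one voxel plus its generating context."""

    matrix: np.ndarray  # (n_volumes, K + 2)
    grid: DiameterGrid
    principal_direction: np.ndarray
    tensor: np.ndarray
    parallel_diffusivity: float
    direction_fallback: bool = False

    @property
    def n_restricted(self) -> int:
        return self.matrix.shape[1] - 2


def restricted_signal(q_perp, diameter) -> np.ndarray:
    """Cylinder attenuation exp(-(q_perp * R)^2) in (0, 1].

    q_perp is the perpendicular q component (rad/um), R the cylinder size
    parameter (um); the product is dimensionless. Valid in the long-
    diffusion-time, short-pulse regime where the decay is insensitive to the
    gradient duration.
    """
    q_perp = np.asarray(q_perp, dtype=float)
    diameter = np.asarray(diameter, dtype=float)
    if np.any(q_perp < 0):
        raise ValueError("q_perp must be >= 0")
    if np.any(diameter <= 0):
        raise ValueError("diameter must be > 0")
    return np.exp(-(q_perp * diameter) ** 2)


def csf_predictor(scheme: GradientScheme, d_csf: float = DEFAULT_D_CSF
                  ) -> np.ndarray:
    """Free-water Gaussian attenuation exp(-b D_csf) per volume; 1 on b0 rows."""
    if d_csf <= 0:
        raise ValueError("d_csf must be > 0")
    b = np.where(scheme.b0_mask, 0.0, scheme.bvals)
    return np.exp(-b * d_csf)


def hindered_predictor(scheme: GradientScheme, tensor: np.ndarray
                       ) -> np.ndarray:
    """Extra-axonal attenuation exp(-b g^T D g) per volume; 1 on b0 rows."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-12):
        raise ValueError("tensor must be symmetric 3x3")
    b = np.where(scheme.b0_mask, 0.0, scheme.bvals)
    adc = np.einsum("ni,ij,nj->n", scheme.bvecs, tensor, scheme.bvecs)
    return np.exp(-b * np.maximum(adc, 0.0))


def build_library(scheme: GradientScheme,
                  principal_direction: np.ndarray,
                  tensor: np.ndarray,
                  parallel_diffusivity: float = DEFAULT_PARALLEL_DIFFUSIVITY,
                  grid: DiameterGrid | None = None,
                  d_csf: float = DEFAULT_D_CSF,
                  fa: float | None = None) -> PredictorLibrary:
    """Assemble the n_volumes x (K+2) predictor matrix for one voxel.

    Each gradient is decomposed about the fiber axis v: with
    cos(theta) = |g_hat . v|, the perpendicular q component is q sin(theta)
    and the parallel b component is b cos^2(theta). Restricted column k is
    exp(-(q_perp R_k)^2) * exp(-b_par D_par) with D_par the fixed
    intra-axonal parallel diffusivity; ``tensor`` generates the hindered
    column.

    When the tensor prior has no usable direction (FA below the floor), the
    gradient-frame axis closest to the tensor's principal axis is used and
    the fallback is flagged.
    """
    grid = grid or DiameterGrid()
    v = np.asarray(principal_direction, dtype=float)
    fallback = False
    if (fa is not None and fa < FA_FLOOR) or not np.isfinite(v).all() \
            or np.linalg.norm(v) < 1e-12:
        axis = int(np.nanargmax(np.abs(v))) if np.isfinite(v).any() else 0
        v = np.eye(3)[axis]
        fallback = True
        log.debug("direction undefined; falling back to axis %d", axis)
    v = v / np.linalg.norm(v)

    b = np.where(scheme.b0_mask, 0.0, scheme.bvals)
    q = scheme.q
    cos_t = np.abs(scheme.bvecs @ v)
    cos_t = np.clip(cos_t, 0.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    q_perp = q * sin_t
    b_par = b * cos_t ** 2

    K = len(grid)
    matrix = np.empty((len(scheme), K + 2))
    matrix[:, 0] = csf_predictor(scheme, d_csf)
    matrix[:, 1] = hindered_predictor(scheme, tensor)
    parallel = np.exp(-b_par * max(parallel_diffusivity, 0.0))
    r_eff = grid.effective_size
    matrix[:, 2:] = np.exp(-(q_perp[:, None] * r_eff[None, :]) ** 2) \
        * parallel[:, None]
    matrix[scheme.b0_mask, :] = 1.0  # exact normalization on b0 rows
    return PredictorLibrary(matrix=matrix, grid=grid, principal_direction=v,
                            tensor=np.asarray(tensor, dtype=float),
                            parallel_diffusivity=float(parallel_diffusivity),
                            direction_fallback=fallback)
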