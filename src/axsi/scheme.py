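"""Acquisition scheme: b-values, gradient directions, and pulse timings.

Unit conventions used throughout the package:

* b-value          s/mm^2
* diffusivity      mm^2/s
* q-value          rad/um
* diameters        um
* gradient pulses  Delta, delta in ms; gradient amplitude g in T/m
* coordinates      mm (world/RAS)

With q in rad/um and diameters in um the restricted-cylinder exponent
q^2 R^2 is dimensionless by construction.

For a pulsed-gradient spin-echo experiment q = gamma * delta * g and
b = q^2 (Delta - delta/3) in consistent units; both directions of that
relation are provided here so q and g can be recovered from the b-value
table alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_PROTON = 2.6752218744e8

#: volumes with b at or below this are treated as non-diffusion-weighted (s/mm^2)
DEFAULT_B0_THRESHOLD = 50.0

#: shells are identified by rounding b to the nearest multiple of this (s/mm^2)
SHELL_ROUNDING = 50.0


class SchemeFormatError(ValueError):
    """Malformed or mutually inconsistent bval/bvec inputs."""


class SchemeValidationError(ValueError):
    """Inputs parsed but violate a scheme invariant."""


def q_from_b(bvals: np.ndarray, big_delta: float, small_delta: float,
             b0_threshold: float = DEFAULT_B0_THRESHOLD) -> np.ndarray:
    """q-value (rad/um) per volume from b (s/mm^2) and timings (ms).

    Inverts b = q^2 (Delta - delta/3); q is exactly 0 for b0 volumes.
    """
    bvals = np.asarray(bvals, dtype=float)
    td_s = (big_delta - small_delta / 3.0) * 1e-3
    q_per_mm = np.sqrt(np.maximum(bvals, 0.0) / td_s)  # rad/mm
    q = q_per_mm / 1000.0
    q[bvals <= b0_threshold] = 0.0
    return q


def g_from_q(q: np.ndarray, small_delta: float,
             gamma: float = GAMMA_PROTON) -> np.ndarray:
    """Gradient amplitude (T/m) from q (rad/um) and delta (ms) via q = gamma delta g."""
    q_per_m = np.asarray(q, dtype=float) * 1e6
    return q_per_m / (gamma * small_delta * 1e-3)


def q_from_delta_g(small_delta: float, g: float,
                   gamma: float = GAMMA_PROTON) -> float:
    """q (rad/um) from delta (ms) and gradient amplitude g (T/m)."""
    return gamma * (small_delta * 1e-3) * g / 1e6


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume acquisition description of a multi-shell DWI protocol.

    Attributes
    ----------
    bvals : (n,) float array, s/mm^2
    bvecs : (n, 3) float array of unit direction vectors (zero rows allowed
        on b0 volumes)
    big_delta, small_delta : gradient separation Delta and duration delta, ms
    gamma : gyromagnetic ratio, rad s^-1 T^-1
    b0_threshold : b at or below this counts as a b0 volume, s/mm^2
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    big_delta: float
    small_delta: float
    gamma: float = GAMMA_PROTON
    b0_threshold: float = DEFAULT_B0_THRESHOLD
    q: np.ndarray = field(init=False, repr=False)
    g: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise SchemeFormatError(
                f"bvecs must be (n, 3); got shape {bvecs.shape}")
        if bvecs.shape[0] != bvals.shape[0]:
            raise SchemeFormatError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions")
        if np.any(bvals < 0):
            raise SchemeValidationError("negative b-value")
        if not (self.big_delta > self.small_delta > 0):
            raise SchemeValidationError(
                f"require Delta > delta > 0; got Delta={self.big_delta}, "
                f"delta={self.small_delta}")
        b0 = bvals <= self.b0_threshold
        if not b0.any():
            raise SchemeValidationError(
                f"no b0 volume (b <= {self.b0_threshold} s/mm^2) in scheme")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = ~b0 & (np.abs(norms - 1.0) > 1e-6)
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise SchemeValidationError(
                f"direction {idx} has norm {norms[idx]:.6g}, expected unit "
                "(non-b0 volumes must carry unit vectors)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        object.__setattr__(
            self, "q",
            q_from_b(bvals, self.big_delta, self.small_delta, self.b0_threshold))
        object.__setattr__(self, "g", g_from_q(self.q, self.small_delta, self.gamma))

    def __len__(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_threshold

    @property
    def shells(self) -> np.ndarray:
        """Distinct nominal shells (b0 included), b rounded to nearest 50 s/mm^2."""
        return np.unique(np.round(self.bvals / SHELL_ROUNDING) * SHELL_ROUNDING)

    def shell_of(self) -> np.ndarray:
        """Nominal shell per volume after rounding."""
        return np.round(self.bvals / SHELL_ROUNDING) * SHELL_ROUNDING

    def subset(self, index: np.ndarray) -> "GradientScheme":
        """Scheme restricted to the given volume indices."""
        return GradientScheme(self.bvals[index], self.bvecs[index],
                              self.big_delta, self.small_delta,
                              self.gamma, self.b0_threshold)


def _load_table(path, expected_rows: int) -> np.ndarray:
    try:
        arr = np.loadtxt(path, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - propagate as a format error
        raise SchemeFormatError(f"cannot parse {path}: {exc}") from exc
    # FSL writes 1 x n (bvals) or 3 x n (bvecs); accept transposed column files
    if arr.shape[0] != expected_rows and arr.shape[1] == expected_rows:
        arr = arr.T
    if arr.shape[0] != expected_rows:
        raise SchemeFormatError(
            f"{path}: expected {expected_rows} rows (FSL dialect), "
            f"got shape {arr.shape}")
    return arr


def read_gradient_scheme(bval_path, bvec_path, big_delta: float,
                         small_delta: float, *,
                         gamma: float = GAMMA_PROTON,
                         b0_threshold: float = DEFAULT_B0_THRESHOLD) -> GradientScheme:
    """Read FSL-dialect bval/bvec text files into a validated scheme.

    ``bval_path`` holds one whitespace-separated row of b-values (s/mm^2);
    ``bvec_path`` holds three rows (x, y, z components). Column-oriented
    files are auto-detected by shape. Timings are in ms.
    """
    bvals = _load_table(bval_path, 1).ravel()
    bvecs = _load_table(bvec_path, 3).T
    if bvecs.shape[0] != bvals.shape[0]:
        raise SchemeFormatError(
            f"{bval_path} has {bvals.shape[0]} entries but {bvec_path} has "
            f"{bvecs.shape[0]} directions")
    return GradientScheme(bvals, bvecs, big_delta, small_delta,
                          gamma=gamma, b0_threshold=b0_threshold)


def write_gradient_scheme(scheme: GradientScheme, bval_path, bvec_path) -> None:
    """Write bvals/bvecs in the FSL row dialect."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")
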