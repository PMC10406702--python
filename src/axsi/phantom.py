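"""Synthetic multi-shell DWI phantoms with known ground truth.

The generator produces datasets with exactly the statistical structure the
spectrum model assumes: per voxel the noise-free signal is the
fraction-weighted sum of the same CSF / hindered / restricted predictors the
fitting library builds, with a single-diameter or gamma-shaped axon diameter
distribution discretized onto the candidate grid, and Rician noise applied
at a stated b0 SNR. Acquisition presets mirror three published multi-shell
protocols (two 3T research protocols and the HCP protocol).

Because the forward model is the analytic predictor library itself (no
Monte-Carlo random walks), noise-free phantoms are fixed points of the
pipeline up to grid resolution and solver tolerance; what passing tests on
these phantoms cannot show is robustness to model misspecification in real
tissue (dispersion, exchange, non-Gaussian hindered diffusion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from axsi.io import DwiDataset
from axsi.library import (DEFAULT_D_CSF, DEFAULT_HINDERED_AXIAL,
                          DEFAULT_HINDERED_RADIAL,
                          DEFAULT_PARALLEL_DIFFUSIVITY, DiameterGrid,
                          build_library, prolate_tensor)
from axsi.scheme import GradientScheme

log = logging.getLogger(__name__)

#: non-weighted signal amplitude, arbitrary units; SNR is defined at b0
DEFAULT_S0 = 1000.0

#: default white-matter hindered tensor eigenvalues (axial, radial), mm^2/s;
#: the phantom emulates tissue that satisfies the model's own compartment
#: assumptions, so these equal the fitting model's hindered prior
WM_AXIAL = DEFAULT_HINDERED_AXIAL
WM_RADIAL = DEFAULT_HINDERED_RADIAL

#: intra-axonal parallel diffusivity, mm^2/s (the fitting model's constant)
INTRA_AXONAL_PARALLEL = DEFAULT_PARALLEL_DIFFUSIVITY

#: acquisition presets: shells (s/mm^2), Delta/delta (ms), and directions
#: per shell chosen so total direction counts match the corresponding
#: published protocols (88, 186 and 270 weighted volumes respectively)
SCHEME_PRESETS = {
    "protocol1": {"shells": (250.0, 1000.0, 3000.0, 5000.0),
                  "big_delta": 60.0, "small_delta": 15.5,
                  "n_dirs_per_shell": 22, "n_b0": 4},
    "protocol2": {"shells": (1000.0, 2000.0, 4000.0),
                  "big_delta": 45.0, "small_delta": 15.0,
                  "n_dirs_per_shell": 62, "n_b0": 6},
    "hcp": {"shells": (1000.0, 2000.0, 3000.0),
            "big_delta": 43.1, "small_delta": 10.6,
            "n_dirs_per_shell": 90, "n_b0": 8},
}


def sphere_directions(n: int, offset: int = 0) -> np.ndarray:
    """n deterministic, roughly uniform unit vectors (golden-spiral points)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * (i + offset)
    cos_t = 1.0 - 2.0 * i / n
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def scheme_preset(name: str, n_dirs_per_shell: int | None = None,
                  n_b0: int | None = None) -> GradientScheme:
    """Build a GradientScheme for one of the named acquisition presets."""
    if name not in SCHEME_PRESETS:
        raise KeyError(f"unknown preset {name!r}; "
                       f"choose from {sorted(SCHEME_PRESETS)}")
    p = SCHEME_PRESETS[name]
    n_dirs = n_dirs_per_shell or p["n_dirs_per_shell"]
    n_b0 = n_b0 or p["n_b0"]
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for si, shell in enumerate(p["shells"]):
        dirs = sphere_directions(n_dirs, offset=si * 7)
        bvals.extend([shell] * n_dirs)
        bvecs.extend(dirs)
    return GradientScheme(np.array(bvals), np.array(bvecs),
                          big_delta=p["big_delta"],
                          small_delta=p["small_delta"])


@dataclass
class RegionSpec:
    """One homogeneous phantom region.

    ``diameter`` is either a single value (um) or the tuple
    ('gamma', shape, scale) giving a gamma ADD in um, truncated and
    renormalized on the candidate grid. Fractions must sum to 1.
    """

    a_f: float = 0.0
    a_h: float = 0.5
    a_r: float = 0.5
    diameter: object = 6.0
    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0]))
    tensor: np.ndarray | None = None
    parallel_diffusivity: float = INTRA_AXONAL_PARALLEL

    def __post_init__(self) -> None:
        total = self.a_f + self.a_h + self.a_r
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        self.direction = np.asarray(self.direction, dtype=float)
        self.direction = self.direction / np.linalg.norm(self.direction)
        if self.tensor is None:
            self.tensor = prolate_tensor(self.direction)


@dataclass
class PhantomSpec:
    """Full phantom description: geometry, regions, acquisition, noise.

    ``region_map`` assigns a region index per voxel (default: region 0
    everywhere). ``snr`` is the b0 signal-to-noise ratio; ``np.inf`` means
    noise-free.
    """

    shape: tuple = (60, 20, 8)
    regions: list = field(default_factory=lambda: [RegionSpec()])
    region_map: np.ndarray | None = None
    protocol: str = "hcp"
    snr: float = np.inf
    seed: int = 0
    s0: float = DEFAULT_S0
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        if not (self.snr > 0):
            raise ValueError("snr must be > 0 (np.inf for noise-free)")
        if self.region_map is None:
            self.region_map = np.zeros(self.shape, dtype=int)
        self.region_map = np.asarray(self.region_map, dtype=int)
        if self.region_map.shape != tuple(self.shape):
            raise ValueError("region_map shape must match phantom shape")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff


def discretize_add(diameter, grid: DiameterGrid) -> np.ndarray:
    """Unit-sum weights pi_k on the grid for a region's ADD descriptor.

    A scalar lands entirely on the nearest grid diameter; a
    ('gamma', shape, scale) tuple is evaluated as the gamma density at the
    grid points, truncated to the grid range, and renormalized.
    """
    pi = np.zeros(len(grid))
    if np.isscalar(diameter):
        pi[int(np.argmin(np.abs(grid.diameters - diameter)))] = 1.0
        return pi
    kind, shape_p, scale_p = diameter
    if kind != "gamma":
        raise ValueError(f"unknown ADD descriptor {kind!r}")
    pdf = gamma_dist.pdf(grid.diameters, a=shape_p, scale=scale_p)
    if pdf.sum() <= 0:
        raise ValueError("gamma ADD has no mass on the diameter grid")
    return pdf / pdf.sum()


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude-reconstruction noise: |(S + n1) + i n2| with n ~ N(0, sigma)."""
    if sigma == 0:
        return signal
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2 ** 2)


def simulate_voxel(region: RegionSpec, scheme: GradientScheme,
                   grid: DiameterGrid | None = None,
                   rng: np.random.Generator | None = None,
                   snr: float = np.inf,
                   s0: float = DEFAULT_S0,
                   d_csf: float = DEFAULT_D_CSF
                   ) -> tuple[np.ndarray, dict]:
    """Forward-simulate one voxel's signal vector plus its ground truth.

    The noise-free signal is s0 times the fraction-weighted sum of the
    predictor columns built for the region's fiber direction, tensor, and
    parallel diffusivity; Rician noise of sd s0/snr is then applied.
    """
    grid = grid or DiameterGrid()
    lib = build_library(scheme, region.direction, region.tensor,
                        region.parallel_diffusivity, grid=grid, d_csf=d_csf)
    pi = discretize_add(region.diameter, grid)
    attenuation = (region.a_f * lib.matrix[:, 0]
                   + region.a_h * lib.matrix[:, 1]
                   + region.a_r * (lib.matrix[:, 2:] @ pi))
    signal = s0 * attenuation
    if np.isfinite(snr):
        if rng is None:
            raise ValueError("noisy simulation needs an rng")
        signal = add_rician_noise(signal, s0 / snr, rng)
    truth = {
        "a_f": region.a_f, "a_h": region.a_h, "a_r": region.a_r,
        "pi": pi,
        "mean_diameter": float((pi * grid.diameters).sum()),
        "direction": region.direction,
    }
    return signal, truth


def simulate_phantom(spec: PhantomSpec,
                     grid: DiameterGrid | None = None,
                     d_csf: float = DEFAULT_D_CSF
                     ) -> tuple[DwiDataset, dict]:
    """Simulate a full 4-D dataset from a PhantomSpec.

    Returns the dataset and a ground-truth dict with per-voxel
    ``mean_diameter``, fraction maps, and the region map. All randomness
    flows from ``spec.seed``; the same spec reproduces the dataset
    bit-identically.
    """
    grid = grid or DiameterGrid()
    scheme = scheme_preset(spec.protocol)
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    signal = np.empty(shape + (len(scheme),))
    truth_mean = np.full(shape, np.nan)
    truth_af = np.full(shape, np.nan)
    truth_ah = np.full(shape, np.nan)
    truth_ar = np.full(shape, np.nan)

    # noise-free attenuation is identical within a region: simulate once per
    # region, then apply voxel-wise noise
    region_signals = {}
    region_truth = {}
    for ridx, region in enumerate(spec.regions):
        sig, truth = simulate_voxel(region, scheme, grid, rng=None,
                                    snr=np.inf, s0=spec.s0, d_csf=d_csf)
        region_signals[ridx] = sig
        region_truth[ridx] = truth
    for vox in np.ndindex(shape):
        ridx = int(spec.region_map[vox])
        sig = region_signals[ridx]
        if np.isfinite(spec.snr):
            sig = add_rician_noise(sig, spec.s0 / spec.snr, rng)
        signal[vox] = sig
        t = region_truth[ridx]
        truth_mean[vox] = t["mean_diameter"]
        truth_af[vox] = t["a_f"]
        truth_ah[vox] = t["a_h"]
        truth_ar[vox] = t["a_r"]

    dataset = DwiDataset(signal=signal, affine=spec.affine, scheme=scheme,
                         mask=np.ones(shape, dtype=bool))
    truth = {"mean_diameter": truth_mean, "a_f": truth_af, "a_h": truth_ah,
             "a_r": truth_ar, "region_map": spec.region_map.copy(),
             "grid": grid}
    return dataset, truth


#: per-section gamma ADD means for the callosal phantom, um (synthetic
#: choices emulating the genu/splenium < body caliber ordering, not
#: measured values); gamma shape parameter fixed at 4
CC_SECTION_MEANS = {"Genu": 3.0, "Anterior Body": 6.0, "Mid Body": 7.0,
                    "Posterior Body": 6.0, "Splenium": 3.5}
CC_GAMMA_SHAPE = 4.0


def simulate_cc_phantom(shape: tuple = (4, 40, 3),
                        protocol: str = "hcp",
                        snr: float = np.inf,
                        seed: int = 0,
                        section_means: dict | None = None,
                        grid: DiameterGrid | None = None
                        ) -> tuple[DwiDataset, dict, np.ndarray]:
    """Midsagittal corpus-callosum slab with five Witelson-style sections.

    The anterior-posterior axis is the second voxel axis (+y anterior);
    fibers run left-right (x). Each section carries a gamma ADD whose mean
    follows the genu/splenium-small, body-large pattern. Returns
    (dataset, ground truth, midsagittal cc mask).
    """
    from axsi.connectome import SECTION_NAMES, witelson_sections

    section_means = section_means or CC_SECTION_MEANS
    cc_mask = np.ones(shape, dtype=bool)
    labels = witelson_sections(cc_mask, ap_axis=1,
                               anterior_is_high_index=True)
    regions = []
    for name in SECTION_NAMES:
        mean = section_means[name]
        regions.append(RegionSpec(
            a_f=0.0, a_h=0.5, a_r=0.5,
            diameter=("gamma", CC_GAMMA_SHAPE, mean / CC_GAMMA_SHAPE),
            direction=np.array([1.0, 0.0, 0.0])))
    spec = PhantomSpec(shape=shape, regions=regions,
                       region_map=labels - 1, protocol=protocol,
                       snr=snr, seed=seed)
    dataset, truth = simulate_phantom(spec, grid=grid)
    truth["section_labels"] = labels
    truth["section_means"] = dict(section_means)
    return dataset, truth, cc_mask


def simulate_tractogram(shape: tuple, affine: np.ndarray,
                        n_streamlines: int, seed: int = 0,
                        axis: int = 0, step_mm: float = 1.0,
                        jitter_mm: float = 0.0) -> list[np.ndarray]:
    """Straight (optionally jittered) polylines spanning the volume.

    Streamlines run parallel to the given voxel axis at random in-volume
    offsets, in world mm. Exactly ``n_streamlines`` are returned.
    """
    rng = np.random.default_rng(seed)
    shape = np.asarray(shape)
    affine = np.asarray(affine, dtype=float)
    extent_vox = shape[axis] - 1
    start_vox = np.zeros(3)
    streamlines = []
    for _ in range(n_streamlines):
        off = rng.uniform(0, shape - 1)
        start_vox = off.copy()
        start_vox[axis] = 0.0
        start_mm = affine[:3, :3] @ start_vox + affine[:3, 3]
        end_vox = start_vox.copy()
        end_vox[axis] = extent_vox
        end_mm = affine[:3, :3] @ end_vox + affine[:3, 3]
        length = np.linalg.norm(end_mm - start_mm)
        n_pts = max(int(np.ceil(length / step_mm)) + 1, 2)
        t = np.linspace(0.0, 1.0, n_pts)[:, None]
        pts = start_mm[None, :] * (1 - t) + end_mm[None, :] * t
        if jitter_mm > 0:
            pts = pts + rng.normal(0, jitter_mm, size=pts.shape)
        streamlines.append(pts)
    return streamlines
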