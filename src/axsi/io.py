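"""NIfTI volume and streamline I/O.

All other modules consume the in-memory types defined here; nothing else in
the package parses files. Streamline points are always exposed in world
(scanner RAS, mm) coordinates regardless of the on-disk dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel.streamlines import Tractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from axsi.scheme import GradientScheme

log = logging.getLogger(__name__)


class DimensionError(ValueError):
    """Input volume has the wrong number of dimensions."""


class StreamlineFormatError(ValueError):
    """Streamline file is neither TCK nor TRK."""


@dataclass
class DwiDataset:
    """A 4-D diffusion-weighted acquisition plus its gradient scheme.

    ``signal`` is (x, y, z, volume) with non-negative intensities; ``affine``
    maps voxel indices to world mm; ``mask`` selects voxels to fit.
    """

    signal: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise DimensionError(
                f"signal must be 4-D, got {self.signal.ndim}-D")
        if self.signal.shape[3] != len(self.scheme):
            raise ValueError(
                f"{self.signal.shape[3]} volumes but scheme has "
                f"{len(self.scheme)} entries")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.mask is None:
            self.mask = np.ones(self.signal.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.signal.shape[:3]:
            raise ValueError("mask shape does not match volume shape")

    @property
    def shape(self) -> tuple:
        return self.signal.shape[:3]


def read_dwi(nifti_path, scheme: GradientScheme, mask_path=None) -> DwiDataset:
    """Load a 4-D NIfTI and pair it with a validated gradient scheme."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DimensionError(
            f"{nifti_path}: expected a 4-D DWI volume, got {data.ndim}-D")
    mask = None
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        mask = np.asarray(mimg.dataobj) > 0
    return DwiDataset(signal=data, affine=img.affine, scheme=scheme, mask=mask)


def write_dwi(dataset: DwiDataset, nifti_path, mask_path=None) -> None:
    nib.save(nib.Nifti1Image(dataset.signal, dataset.affine), str(nifti_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8),
                                 dataset.affine), str(mask_path))


def write_map(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a scalar (or vector-per-voxel) map as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine),
             str(path))


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def read_streamlines(path) -> list[np.ndarray]:
    """Read a TCK or TRK file as a list of (n_points, 3) world-mm arrays.

    nibabel applies each dialect's internal offsets and returns points in
    scanner RAS mm for both formats.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        log.warning("empty streamline file %s", path)
        return []
    if TckFile.is_correct_format(str(path)):
        tf = TckFile.load(str(path))
    elif TrkFile.is_correct_format(str(path)):
        tf = TrkFile.load(str(path))
    else:
        raise StreamlineFormatError(
            f"{path}: not recognized as TCK or TRK")
    streamlines = [np.asarray(s, dtype=float) for s in tf.streamlines]
    if not streamlines:
        log.warning("no streamlines in %s", path)
    return streamlines


def write_streamlines(streamlines, path, affine: np.ndarray | None = None,
                      shape: tuple | None = None) -> None:
    """Write world-mm streamlines as TCK (default) or TRK by extension.

    TRK requires the reference grid (``affine`` and ``shape``) to build its
    header; TCK is header-light and needs neither.
    """
    path = Path(path)
    tractogram = Tractogram([np.asarray(s, dtype=np.float32)
                             for s in streamlines],
                            affine_to_rasmm=np.eye(4))
    if path.suffix.lower() == ".trk":
        if affine is None or shape is None:
            raise ValueError("TRK output needs affine and shape")
        header = {
            "voxel_to_rasmm": np.asarray(affine, dtype=np.float32),
            "voxel_sizes": np.linalg.norm(np.asarray(affine)[:3, :3],
                                          axis=0).astype(np.float32),
            "dimensions": np.asarray(shape, dtype=np.int16),
        }
        TrkFile(tractogram, header).save(str(path))
    else:
        TckFile(tractogram).save(str(path))
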