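"""Volumetric data model, NIfTI I/O, and hemisphere partitioning.

All downstream analysis operates on three small container types:

``ScalarVolume``
    A single 3D parameter map (ADC, CBF, CBV, MTT, Tmax, or a
    contralateral-normalized relative map) together with its voxel
    spacing and units.  Background / unanalyzable voxels are flagged
    as NaN ("invalid") rather than silently set to zero, so division
    never manufactures spurious values.
``BinaryMask``
    A boolean region-of-interest on the same grid as its parent map.
``HemispherePartition``
    The brain mask split at the mid-sagittal grid plane into left and
    right halves, with the affected (stroke) side recorded.

Coordinate convention: 0-based voxel indices, axis order
(x = left-right, y = anterior-posterior, z = inferior-superior).
All masks live on the grid of the baseline ADC volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "BinaryMask",
    "HemispherePartition",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "split_hemispheres",
    "brain_mask_from_adc",
]

# Physiologic ADC range used for background rejection (mm^2/s): values
# outside (1e-6, 3500e-6) cannot be brain tissue or CSF.
ADC_BACKGROUND_LOW = 1e-6
ADC_BACKGROUND_HIGH = 3500e-6


@dataclass
class ScalarVolume:
    """One 3D scalar map on a regular voxel grid.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel values; NaN marks invalid (background) voxels.
    spacing_mm : ndarray, shape (3,)
        Strictly positive voxel edge lengths in millimetres.
    units : str
        Free-text physical units, e.g. ``"mm^2/s"``, ``"s"``,
        ``"dimensionless"``.
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"ScalarVolume requires a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        if not np.all(np.isfinite(self.spacing_mm)) or np.any(self.spacing_mm <= 0):
            raise ValueError(f"spacing must be finite and strictly positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing_mm)) / 1000.0

    def valid(self) -> np.ndarray:
        """Boolean array of voxels carrying a finite value."""
        return np.isfinite(self.values)

    def like(self, values: np.ndarray, units: str | None = None) -> "ScalarVolume":
        """New volume on this grid with different values."""
        return ScalarVolume(values, self.spacing_mm.copy(), self.units if units is None else units)


@dataclass
class BinaryMask:
    """Boolean ROI mask on the grid of a parent :class:`ScalarVolume`."""

    values: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError(f"BinaryMask requires a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def volume_ml(self) -> float:
        return self.count * float(np.prod(self.spacing_mm)) / 1000.0

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & other.values, self.spacing_mm)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values | other.values, self.spacing_mm)

    def __sub__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.values & ~other.values, self.spacing_mm)


@dataclass
class HemispherePartition:
    """Brain mask split at the mid-sagittal grid plane.

    The split plane is the midpoint of the left-right (first) axis;
    phantoms are generated head-centred so no midline estimation is
    required.  ``affected_side`` names the hemisphere containing the
    lesion; :meth:`contralateral` returns the other half, which serves
    as the normalization reference for relative maps.
    """

    left: BinaryMask
    right: BinaryMask
    affected_side: Literal["left", "right"]

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError(f"affected_side must be 'left' or 'right', got {self.affected_side!r}")
        if np.any(self.left.values & self.right.values):
            raise ValueError("hemisphere masks overlap")

    @property
    def affected(self) -> BinaryMask:
        return self.left if self.affected_side == "left" else self.right

    @property
    def contralateral(self) -> BinaryMask:
        return self.right if self.affected_side == "left" else self.left

    @property
    def brain(self) -> BinaryMask:
        return self.left | self.right


def _affine_from_spacing(spacing_mm: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def read_volume(path: str | Path) -> ScalarVolume:
    """Read a 3D NIfTI-1 volume.

    4D files are rejected here; dynamic DSC series are loaded through
    :func:`perfmismatch.phantom.read_dynamic_series`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"4D not allowed: {path} has shape {data.shape}; use a 3D volume")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
        raise ValueError(f"non-finite or non-positive voxel spacing in {path}: {spacing}")
    return ScalarVolume(np.asarray(data, dtype=np.float64), spacing)


def write_volume(vol: ScalarVolume, path: str | Path, dtype=np.float32) -> Path:
    """Write a ScalarVolume as NIfTI-1; float32 by default."""
    path = Path(path)
    img = nib.Nifti1Image(vol.values.astype(dtype), _affine_from_spacing(vol.spacing_mm))
    img.header.set_zooms(tuple(vol.spacing_mm))
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, spacing_mm: np.ndarray | None = None) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.values > 0.5, vol.spacing_mm if spacing_mm is None else spacing_mm)


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Masks are stored as uint8 {0,1}."""
    path = Path(path)
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from_spacing(mask.spacing_mm))
    img.header.set_zooms(tuple(mask.spacing_mm))
    nib.save(img, str(path))
    return path


def split_hemispheres(
    brain: BinaryMask, affected_side: Literal["left", "right"]
) -> HemispherePartition:
    """Split a brain mask at the mid-sagittal grid plane.

    The first (left-right) axis is cut at its midpoint: voxels with
    x < nx//2 belong to the left half, the rest to the right.  The two
    halves are disjoint and their union is the brain mask.
    """
    if brain.count == 0:
        raise ValueError("empty brain mask")
    nx = brain.shape[0]
    mid = nx // 2
    left = np.zeros(brain.shape, dtype=bool)
    left[:mid] = True
    left_mask = BinaryMask(brain.values & left, brain.spacing_mm)
    right_mask = BinaryMask(brain.values & ~left, brain.spacing_mm)
    return HemispherePartition(left_mask, right_mask, affected_side)


def brain_mask_from_adc(
    adc: ScalarVolume,
    low: float = ADC_BACKGROUND_LOW,
    high: float = ADC_BACKGROUND_HIGH,
) -> BinaryMask:
    """Brain mask from an ADC map by physiologic-range thresholding.

    Voxels with ADC inside the open interval (``low``, ``high``) are
    brain (parenchyma or CSF); everything else — air, bone, the
    clamped-to-zero background — is rejected.  This is deliberately
    simple plumbing: phantoms carry a ground-truth brain mask and this
    function must reproduce it.
    """
    vals = adc.values
    mask = np.isfinite(vals) & (vals > low) & (vals < high)
    if not mask.any():
        raise ValueError("all-background ADC volume: no voxels in physiologic range")
    return BinaryMask(mask, adc.spacing_mm)
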