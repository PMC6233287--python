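"""PET volumes, binary masks and regions of interest.

Containers for 3D SUV images (:class:`ScalarVolume`), segmentations
(:class:`BinaryMask`) and axis-aligned regions of interest (:class:`VOI`),
together with NIfTI I/O and the elementary measurements every thresholding
method builds on: voxel-counted volume in cc and the SUVmax within a VOI.

Volumes are assumed to be already calibrated to SUV (the dimensionless
g/mL convention). Converting raw activity to SUV — injected dose, body
weight, decay correction — is an acquisition-side responsibility and is
deliberately not handled here.

Indexing is 0-based throughout and VOIs are half-open boxes
``[lower, upper)``, matching numpy slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "ScalarVolume",
    "BinaryMask",
    "VOI",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_volume_cc",
    "suv_max",
]

Index3 = Tuple[int, int, int]


class GridMismatchError(ValueError):
    """Two lattices that must share shape and spacing do not."""


def _as_spacing(spacing) -> Tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(s)}")
    if any(not np.isfinite(v) or v <= 0 for v in s):
        raise ValueError(f"spacing must be positive and finite, got {s}")
    return s


@dataclass
class ScalarVolume:
    """A 3D lattice of SUV values with physical voxel spacing.

    Parameters
    ----------
    voxels:
        3D float array of SUV values (dimensionless, g/mL convention).
        Must be finite and non-negative.
    spacing:
        Voxel size in mm along each axis.
    origin:
        Physical offset of the first voxel in mm (carried through I/O,
        not used by any measurement).
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D voxel data, got {self.voxels.ndim}D")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel data contains NaN or infinite values")
        if np.any(self.voxels < 0):
            raise ValueError("SUV values must be non-negative")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def shape(self) -> Index3:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A boolean lattice on the same grid as its parent :class:`ScalarVolume`."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D mask data, got {self.voxels.ndim}D")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> Index3:
        return self.voxels.shape

    @property
    def volume_cc(self) -> float:
        return mask_volume_cc(self)

    def same_grid(self, other: "BinaryMask | ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass(frozen=True)
class VOI:
    """Half-open axis-aligned box of voxel indices: ``lower <= i < upper``."""

    lower: Index3
    upper: Index3

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lower)
        up = tuple(int(v) for v in self.upper)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        if any(l < 0 for l in lo) or any(l >= u for l, u in zip(lo, up)):
            raise ValueError(f"invalid VOI bounds lower={lo}, upper={up}")

    @classmethod
    def full(cls, shape: Index3) -> "VOI":
        return cls((0, 0, 0), tuple(int(s) for s in shape))

    def validate(self, shape: Index3) -> None:
        if any(u > s for u, s in zip(self.upper, shape)):
            raise ValueError(f"VOI upper bound {self.upper} exceeds lattice shape {shape}")

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))

    @property
    def shape(self) -> Index3:
        return tuple(u - l for l, u in zip(self.lower, self.upper))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def volume_cc(self, spacing) -> float:
        return self.n_voxels * float(np.prod(_as_spacing(spacing))) / 1000.0


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path) -> ScalarVolume:
    """Read a 3D SUV volume from a NIfTI file.

    Fails rather than silently defaulting metadata: the file must carry 3D
    data, strictly positive voxel spacing and finite, non-negative voxels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: voxel data contains NaN or infinite values")
    return ScalarVolume(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a :class:`ScalarVolume` to NIfTI (float64, spacing in the affine)."""
    img = nib.Nifti1Image(vol.voxels.astype(np.float64), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_mask(path, *, spacing=None) -> BinaryMask:
    """Read a 0/1 NIfTI volume as a :class:`BinaryMask`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D mask, got shape {data.shape}")
    zooms = spacing if spacing is not None else img.header.get_zooms()[:3]
    return BinaryMask(voxels=data > 0, spacing=tuple(float(z) for z in zooms))


def write_mask(mask: BinaryMask, path, *, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a :class:`BinaryMask` to NIfTI as a 0/1 uint8 volume."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing, origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def mask_volume_cc(mask: BinaryMask) -> float:
    """Volume of a mask in cc: true-voxel count x voxel volume (mm^3) / 1000."""
    return int(np.count_nonzero(mask.voxels)) * float(np.prod(mask.spacing)) / 1000.0


def suv_max(vol: ScalarVolume, voi: VOI) -> Tuple[float, Index3]:
    """Maximum single-voxel SUV within a VOI and one index attaining it.

    The hottest voxel is reported as-is (no SUVpeak neighbourhood
    averaging). Ties resolve to the lowest lexicographic index, which is
    what C-order ``argmax`` returns.
    """
    voi.validate(vol.shape)
    sub = vol.voxels[voi.slices()]
    if sub.size == 0:
        raise ValueError("empty VOI")
    flat = int(np.argmax(sub))
    local = np.unravel_index(flat, sub.shape)
    index = tuple(int(l + o) for l, o in zip(voi.lower, local))
    return float(sub[local]), index
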