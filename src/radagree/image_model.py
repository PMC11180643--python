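"""Domain types for 3-D volumes and masks with NIfTI-1 I/O.

Arrays are indexed ``(i, j, k)`` with ``i`` the fastest-varying NIfTI axis;
spacing and origin vectors follow the same order.  Only axis-aligned
orientations (diagonal affines, up to sign flips) are accepted: oblique
volumes are rejected rather than silently reoriented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "ImageVolume",
    "ROIMask",
    "PatientRecord",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "GridMismatchError",
]

#: Tolerance (mm) for geometric consistency checks between a mask and its volume.
GEOM_TOL = 1e-6


class Modality(str, Enum):
    CT = "CT"
    MRI = "MRI"


class GridMismatchError(ValueError):
    """Mask and reference volume do not share shape/spacing/origin."""


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    return arr


@dataclass
class ImageVolume:
    """A 3-D scalar grid with physical geometry and a modality tag.

    World coordinate of voxel index ``(i, j, k)`` is
    ``origin + (i, j, k) * spacing`` (identity orientation).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    modality: Modality = Modality.CT

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {tuple(self.spacing)}")
        self.origin = _as_vec3(self.origin, "origin")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_world(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one index axis."""
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def same_grid(self, other: "ImageVolume | ROIMask", tol: float = GEOM_TOL) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class ROIMask:
    """Binary 3-D grid aligned to an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask data must be 3-D, got shape {arr.shape}")
        self.data = arr != 0
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing components must be > 0, got {tuple(self.spacing)}")
        self.origin = _as_vec3(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def check_against(self, reference: ImageVolume, tol: float = GEOM_TOL) -> None:
        """Raise :class:`GridMismatchError` naming the first mismatching field."""
        if self.shape != reference.shape:
            raise GridMismatchError(
                f"shape mismatch: mask {self.shape} vs volume {reference.shape}"
            )
        if not np.allclose(self.spacing, reference.spacing, atol=tol):
            raise GridMismatchError(
                f"spacing mismatch: mask {tuple(self.spacing)} vs volume "
                f"{tuple(reference.spacing)}"
            )
        if not np.allclose(self.origin, reference.origin, atol=tol):
            raise GridMismatchError(
                f"origin mismatch: mask {tuple(self.origin)} vs volume "
                f"{tuple(reference.origin)}"
            )


@dataclass
class PatientRecord:
    """One patient's paired CT and MRI volume/mask data."""

    patient_id: str
    ct: tuple[ImageVolume, ROIMask]
    mri: tuple[ImageVolume, ROIMask]

    def __post_init__(self) -> None:
        for name, (vol, mask) in (("ct", self.ct), ("mri", self.mri)):
            mask.check_against(vol)
            if name == "ct" and vol.modality is not Modality.CT:
                raise ValueError("ct pair must carry modality CT")
            if name == "mri" and vol.modality is not Modality.MRI:
                raise ValueError("mri pair must carry modality MRI")

    def pair(self, modality: Modality) -> tuple[ImageVolume, ROIMask]:
        return self.ct if Modality(modality) is Modality.CT else self.mri


def _affine_geometry(affine: np.ndarray, path) -> tuple[np.ndarray, np.ndarray]:
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-6:
        raise ValueError(
            f"{path}: non-axis-aligned orientation; only diagonal affines are supported"
        )
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: degenerate affine (zero spacing)")
    return spacing, affine[:3, 3].astype(float)


def read_volume(path, modality: Modality = Modality.CT) -> ImageVolume:
    """Load a 3-D NIfTI-1 volume; header scale/slope is applied by nibabel."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: non-3-D image (ndim={img.ndim})")
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    spacing, origin = _affine_geometry(img.affine, path)
    return ImageVolume(data=data, spacing=spacing, origin=origin, modality=modality)


def read_mask(path, reference: ImageVolume) -> ROIMask:
    """Load a mask and verify its grid against *reference*.

    Any nonzero label is foreground.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: non-3-D image (ndim={img.ndim})")
    spacing, origin = _affine_geometry(img.affine, path)
    mask = ROIMask(
        data=np.asanyarray(img.dataobj) != 0, spacing=spacing, origin=origin
    )
    mask.check_against(reference)
    return mask


def _affine_of(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    affine[:3, 3] = origin
    return affine


def write_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.data, dtype=np.float64), _affine_of(vol.spacing, vol.origin)
    )
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path) -> None:
    # masks are stored unsigned 8-bit; any nonzero value is foreground
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_of(mask.spacing, mask.origin)
    )
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
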