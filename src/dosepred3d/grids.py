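"""Volumetric containers shared by every stage of the pipeline.

A :class:`VolumeGrid` is a 3D scalar field (CT intensity, normalized units,
or dose in Gy) on a regular grid described by per-axis voxel spacing and a
world-space origin.  Voxel ``(i, j, k)`` sits at world coordinate
``origin + index * spacing`` (node-centered convention).  A
:class:`StructureMask` is a named binary field on the same geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "StructureMask",
    "GeometryError",
    "read_nifti_volume",
    "read_nifti_mask",
]


class GeometryError(ValueError):
    """Raised when two grids that must share a geometry do not."""


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class VolumeGrid:
    """A 3D scalar field with spacing/origin metadata.

    Parameters
    ----------
    values:
        3D array of scalars (HU, normalized units, or Gy).
    spacing_mm:
        Per-axis voxel spacing in millimetres; must be positive.
    origin_mm:
        World coordinate of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeGrid | StructureMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=atol)
        )

    def require_same_geometry(self, other: "VolumeGrid | StructureMask") -> None:
        if not self.same_geometry(other):
            raise GeometryError(
                f"geometry mismatch: {self.shape}/{self.spacing_mm}/{self.origin_mm} vs "
                f"{other.shape}/{other.spacing_mm}/{other.origin_mm}"
            )

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        return replace(self, values=np.asarray(values))

    # --- NIfTI round trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([*self.spacing_mm, 1.0])
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class StructureMask:
    """A named binary mask sharing a :class:`VolumeGrid` geometry."""

    name: str
    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {vals.shape}")
        uniq = np.unique(vals)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask {self.name!r} must be binary, found values {uniq[:5]}")
        self.values = vals.astype(np.uint8)
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def same_geometry(self, other: "VolumeGrid | StructureMask", atol: float = 1e-6) -> bool:
        return VolumeGrid.same_geometry(self, other, atol=atol)  # type: ignore[arg-type]

    def require_same_geometry(self, other: "VolumeGrid | StructureMask") -> None:
        VolumeGrid.require_same_geometry(self, other)  # type: ignore[arg-type]

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def boolean(self) -> np.ndarray:
        return self.values.astype(bool)

    def as_grid(self) -> VolumeGrid:
        return VolumeGrid(self.values.astype(np.float32), self.spacing_mm, self.origin_mm)

    def to_nifti(self) -> nib.Nifti1Image:
        return self.as_grid().to_nifti()

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


def _geometry_from_nifti(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    affine = img.affine
    spacing = tuple(float(x) for x in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(x) for x in affine[:3, 3])
    return spacing, origin


def read_nifti_volume(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    spacing, origin = _geometry_from_nifti(img)
    return VolumeGrid(np.asarray(img.dataobj, dtype=np.float32), spacing, origin)


def read_nifti_mask(path: str | Path, name: str) -> StructureMask:
    img = nib.load(str(path))
    spacing, origin = _geometry_from_nifti(img)
    vals = np.asarray(img.dataobj)
    return StructureMask(name, (vals > 0.5).astype(np.uint8), spacing, origin)
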