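"""Voxel containers: scalar volumes and binary masks on an axis-aligned grid.

World coordinates follow ``x_world = origin + index * spacing`` per axis, in a
fixed right-handed mm frame (no direction matrix; CBCT-like stand-in data are
generated in this convention and I/O preserves it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

__all__ = ["VoxelVolume", "BinaryMask"]


def _validate_grid(data: np.ndarray, spacing, origin):
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 2:
        raise ValueError(f"grid must be >= 2 voxels per axis, got {data.shape}")
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    origin = np.asarray(origin, dtype=float).reshape(3)
    return spacing, origin


@dataclass
class VoxelVolume:
    """3D scalar grid (HU-like units) with physical spacing and origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing, self.origin = _validate_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self):
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_axis(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing[axis]

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, point) -> np.ndarray:
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T).astype(np.float32))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image) -> "VoxelVolume":
        data = sitk.GetArrayFromImage(img).T
        return cls(np.ascontiguousarray(data), np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()))

    def allclose(self, other: "VoxelVolume", atol: float = 1e-5) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=1e-9)
            and np.allclose(self.origin, other.origin, atol=1e-6)
            and np.allclose(self.data, other.data, atol=atol)
        )


@dataclass
class BinaryMask:
    """Boolean occupancy on the same grid as its source volume."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.spacing, self.origin = _validate_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    def grid_compatible(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(self.data.T).astype(np.uint8))
        img.SetSpacing(tuple(self.spacing))
        img.SetOrigin(tuple(self.origin))
        return img

    @classmethod
    def like(cls, volume: VoxelVolume, data: np.ndarray) -> "BinaryMask":
        if data.shape != volume.shape:
            raise ValueError("mask shape does not match the source volume")
        return cls(data, volume.spacing.copy(), volume.origin.copy())
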