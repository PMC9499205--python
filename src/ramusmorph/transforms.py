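"""Proper rigid (rotation + translation) transforms in millimetre space.

A :class:`RigidTransform` maps points ``x`` to ``R @ x + t`` with ``R`` a
proper orthonormal rotation (``det R = +1``).  Both registration engines and
the synthetic ground truth use this type, so composition/inversion round-trips
must be numerically tight (see the property tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "NonRigidMatrixError", "random_rigid", "rotation_angle_deg"]

_ORTHO_TOL = 1e-8


class NonRigidMatrixError(ValueError):
    """Raised when a 3x3 matrix is not a proper rotation within tolerance."""


def _check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise NonRigidMatrixError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.linalg.norm(rotation.T @ rotation - np.eye(3))
    if err > tol:
        raise NonRigidMatrixError(f"matrix is not orthonormal (||R^T R - I|| = {err:.3g})")
    if np.linalg.det(rotation) < 0:
        raise NonRigidMatrixError("matrix has det = -1 (reflection, not a rotation)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid transform ``x -> R x + t`` (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise NonRigidMatrixError(f"expected a 4x4 matrix, got {matrix.shape}")
        return cls(matrix[:3, :3], matrix[:3, 3])

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0), center=None
    ) -> "RigidTransform":
        """Rotation about ``axis`` by ``angle_deg`` (optionally about ``center``)."""
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
        t = np.asarray(translation, dtype=float)
        if center is not None:
            center = np.asarray(center, dtype=float)
            t = t + center - rot @ center
        return cls(rot, t)

    @property
    def matrix(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (
            np.linalg.norm(self.rotation - np.eye(3)) < tol
            and np.linalg.norm(self.translation) < tol
        )


def rotation_angle_deg(a: RigidTransform, b: RigidTransform | None = None) -> float:
    """Geodesic rotation angle of ``a`` (relative to ``b`` if given), degrees."""
    rot = a.rotation if b is None else a.rotation @ b.rotation.T
    return float(np.rad2deg(np.abs(Rotation.from_matrix(rot).magnitude())))


def random_rigid(
    rng: np.random.Generator,
    max_translation_mm: float = 5.0,
    max_rotation_deg: float = 10.0,
    center=None,
) -> RigidTransform:
    """Draw a uniform random rigid displacement within the given bounds."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_rotation_deg)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = direction * rng.uniform(0.0, max_translation_mm)
    return RigidTransform.from_axis_angle(axis, angle, translation, center=center)
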