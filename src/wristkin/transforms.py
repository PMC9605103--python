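"""Proper rigid transforms in 3-D (rotation + translation, millimetres).

A :class:`RigidTransform` maps points as ``x -> R @ x + t`` with ``R`` a
proper orthonormal matrix (``det R = +1``).  The class is closed under
composition and inversion and is the currency passed between the
registration, frame and helical-axis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "rotation_about_axis", "random_rotation"]

_ORTHO_TOL = 1e-9


def _check_rotation(rotation: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.abs(rotation.T @ rotation - np.eye(3)).max()
    if err > tol:
        raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
    if np.linalg.det(rotation) < 0:
        raise ValueError("rotation has determinant -1 (improper; reflections are not rigid)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (row-major)."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return RigidTransform(matrix[:3, :3], matrix[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        out = np.eye(4)
        out[:3, :3] = self.rotation
        out[:3, 3] = self.translation
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of points (or a single 3-vector)."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() < tol
            and np.abs(self.translation - other.translation).max() < tol
        )


def rotation_about_axis(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``direction`` through the origin."""
    n = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("rotation axis direction must be nonzero")
    n = n / norm
    theta = np.radians(angle_deg)
    k = np.array([[0.0, -n[2], n[1]], [n[2], 0.0, -n[0]], [-n[1], n[0], 0.0]])
    return np.eye(3) + np.sin(theta) * k + (1.0 - np.cos(theta)) * (k @ k)


def random_rotation(rng: np.random.Generator, max_angle_deg: float = 180.0) -> np.ndarray:
    """Uniform random axis, angle uniform in [0, max_angle_deg]."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return rotation_about_axis(v, rng.uniform(0.0, max_angle_deg))
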