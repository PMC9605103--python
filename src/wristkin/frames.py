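"""Anatomical coordinate systems: the radius-based frame and inertial bone frames.

The radius frame anchors all kinematic reporting.  Its X-axis is the
radial long axis (the smallest-moment principal inertial axis of the
radius, pointing distally toward the epicondyle landmark, the pro-/
supination axis); Y is the unit component of (styloid − centroid)
orthogonal to X (the flexion-extension axis); Z = X × Y aims palmarly
(the radial-ulnar deviation axis).  The origin is the projection of the
distal epicondyle landmark onto the X-axis line through the centroid.

Carpal bones have no reliable landmarks, so each bone's frame is its
centroid plus its sign-unified principal inertial axes.

Left hands are mirror images of right hands; to share one sign
convention (flexion +, radial deviation +, pronation +), left-hand
geometry is reflected across the sagittal (Y = 0) plane of the radius
frame before kinematic analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mesh import TriMesh, mass_properties, unify_axis_signs
from .transforms import RigidTransform

__all__ = [
    "AnatomicalFrame",
    "Landmarks",
    "radius_frame",
    "bone_frame",
    "canonical_axis_signs",
    "mirror_points",
    "mirror_mesh",
    "load_landmarks",
    "save_landmarks",
]


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin (mm) plus right-handed orthonormal axes."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        for name in ("x_axis", "y_axis", "z_axis"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        a = self.axes
        if np.abs(a.T @ a - np.eye(3)).max() > 1e-9:
            raise ValueError("frame axes are not orthonormal")
        if np.abs(np.cross(self.x_axis, self.y_axis) - self.z_axis).max() > 1e-9:
            raise ValueError("frame is not right-handed (z != x cross y)")

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix with columns x, y, z."""
        return np.column_stack([self.x_axis, self.y_axis, self.z_axis])

    @staticmethod
    def from_axes(origin: np.ndarray, axes: np.ndarray) -> "AnatomicalFrame":
        axes = np.asarray(axes, dtype=float)
        return AnatomicalFrame(origin, axes[:, 0], axes[:, 1], np.cross(axes[:, 0], axes[:, 1]))

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World points -> frame coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes

    def to_world(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.axes.T + self.origin

    def direction_to_local(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v, dtype=float) @ self.axes

    def transformed(self, transform: RigidTransform) -> "AnatomicalFrame":
        r = transform.rotation
        return AnatomicalFrame(
            transform.apply(self.origin), r @ self.x_axis, r @ self.y_axis, r @ self.z_axis
        )


@dataclass(frozen=True)
class Landmarks:
    """Manually picked radius landmarks, same space as the meshes (mm)."""

    styloid: np.ndarray
    distal_epicondyle: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "styloid", np.asarray(self.styloid, dtype=float).reshape(3))
        object.__setattr__(
            self, "distal_epicondyle", np.asarray(self.distal_epicondyle, dtype=float).reshape(3)
        )

    def validate_against(self, radius: TriMesh) -> None:
        """Both points must lie within 2x the radius bounding box."""
        lo, hi = radius.bounds
        center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        for name, p in (("styloid", self.styloid), ("distal_epicondyle", self.distal_epicondyle)):
            if np.any(np.abs(p - center) > 2.0 * half + 1e-9):
                raise ValueError(f"landmark {name} lies outside 2x the radius bounding box")

    def transformed(self, transform: RigidTransform) -> "Landmarks":
        return Landmarks(transform.apply(self.styloid), transform.apply(self.distal_epicondyle))


def load_landmarks(path: str | Path) -> Landmarks:
    data = json.loads(Path(path).read_text())
    return Landmarks(np.asarray(data["styloid"]), np.asarray(data["distal_epicondyle"]))


def save_landmarks(marks: Landmarks, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(
        json.dumps(
            {
                "styloid": marks.styloid.tolist(),
                "distal_epicondyle": marks.distal_epicondyle.tolist(),
            },
            indent=2,
        )
    )
    return path


def radius_frame(radius: TriMesh, marks: Landmarks) -> AnatomicalFrame:
    """Construct the radius-based anatomical frame from the mesh + landmarks."""
    marks.validate_against(radius)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transverse-moment degeneracy is fine here
        props = mass_properties(radius)
    # long axis = smallest principal moment (last column, moments sorted descending)
    x = props.principal_axes[:, 2].copy()
    gap = (props.principal_moments[1] - props.principal_moments[2]) / props.principal_moments[0]
    if gap < 1e-6:
        raise ValueError("radius mesh is near-isotropic; long axis is ambiguous")
    towards_distal = marks.distal_epicondyle - props.centroid
    if abs(float(x @ towards_distal)) < 1e-9:
        raise ValueError("epicondyle landmark does not resolve the distal direction")
    if float(x @ towards_distal) < 0:
        x = -x
    radial = marks.styloid - props.centroid
    y = radial - (radial @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("styloid landmark is collinear with the long axis; Y undefined")
    y /= ny
    z = np.cross(x, y)
    origin = props.centroid + float((marks.distal_epicondyle - props.centroid) @ x) * x
    return AnatomicalFrame(origin, x, y, z)


def canonical_axis_signs(axes: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Default sign fix without a reference: first nonzero component of each
    axis made positive, then right-handedness restored on the last axis."""
    axes = np.asarray(axes, dtype=float).copy()
    for i in range(3):
        col = axes[:, i]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if nz.size and col[nz[0]] < 0:
            axes[:, i] = -col
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def bone_frame(bone: TriMesh, reference_frame: np.ndarray | None = None) -> AnatomicalFrame:
    """Inertial frame of a carpal bone: centroid origin, principal axes.

    With ``reference_frame`` (3x3, e.g. the same bone's neutral-position
    frame) the axis signs are unified against it; otherwise the canonical
    sign convention applies.
    """
    props = mass_properties(bone)
    if reference_frame is not None:
        axes = unify_axis_signs(props.principal_axes, np.asarray(reference_frame, dtype=float))[0]
    else:
        axes = canonical_axis_signs(props.principal_axes)
    return AnatomicalFrame.from_axes(props.centroid, axes)


def mirror_points(points: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Reflect points across the plane through ``origin`` with unit ``normal``."""
    points = np.asarray(points, dtype=float)
    n = np.asarray(normal, dtype=float).reshape(3)
    n = n / np.linalg.norm(n)
    single = points.ndim == 1
    pts = np.atleast_2d(points)
    d = (pts - origin) @ n
    out = pts - 2.0 * np.outer(d, n)
    return out[0] if single else out


def mirror_mesh(mesh: TriMesh, origin: np.ndarray, normal: np.ndarray) -> TriMesh:
    """Reflect a mesh across a plane, flipping face winding to keep outward normals."""
    return TriMesh(
        vertices=mirror_points(mesh.vertices, origin, normal),
        faces=mesh.faces[:, ::-1].copy(),
        process=False,
    )
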