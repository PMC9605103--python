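"""Triangle-mesh I/O and homogeneous-solid mass properties.

Bone surfaces are closed, consistently oriented triangle meshes in
millimetres (``trimesh.Trimesh`` is the in-memory container).  Treating
each bone as a homogeneous dense solid of unit density, the exact
per-tetrahedron (divergence-theorem) integrals give its volume, centroid
and centroidal inertia tensor; the eigenvectors of that tensor are the
principal inertial axes used as an intrinsic, landmark-free bone frame.

Principal axes are only defined up to sign.  :func:`unify_axis_signs`
resolves the four proper sign patterns of a frame against a reference
frame so that the same bone tracked across wrist positions keeps one
consistent coordinate system.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

__all__ = [
    "TriMesh",
    "InertialProperties",
    "load_mesh",
    "save_mesh",
    "mass_properties",
    "unify_axis_signs",
    "NearSymmetricWarning",
]

log = logging.getLogger(__name__)

# Alias: the package-wide triangle-mesh container.
TriMesh = trimesh.Trimesh

_SUPPORTED_SUFFIXES = {".stl", ".ply", ".off"}

# Relative gap below which two principal moments are treated as degenerate.
NEAR_SYMMETRIC_RTOL = 1e-6


class NearSymmetricWarning(UserWarning):
    """Two or more principal moments are (nearly) equal; axes are ill-conditioned."""


@dataclass(frozen=True)
class InertialProperties:
    """Homogeneous-solid mass properties of a closed surface (unit density).

    Attributes
    ----------
    volume : float
        Enclosed volume, mm^3.
    centroid : (3,) ndarray
        Centre of mass, mm.
    principal_moments : (3,) ndarray
        Centroidal principal moments of inertia, sorted descending.
    principal_axes : (3, 3) ndarray
        Orthonormal, det +1; column ``i`` is the axis of
        ``principal_moments[i]``.
    near_symmetric : bool
        True when moments are degenerate within ``NEAR_SYMMETRIC_RTOL``
        (axes then carry no shape information in the degenerate plane).
    """

    volume: float
    centroid: np.ndarray
    principal_moments: np.ndarray
    principal_axes: np.ndarray
    near_symmetric: bool = False

    def __post_init__(self) -> None:
        axes = np.asarray(self.principal_axes, dtype=float)
        if np.abs(axes.T @ axes - np.eye(3)).max() > 1e-9:
            raise ValueError("principal axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("principal axes must form a right-handed frame")
        m = np.asarray(self.principal_moments, dtype=float)
        if np.any(np.diff(m) > 1e-12 * max(1.0, abs(m[0]))):
            raise ValueError("principal moments must be sorted descending")


def load_mesh(path: str | Path) -> TriMesh:
    """Read an STL/PLY/OFF triangle mesh and repair a globally inverted orientation.

    Raises
    ------
    FileNotFoundError
        Missing file.
    ValueError
        Unsupported format or non-manifold surface (offending edges reported).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported mesh format {path.suffix!r}; expected STL, PLY or OFF")
    mesh = trimesh.load(path, process=False, force="mesh")
    mesh = TriMesh(
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        process=False,
    )
    if not mesh.is_watertight:
        # STL stores three vertices per facet; weld exact duplicates first
        welded = mesh.copy()
        welded.merge_vertices()
        if welded.is_watertight:
            mesh = welded
    if not mesh.is_watertight:
        # report edges not shared by exactly two faces
        edges = mesh.edges_sorted
        _, counts = np.unique(edges, axis=0, return_counts=True)
        bad = int(np.sum(counts != 2))
        raise ValueError(
            f"{path.name}: surface is not watertight ({bad} edges not shared by exactly 2 faces)"
        )
    if not mesh.is_winding_consistent:
        raise ValueError(f"{path.name}: face winding is not consistent")
    if mesh.volume < 0:
        # globally inverted: flip all faces so the signed volume is positive
        mesh.invert()
        log.info("repaired inverted orientation of %s", path.name)
    return mesh


def save_mesh(mesh: TriMesh, path: str | Path) -> Path:
    """Write a mesh; format from the suffix (.stl/.ply/.off). PLY is written ASCII."""
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".ply":
        path.write_bytes(mesh.export(file_type="ply", encoding="ascii"))
    else:
        mesh.export(path)
    return path


def mass_properties(mesh: TriMesh) -> InertialProperties:
    """Exact homogeneous-solid volume, centroid and principal inertial frame.

    Volume, centroid and the centroidal inertia tensor come from exact
    signed-tetrahedron integration over the faces; the principal frame is
    the eigendecomposition of the inertia tensor with moments sorted
    descending and the axes made right-handed.

    Raises
    ------
    ValueError
        Open (non-watertight) mesh — volume undefined — or (near) zero
        enclosed volume.
    """
    if not mesh.is_watertight:
        raise ValueError("mass properties require a watertight mesh (volume undefined)")
    volume = float(mesh.volume)
    if volume < 0:
        raise ValueError("mesh is inverted (negative signed volume); load via load_mesh")
    if volume < 1e-12:
        raise ValueError("mesh encloses (near) zero volume")
    centroid = np.asarray(mesh.center_mass, dtype=float)
    inertia = np.asarray(mesh.moment_inertia, dtype=float)  # centroidal, unit density
    inertia = (inertia + inertia.T) / 2.0
    moments, axes = np.linalg.eigh(inertia)  # ascending
    order = np.argsort(moments)[::-1]
    moments = moments[order]
    axes = axes[:, order]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    scale = max(abs(moments[0]), 1e-300)
    gaps = np.abs(np.diff(moments)) / scale
    near_symmetric = bool(np.any(gaps < NEAR_SYMMETRIC_RTOL))
    if near_symmetric:
        warnings.warn(
            "principal moments are nearly degenerate; axes in the degenerate "
            "plane are arbitrary",
            NearSymmetricWarning,
            stacklevel=2,
        )
    return InertialProperties(
        volume=volume,
        centroid=centroid,
        principal_moments=moments,
        principal_axes=axes,
        near_symmetric=near_symmetric,
    )


# the four column-sign patterns that keep det = +1, ordered by number of flips
_PROPER_SIGN_PATTERNS = (
    np.array([1.0, 1.0, 1.0]),
    np.array([1.0, -1.0, -1.0]),
    np.array([-1.0, 1.0, -1.0]),
    np.array([-1.0, -1.0, 1.0]),
)


def unify_axis_signs(
    frames: Sequence[np.ndarray] | np.ndarray,
    reference: np.ndarray,
    tie_tol: float = 1e-9,
) -> list[np.ndarray]:
    """Resolve the column-sign ambiguity of principal-axis frames.

    For each frame the proper sign pattern (an even number of column
    flips, so det stays +1) maximizing ``trace(reference.T @ frame)`` is
    applied: the choice closest to the reference orientation.  Ties —
    possible only for inputs 90°-symmetric w.r.t. the reference — are
    broken toward fewer flips, with a warning.
    """
    reference = np.asarray(reference, dtype=float)
    if np.abs(reference.T @ reference - np.eye(3)).max() > 1e-8:
        raise ValueError("reference frame is not orthonormal")
    if np.linalg.det(reference) < 0:
        raise ValueError("reference frame must have det +1")
    single = isinstance(frames, np.ndarray) and np.ndim(frames) == 2
    frame_list = [frames] if single else list(frames)
    out = []
    for frame in frame_list:
        frame = np.asarray(frame, dtype=float)
        if np.abs(frame.T @ frame - np.eye(3)).max() > 1e-8:
            raise ValueError("frame is not orthonormal")
        # trace(ref.T @ frame @ diag(s)) = sum_i s_i (ref[:,i] . frame[:,i])
        dots = np.einsum("ij,ij->j", reference, frame)
        scores = [float(signs @ dots) for signs in _PROPER_SIGN_PATTERNS]
        best = int(np.argmax(scores))
        ties = [i for i, s in enumerate(scores) if abs(s - scores[best]) <= tie_tol]
        if len(ties) > 1:
            warnings.warn(
                "sign unification is ambiguous (90°-symmetric frame); "
                "keeping the pattern with fewest flips",
                stacklevel=2,
            )
            best = min(ties)  # patterns are ordered by flip count
        out.append(frame * _PROPER_SIGN_PATTERNS[best])
    return out
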