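"""Helical (screw) axis extraction and anatomical angle decomposition.

Any proper rigid displacement equals a rotation about a unique spatial
line plus a translation along it (Chasles).  For each carpal bone the
displacement from the neutral wrist position to a given position is
formed from the bone's centroid + sign-unified principal inertial axes
("markers"), its helical axis extracted directly from the rotation
matrix, and the rotation additionally decomposed into intrinsic Cardan
angles about the radius frame's FE (Y), RUD (Z) and pro-/supination (X)
axes.

Sign conventions
----------------
The screw pair ``(n, theta)`` is intrinsically equivalent to
``(-n, -theta)``.  The ambiguity is resolved by orienting the axis
direction toward the motion's nominal radius axis (Y for FE, Z for RUD)
and keeping the right-hand-rule signed angle, so flexion and radial
deviation come out positive, extension and ulnar deviation negative.
The translation along the axis carries the sign of the oriented
direction.  Rotation angle and slide are invariant under change of
coordinates; direction and axis point map with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .frames import AnatomicalFrame
from .transforms import RigidTransform, rotation_about_axis

__all__ = [
    "BonePose",
    "HelicalAxis",
    "DecomposedRotation",
    "relative_transform",
    "helical_axis",
    "decompose_rotation",
    "mean_axis",
    "screw_transform",
]

FE_POSITIONS = (0.0, 30.0, 60.0, -30.0, -60.0)
RUD_POSITIONS = (0.0, 10.0, 20.0, -20.0, -40.0)

# below this rotation magnitude (rad) a displacement is treated as a pure translation
_PURE_TRANSLATION_RAD = 1e-8
# within this distance (rad) of pi the axis comes from the +1 eigenvector branch
_NEAR_PI_RAD = 1e-6


@dataclass(frozen=True)
class BonePose:
    """One bone's frame at one scan, with scan metadata."""

    frame: AnatomicalFrame
    subject: str = ""
    hand: str = "R"
    motion: str = "FE"
    nominal_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.motion not in ("FE", "RUD"):
            raise ValueError("motion must be 'FE' or 'RUD'")
        allowed = FE_POSITIONS if self.motion == "FE" else RUD_POSITIONS
        if not any(abs(self.nominal_angle_deg - a) < 1e-9 for a in allowed):
            raise ValueError(
                f"nominal angle {self.nominal_angle_deg} not in the {self.motion} protocol"
            )


@dataclass(frozen=True)
class HelicalAxis:
    """Screw parameters of a rigid displacement.

    ``axis_point`` is the unique point on the axis with
    ``axis_point . direction = 0`` (or the supplied fallback for a pure
    translation, where the axis line is undefined).
    """

    direction: np.ndarray
    angle_deg: float
    translation_along: float
    axis_point: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float).reshape(3)
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "axis_point", np.asarray(self.axis_point, dtype=float).reshape(3))
        if not self.degenerate and abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValueError("direction must be a unit vector")

    def to_transform(self) -> RigidTransform:
        """Recompose the rigid transform this axis describes."""
        if self.degenerate:
            return RigidTransform(np.eye(3), self.translation_along * self.direction)
        return screw_transform(
            self.direction, self.axis_point, self.angle_deg, self.translation_along
        )


@dataclass(frozen=True)
class DecomposedRotation:
    """Intrinsic Cardan angles (deg) of a rotation in the radius frame.

    Sequence Y (FE) -> Z (RUD) -> X (PS); flexion, radial deviation and
    pronation positive by the declared convention.
    """

    fe_deg: float
    rud_deg: float
    ps_deg: float
    sequence: str = "YZX"


def screw_transform(
    direction: np.ndarray, point: np.ndarray, angle_deg: float, slide_mm: float
) -> RigidTransform:
    """Rigid transform of a screw: rotate ``angle_deg`` about the line through
    ``point`` along unit ``direction``, then slide ``slide_mm`` along it."""
    n = np.asarray(direction, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("screw direction must be nonzero")
    if abs(norm - 1.0) > 1e-9:
        raise ValueError("screw direction must be a unit vector")
    n = n / norm
    p = np.asarray(point, dtype=float).reshape(3)
    rot = rotation_about_axis(n, angle_deg)
    trans = p - rot @ p + slide_mm * n
    return RigidTransform(rot, trans)


def relative_transform(neutral: BonePose, moved: BonePose) -> RigidTransform:
    """Displacement of a bone from its neutral pose to a moved pose.

    With frames as markers: ``rotation = A_moved @ A_neutral.T`` and the
    translation maps the neutral centroid onto the moved centroid.  Both
    poses must be sign-unified; a relative rotation of 90° or more about
    some axis indicates unification failed and only warns.
    """
    for key in ("subject", "hand", "motion"):
        if getattr(neutral, key) != getattr(moved, key):
            raise ValueError(f"poses are from different scans ({key} differs)")
    rot = moved.frame.axes @ neutral.frame.axes.T
    angle = np.degrees(
        np.arccos(np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0))
    )
    if angle >= 90.0:
        warnings.warn(
            f"relative rotation of {angle:.1f} deg suggests axis signs were not "
            "unified between poses",
            stacklevel=2,
        )
    trans = moved.frame.origin - rot @ neutral.frame.origin
    return RigidTransform(rot, trans)


def helical_axis(
    transform: RigidTransform,
    motion_reference_axis: np.ndarray,
    degenerate_point: np.ndarray | None = None,
) -> HelicalAxis:
    """Extract the helical axis of a rigid transform.

    The unsigned angle is ``atan2(|a|, (trace(R)-1)/2)`` with ``a`` half
    the axial vector of ``R - R^T``; the direction is ``a/|a|`` away from
    0 and pi and the +1 eigenvector of ``R`` near pi.  The axis point is
    the unique solution of ``(I - R) p = t - (n.t) n`` perpendicular to
    the axis.  The direction is then oriented so its dot product with
    ``motion_reference_axis`` is non-negative, carrying the angle and
    slide signs with it.

    A (near) identity rotation is a pure translation: ``degenerate`` is
    set, the direction is the translation direction and the axis point is
    ``degenerate_point`` (e.g. the neutral centroid) or zero.
    """
    ref = np.asarray(motion_reference_axis, dtype=float).reshape(3)
    if abs(np.linalg.norm(ref) - 1.0) > 1e-9:
        raise ValueError("motion_reference_axis must be a unit vector")
    r, t = transform.rotation, transform.translation
    a = 0.5 * np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    sin_theta = np.linalg.norm(a)
    cos_theta = (np.trace(r) - 1.0) / 2.0
    theta = float(np.arctan2(sin_theta, cos_theta))

    if theta < _PURE_TRANSLATION_RAD:
        norm_t = np.linalg.norm(t)
        direction = t / norm_t if norm_t > 0 else np.zeros(3)
        point = np.zeros(3) if degenerate_point is None else np.asarray(degenerate_point, float)
        return HelicalAxis(direction, 0.0, float(norm_t), point, degenerate=True)

    if theta > np.pi - _NEAR_PI_RAD:
        # sin(theta) ~ 0: use the +1 eigenspace of R, i.e. the dominant column of R + I
        b = r + np.eye(3)
        n = b[:, int(np.argmax((b * b).sum(axis=0)))]
        n = n / np.linalg.norm(n)
        # keep right-hand consistency with the (tiny) axial vector if usable
        if sin_theta > 1e-12 and float(n @ a) < 0:
            n = -n
    else:
        n = a / sin_theta

    slide = float(n @ t)
    t_perp = t - slide * n
    # solve (I - R) p = t_perp in the plane perpendicular to n
    point = 0.5 * (t_perp + np.cross(n, t_perp) / np.tan(theta / 2.0))
    point = point - float(point @ n) * n  # enforce the p . n = 0 convention

    angle = float(np.degrees(theta))
    if float(n @ ref) < 0:
        n, angle, slide = -n, -angle, -slide
    return HelicalAxis(n, angle, slide, point, degenerate=False)


def decompose_rotation(
    rotation: np.ndarray, radius_frame: AnatomicalFrame, sequence: str = "YZX"
) -> DecomposedRotation:
    """Cardan decomposition of a (world-frame) rotation in radius-frame axes.

    The rotation is expressed in radius-frame coordinates and split into
    intrinsic angles in the given sequence (default Y -> Z -> X, i.e. FE
    first).  Refuses FE or RUD angles of 90° or more (gimbal region —
    outside the wrist's range of motion).
    """
    if sorted(sequence) != ["X", "Y", "Z"]:
        raise ValueError("sequence must be a permutation of 'XYZ' (intrinsic)")
    f = radius_frame.axes
    r_local = f.T @ np.asarray(rotation, dtype=float) @ f
    angles = Rotation.from_matrix(r_local).as_euler(sequence, degrees=True)
    by_axis = dict(zip(sequence, angles))
    fe, rud, ps = by_axis["Y"], by_axis["Z"], by_axis["X"]
    if abs(fe) >= 90.0 or abs(rud) >= 90.0:
        raise ValueError(
            f"FE {fe:.1f} / RUD {rud:.1f} deg at or beyond 90°: gimbal region, refusing"
        )
    return DecomposedRotation(float(fe), float(rud), float(ps), sequence)


def recompose_rotation(decomposed: DecomposedRotation, radius_frame: AnatomicalFrame) -> np.ndarray:
    """Inverse of :func:`decompose_rotation` (world-frame rotation matrix)."""
    by_axis = {"Y": decomposed.fe_deg, "Z": decomposed.rud_deg, "X": decomposed.ps_deg}
    angles = [by_axis[ax] for ax in decomposed.sequence]
    r_local = Rotation.from_euler(decomposed.sequence, angles, degrees=True).as_matrix()
    f = radius_frame.axes
    return f @ r_local @ f.T


def mean_axis(axes: np.ndarray, motion_reference_axis: np.ndarray) -> np.ndarray:
    """Sign-invariant average direction of a set of (unit) axes.

    The principal eigenvector of ``sum_i n_i n_i^T`` — invariant to
    flipping any individual axis — oriented so its dot product with the
    motion reference axis is non-negative.
    """
    arr = np.atleast_2d(np.asarray(axes, dtype=float))
    if arr.shape[0] < 1 or arr.shape[1] != 3:
        raise ValueError("need at least one 3-vector")
    arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    scatter = arr.T @ arr
    w, v = np.linalg.eigh(scatter)
    mean = v[:, int(np.argmax(w))]
    ref = np.asarray(motion_reference_axis, dtype=float).reshape(3)
    if float(mean @ ref) < 0:
        mean = -mean
    return mean
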