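"""Synthetic wrist scenarios with known ground-truth screw motions.

The generator emulates the study conditions: five subjects, both hands,
flexion-extension (FE) scans at 0°, ±30°, ±60° and radial-ulnar
deviation (RUD) scans at 0°, +10°, ±20°, −40°.  Each scan is a radius
surface plus eight carpal-bone meshes; bones move from neutral by known
per-bone screws, the whole scan is disturbed by a random global rigid
transform (scanner/arm placement), and vertex-level Gaussian noise is
added.  Left hands are mirror images built from the same right-hand
convention motion model with independent noise draws, so left-vs-right
paired tests are calibrated under a true null.

Bones are ellipsoids, not anatomical shapes: the inertial-frame and
screw mathematics downstream are shape-agnostic, and ellipsoids carry
analytic volume/inertia oracles.  The radius is one shared, asymmetric
template per hand (per-subject size scaling applies to the carpal bones
only), so registration recovers rigid motion rather than confounding it
with shape correspondence.

The carpal motion model is deliberately simple: distal-row bones track
the wrist angle about the motion's nominal axis, while during RUD the
scaphoid, lunate and triquetrum receive flexion-extension-dominant
screws; base gains and slides echo the magnitudes reported for real
wrists (capitate rotating most, translations within ~3 mm) with no
claim of anatomical realism.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .descriptors import BONE_NAMES
from .frames import (
    AnatomicalFrame,
    Landmarks,
    mirror_mesh,
    mirror_points,
    radius_frame,
    save_landmarks,
)
from .helical import FE_POSITIONS, RUD_POSITIONS, screw_transform
from .mesh import TriMesh, save_mesh
from .transforms import RigidTransform, random_rotation

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "ScrewParams",
    "make_bone",
    "make_radius_template",
    "generate_scenario",
    "simulate_kinematics_records",
    "screw_transform",
]


# ---------------------------------------------------------------------------
# motion-model defaults (radius-frame coordinates, mm / deg)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoneModel:
    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]  # radius-frame coords, mm
    row: str  # "proximal" | "distal"
    fe_gain: float  # bone angle / wrist angle in FE
    rud_gain: float  # bone angle / wrist angle in RUD
    fe_slide_mm: float  # slide at |FE| = 60 deg
    rud_slide_mm: float  # slide at |RUD| = 40 deg


# semi-axes keep the ratio ~(1 : 0.78 : 0.40), which balances both principal-
# moment gaps near 30% so every bone's inertial frame is well conditioned
# against vertex noise; volumes echo real carpal bones
BONE_MODELS: dict[str, BoneModel] = {
    "scaphoid": BoneModel((12.0, 9.3, 4.7), (12.0, 8.0, 2.0), "proximal", 0.70, 0.36, -1.3, -0.9),
    "lunate": BoneModel((10.6, 8.3, 4.2), (12.0, -2.0, 2.0), "proximal", 0.47, 0.35, -1.1, -0.8),
    "triquetrum": BoneModel((10.0, 7.8, 4.0), (12.0, -10.0, 1.0), "proximal", 0.49, 0.33, -1.2, -0.3),
    "pisiform": BoneModel((8.1, 6.3, 3.3), (10.0, -9.0, 8.0), "proximal", 0.43, 0.18, 0.7, -0.7),
    "trapezium": BoneModel((11.0, 8.6, 4.4), (27.0, 12.0, 3.0), "distal", 0.66, 0.34, -1.6, -1.5),
    "trapezoid": BoneModel((9.9, 7.7, 3.8), (27.0, 5.0, 1.0), "distal", 0.73, 0.33, -2.0, -1.8),
    "capitate": BoneModel((13.3, 10.4, 5.3), (27.0, -2.0, 0.0), "distal", 0.70, 0.39, -1.3, -1.6),
    "hamate": BoneModel((12.4, 9.7, 5.0), (27.0, -10.0, 0.0), "distal", 0.70, 0.40, -1.8, -1.3),
}

_RADIUS_SEMI_AXES = (60.0, 14.0, 11.0)
# Gaussian surface features (center, amplitude, width): a styloid-like distal
# process, a dorsal tubercle, a notch-like depression and a proximal flare.
# Together with the shaft crest and bend below they make the template as
# asymmetric as a real distal radius, which is what pins the registration's
# soft twist mode about the long axis.
_RADIUS_FEATURES = (
    ((55.0, 8.0, 0.0), 0.8, 10.0),
    ((35.0, 0.0, 9.0), 0.5, 8.0),
    ((-20.0, -12.0, 0.0), -0.35, 12.0),
    ((-50.0, 5.0, -6.0), 0.5, 12.0),
)
_CREST_AZIMUTH_DEG = 200.0  # interosseous-crest-like ridge along the shaft
_CREST_AMPLITUDE = 0.45
_CREST_ANGULAR_WIDTH_DEG = 28.0
_SHAFT_BEND_MM = 4.0
_STYLOID_TEMPLATE = (52.0, 16.0, 0.0)
_EPICONDYLE_TEMPLATE = (57.0, 2.0, 2.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of a synthetic wrist scenario.

    Defaults are the acquisition protocol emulated by the package: five
    subjects, both hands, FE positions 0/±30/±60°, RUD positions
    0/+10/±20/−40°, per-scan pose perturbation up to 15° / 20 mm and
    0.1 mm vertex noise.
    """

    n_subjects: int = 5
    hands: tuple[str, ...] = ("L", "R")
    fe_positions_deg: tuple[float, ...] = FE_POSITIONS
    rud_positions_deg: tuple[float, ...] = RUD_POSITIONS
    bone_scale_range: tuple[float, float] = (0.85, 1.15)
    gain_sd: float = 0.08  # per-subject multiplicative spread of motion gains
    angle_jitter_deg: float = 0.3  # per-hand additive angle noise
    slide_jitter_mm: float = 0.1  # per-hand additive slide noise
    axis_tilt_sd_deg: float = 2.0  # per-record tilt of the screw axis
    axis_point_jitter_mm: float = 0.5
    perturb_rot_deg: float = 15.0  # per-scan global pose disturbance
    perturb_trans_mm: float = 20.0
    vertex_noise_mm: float = 0.1
    bone_subdivisions: int = 5
    radius_subdivisions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for positions, name in (
            (self.fe_positions_deg, "FE"),
            (self.rud_positions_deg, "RUD"),
        ):
            if not any(abs(p) < 1e-9 for p in positions):
                raise ValueError(f"{name} protocol must include the neutral (0°) position")
        if not set(self.hands) <= {"L", "R"}:
            raise ValueError("hands must be a subset of {'L', 'R'}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")

    def positions(self, motion: str) -> tuple[float, ...]:
        return self.fe_positions_deg if motion == "FE" else self.rud_positions_deg


@dataclass(frozen=True)
class ScrewParams:
    """Ground-truth screw of one bone at one position, radius-frame coords.

    ``point`` follows the axis-point convention ``point . direction = 0``.
    """

    direction: np.ndarray
    point: np.ndarray
    angle_deg: float
    slide_mm: float

    def world_transform(self, frame: AnatomicalFrame) -> RigidTransform:
        n = frame.axes @ self.direction
        p = frame.to_world(self.point)
        return screw_transform(n, p, self.angle_deg, self.slide_mm)


@dataclass
class GroundTruth:
    """Everything the generator knows: per-record screws (radius-frame
    coordinates, right-hand convention), per-scan perturbations and the
    reference radius frame in template coordinates."""

    screws: dict[tuple[str, str, str, str, float], ScrewParams]
    perturbations: dict[str, RigidTransform]
    reference_frame: AnatomicalFrame
    config: ScenarioConfig

    def screw(self, subject: str, hand: str, bone: str, motion: str,
              position_deg: float) -> ScrewParams:
        return self.screws[(subject, hand, bone, motion, float(position_deg))]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": asdict(self.config),
            "reference_frame": {
                "origin": self.reference_frame.origin.tolist(),
                "axes": self.reference_frame.axes.tolist(),
            },
            "screws": [
                {
                    "subject": k[0], "hand": k[1], "bone": k[2], "motion": k[3],
                    "position_deg": k[4],
                    "direction": v.direction.tolist(),
                    "point": v.point.tolist(),
                    "angle_deg": v.angle_deg,
                    "slide_mm": v.slide_mm,
                }
                for k, v in sorted(self.screws.items())
            ],
            "perturbations": {k: v.matrix.tolist() for k, v in sorted(self.perturbations.items())},
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @staticmethod
    def from_json(path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        cfg_kwargs = data["config"]
        for key in ("hands", "fe_positions_deg", "rud_positions_deg",
                    "bone_scale_range"):
            cfg_kwargs[key] = tuple(cfg_kwargs[key])
        frame = AnatomicalFrame.from_axes(
            np.asarray(data["reference_frame"]["origin"]),
            np.asarray(data["reference_frame"]["axes"]),
        )
        screws = {
            (s["subject"], s["hand"], s["bone"], s["motion"], float(s["position_deg"])):
            ScrewParams(
                np.asarray(s["direction"]), np.asarray(s["point"]),
                float(s["angle_deg"]), float(s["slide_mm"]),
            )
            for s in data["screws"]
        }
        perturb = {
            k: RigidTransform.from_matrix(np.asarray(m))
            for k, m in data["perturbations"].items()
        }
        return GroundTruth(screws, perturb, frame, ScenarioConfig(**cfg_kwargs))


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def make_bone(semi_axes: tuple[float, float, float], subdivisions: int = 3) -> TriMesh:
    """Watertight triangulated ellipsoid with semi-axes in mm.

    Volume, centroid and principal axes are analytic (4/3 pi abc;
    origin; the coordinate axes for distinct semi-axes).  Near-equal
    semi-axes are allowed but warned about: the inertial frame is then
    degenerate by construction.
    """
    a, b, c = (float(s) for s in semi_axes)
    if min(a, b, c) <= 0:
        raise ValueError("semi-axes must be positive")
    vals = sorted((a, b, c), reverse=True)
    if any((hi - lo) / hi < 1e-3 for hi, lo in zip(vals, vals[1:])):
        warnings.warn(
            "near-equal ellipsoid semi-axes: principal frame is degenerate",
            stacklevel=2,
        )
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = sphere.vertices * np.array([a, b, c])
    return TriMesh(vertices=verts, faces=sphere.faces.copy(), process=False)


def make_radius_template(subdivisions: int = 5) -> tuple[TriMesh, Landmarks]:
    """The shared radius surface plus its two landmarks.

    An elongated ellipsoid decorated with localized Gaussian features, a
    ridge along the shaft and a gentle bend — a caricature of a distal
    radius (styloid process, dorsal tubercle, notch, interosseous crest)
    with no residual rotational or reflective symmetry.
    """
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = sphere.vertices * np.array(_RADIUS_SEMI_AXES)
    scale = np.ones(len(verts))
    for center, amp, width in _RADIUS_FEATURES:
        d2 = ((verts - np.array(center)) ** 2).sum(axis=1)
        scale += amp * np.exp(-d2 / (2.0 * width**2))
    azimuth = np.arctan2(verts[:, 2], verts[:, 1])
    ang = np.angle(np.exp(1j * (azimuth - np.radians(_CREST_AZIMUTH_DEG))))
    along_shaft = np.exp(-(((verts[:, 0] + 15.0) / 35.0) ** 2))
    scale += _CREST_AMPLITUDE * along_shaft * np.exp(
        -((ang / np.radians(_CREST_ANGULAR_WIDTH_DEG)) ** 2)
    )
    verts = verts * scale[:, None]
    verts[:, 1] += _SHAFT_BEND_MM * (((verts[:, 0] + 60.0) / 120.0) ** 2)
    mesh = TriMesh(vertices=verts, faces=sphere.faces.copy(), process=False)
    marks = Landmarks(np.array(_STYLOID_TEMPLATE), np.array(_EPICONDYLE_TEMPLATE))
    return mesh, marks


# ---------------------------------------------------------------------------
# seeded parameter draws
# ---------------------------------------------------------------------------

_HAND_INDEX = {"L": 0, "R": 1}
_MOTION_INDEX = {"FE": 0, "RUD": 1}


def _subject_rng(cfg: ScenarioConfig, subj: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 1, subj])


def _record_rng(cfg: ScenarioConfig, subj: int, hand: str, bone_idx: int,
                motion: str, pos_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        [cfg.seed, 2, subj, _HAND_INDEX[hand], bone_idx, _MOTION_INDEX[motion], pos_idx]
    )


def _scan_rng(cfg: ScenarioConfig, kind: int, subj: int, hand: str, motion: str,
              pos_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        [cfg.seed, kind, subj, _HAND_INDEX[hand], _MOTION_INDEX[motion], pos_idx]
    )


@dataclass(frozen=True)
class _SubjectAnatomy:
    bone_scale: float
    bone_rotations: dict[str, np.ndarray]  # fixed per-subject bone attitude
    gain_factors: dict[tuple[str, str], float]  # (bone, motion) -> multiplier


def _draw_subject(cfg: ScenarioConfig, subj: int) -> _SubjectAnatomy:
    rng = _subject_rng(cfg, subj)
    lo, hi = cfg.bone_scale_range
    scale = float(rng.uniform(lo, hi))
    rotations = {name: random_rotation(rng, 25.0) for name in BONE_NAMES}
    gains = {
        (name, motion): float(max(0.5, 1.0 + rng.normal(0.0, cfg.gain_sd)))
        for name in BONE_NAMES
        for motion in ("FE", "RUD")
    }
    return _SubjectAnatomy(scale, rotations, gains)


def _tilt(direction: np.ndarray, rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Rotate a unit vector by a random small angle about a random
    perpendicular axis."""
    angle = rng.normal(0.0, sd_deg)
    azimuth = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal basis perpendicular to direction
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    axis = np.cos(azimuth) * u + np.sin(azimuth) * v
    from .transforms import rotation_about_axis

    return rotation_about_axis(axis, angle) @ direction


def _base_axis(bone: str, motion: str) -> np.ndarray:
    """Nominal screw-axis direction (radius-frame coords) before jitter."""
    y = np.array([0.0, 1.0, 0.0])
    z = np.array([0.0, 0.0, 1.0])
    if motion == "FE":
        n = y + 0.15 * z  # slight ulnar coupling while flexing
    elif BONE_MODELS[bone].row == "proximal" and bone != "pisiform":
        n = 0.9 * y + 0.45 * z  # FE-dominant behaviour of the proximal row in RUD
    else:
        n = z + 0.2 * y
    return n / np.linalg.norm(n)


def _true_screw(cfg: ScenarioConfig, anatomy: _SubjectAnatomy, subj: int, hand: str,
                bone: str, motion: str, pos_idx: int, wrist_deg: float) -> ScrewParams:
    """Draw the ground-truth screw of one record (radius-frame coords)."""
    model = BONE_MODELS[bone]
    bone_idx = BONE_NAMES.index(bone)
    rng = _record_rng(cfg, subj, hand, bone_idx, motion, pos_idx)
    gain = (model.fe_gain if motion == "FE" else model.rud_gain)
    gain *= anatomy.gain_factors[(bone, motion)]
    angle = gain * wrist_deg + rng.normal(0.0, cfg.angle_jitter_deg)
    full = 60.0 if motion == "FE" else 40.0
    slide_base = model.fe_slide_mm if motion == "FE" else model.rud_slide_mm
    slide = slide_base * abs(wrist_deg) / full + rng.normal(0.0, cfg.slide_jitter_mm)
    direction = _tilt(_base_axis(bone, motion), rng, cfg.axis_tilt_sd_deg)
    if model.row == "proximal":
        point = np.asarray(model.center, dtype=float)
    else:
        point = np.array([6.0, 0.25 * model.center[1], 3.0])
    point = point + rng.normal(0.0, cfg.axis_point_jitter_mm, size=3)
    point = point - float(point @ direction) * direction  # canonical p . n = 0
    return ScrewParams(direction, point, float(angle), float(slide))


# ---------------------------------------------------------------------------
# scenario generation
# ---------------------------------------------------------------------------

def scan_id(subject: str, hand: str, motion: str, position_deg: float) -> str:
    a = int(round(position_deg))
    tag = f"m{abs(a)}" if a < 0 else f"p{a}"
    return f"{subject}_{hand}_{motion}_{tag}"


@dataclass(frozen=True)
class Scenario:
    """Paths of an emitted scenario plus its ground truth."""

    out_dir: Path
    manifest_path: Path
    ground_truth_path: Path
    ground_truth: GroundTruth


def _neutral_bone_mesh(cfg: ScenarioConfig, anatomy: _SubjectAnatomy, bone: str,
                       frame: AnatomicalFrame) -> TriMesh:
    model = BONE_MODELS[bone]
    semi = tuple(s * anatomy.bone_scale for s in model.semi_axes)
    mesh = make_bone(semi, cfg.bone_subdivisions)
    verts = mesh.vertices @ anatomy.bone_rotations[bone].T
    verts = frame.to_world(verts + np.asarray(model.center))
    # to_world applied per-vertex after offsetting in frame coords
    return TriMesh(vertices=verts, faces=mesh.faces.copy(), process=False)


def generate_scenario(config: ScenarioConfig, out_dir: str | Path) -> Scenario:
    """Emit a complete scenario (meshes, landmarks, manifest, ground truth).

    Deterministic: the same config (including its seed) reproduces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    scans_dir = out_dir / "scans"
    scans_dir.mkdir(parents=True, exist_ok=True)
    radius_mesh, marks = make_radius_template(config.radius_subdivisions)
    frame = radius_frame(radius_mesh, marks)
    mirror_origin, mirror_normal = frame.origin, frame.y_axis

    screws: dict[tuple[str, str, str, str, float], ScrewParams] = {}
    perturbations: dict[str, RigidTransform] = {}
    scan_entries = []
    references: dict[str, str] = {}

    for subj_idx in range(config.n_subjects):
        subject = f"sub{subj_idx + 1}"
        anatomy = _draw_subject(config, subj_idx)
        for hand in sorted(config.hands):
            neutral_bones = {
                bone: _neutral_bone_mesh(config, anatomy, bone, frame)
                for bone in BONE_NAMES
            }
            for motion in ("FE", "RUD"):
                for pos_idx, wrist_deg in enumerate(config.positions(motion)):
                    sid = scan_id(subject, hand, motion, wrist_deg)
                    sdir = scans_dir / sid
                    sdir.mkdir(parents=True, exist_ok=True)

                    bone_meshes = {}
                    for bone in BONE_NAMES:
                        if abs(wrist_deg) < 1e-9:
                            # the neutral scan is the reference: zero screw by definition
                            screw = ScrewParams(
                                _base_axis(bone, motion), np.zeros(3), 0.0, 0.0
                            )
                        else:
                            screw = _true_screw(
                                config, anatomy, subj_idx, hand, bone, motion,
                                pos_idx, wrist_deg,
                            )
                        screws[(subject, hand, bone, motion, float(wrist_deg))] = screw
                        if abs(wrist_deg) < 1e-9:
                            moved = neutral_bones[bone]
                        else:
                            world = screw.world_transform(frame)
                            moved = TriMesh(
                                vertices=world.apply(neutral_bones[bone].vertices),
                                faces=neutral_bones[bone].faces.copy(),
                                process=False,
                            )
                        bone_meshes[bone] = moved
                    scan_radius = radius_mesh
                    scan_marks = marks

                    if hand == "L":
                        scan_radius = mirror_mesh(scan_radius, mirror_origin, mirror_normal)
                        scan_marks = Landmarks(
                            mirror_points(scan_marks.styloid, mirror_origin, mirror_normal),
                            mirror_points(
                                scan_marks.distal_epicondyle, mirror_origin, mirror_normal
                            ),
                        )
                        bone_meshes = {
                            b: mirror_mesh(m, mirror_origin, mirror_normal)
                            for b, m in bone_meshes.items()
                        }

                    rng_p = _scan_rng(config, 3, subj_idx, hand, motion, pos_idx)
                    if config.perturb_rot_deg > 0 or config.perturb_trans_mm > 0:
                        perturb = RigidTransform(
                            random_rotation(rng_p, config.perturb_rot_deg),
                            rng_p.uniform(
                                -config.perturb_trans_mm, config.perturb_trans_mm, size=3
                            ),
                        )
                    else:
                        perturb = RigidTransform.identity()
                    perturbations[sid] = perturb

                    rng_n = _scan_rng(config, 4, subj_idx, hand, motion, pos_idx)

                    def emit(mesh: TriMesh, name: str) -> str:
                        verts = perturb.apply(mesh.vertices)
                        if config.vertex_noise_mm > 0:
                            verts = verts + rng_n.normal(
                                0.0, config.vertex_noise_mm, size=verts.shape
                            )
                        out = TriMesh(vertices=verts, faces=mesh.faces.copy(), process=False)
                        rel = f"scans/{sid}/{name}.off"
                        save_mesh(out, out_dir / rel)
                        return rel

                    radius_rel = emit(scan_radius, "radius")
                    bone_rels = {b: emit(m, b) for b, m in bone_meshes.items()}
                    marks_rel = f"scans/{sid}/landmarks.json"
                    save_landmarks(scan_marks.transformed(perturb), out_dir / marks_rel)

                    scan_entries.append(
                        {
                            "id": sid,
                            "subject": subject,
                            "hand": hand,
                            "motion": motion,
                            "position_deg": float(wrist_deg),
                            "radius": radius_rel,
                            "landmarks": marks_rel,
                            "bones": bone_rels,
                        }
                    )
                    if subj_idx == 0 and motion == "FE" and abs(wrist_deg) < 1e-9:
                        references[hand] = sid

    manifest = {"reference": references, "scans": scan_entries}
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    gt = GroundTruth(screws, perturbations, frame, config)
    gt_path = gt.to_json(out_dir / "ground_truth.json")
    return Scenario(out_dir, manifest_path, gt_path, gt)


def simulate_kinematics_records(config: ScenarioConfig) -> pd.DataFrame:
    """Ground-truth kinematics records without any geometry.

    Draws the same per-record screw parameters the mesh generator uses
    and returns them as a records table (one row per subject, hand,
    bone, motion, non-neutral position).  Used for statistical
    calibration studies where the mesh pipeline adds nothing but run
    time.
    """
    rows = []
    for subj_idx in range(config.n_subjects):
        subject = f"sub{subj_idx + 1}"
        anatomy = _draw_subject(config, subj_idx)
        for hand in sorted(config.hands):
            for motion in ("FE", "RUD"):
                for pos_idx, wrist_deg in enumerate(config.positions(motion)):
                    if abs(wrist_deg) < 1e-9:
                        continue
                    for bone in BONE_NAMES:
                        screw = _true_screw(
                            config, anatomy, subj_idx, hand, bone, motion,
                            pos_idx, wrist_deg,
                        )
                        rows.append(
                            {
                                "subject": subject,
                                "hand": hand,
                                "bone": bone,
                                "motion": motion,
                                "position_deg": float(wrist_deg),
                                "ha_angle_deg": screw.angle_deg,
                                "ha_translation_mm": screw.slide_mm,
                            }
                        )
    return pd.DataFrame(rows)
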