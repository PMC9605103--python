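"""End-to-end pipeline: register -> frames -> helical axes -> statistics.

Given a scan inventory (radius + eight carpal meshes + landmarks per
scan), every scan's radius is rigidly registered to a per-hand reference
radius and the transform propagated to that scan's carpal bones.  The
radius-based anatomical frame is built on the reference scan; left-hand
geometry is mirrored across its sagittal plane so both hands share one
sign convention.  Per bone and position, the displacement from neutral
is taken between sign-unified inertial bone frames, its helical axis
extracted and decomposed, and the results written as a kinematics table,
per-position summary tables with left/right paired tests, a bone-volume
table and an OBJ file of helical-axis segments.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptors
from .descriptors import BONE_NAMES, SummaryResult, bone_radius_distance, summarize
from .frames import (
    AnatomicalFrame,
    Landmarks,
    load_landmarks,
    mirror_mesh,
    mirror_points,
    radius_frame,
)
from .helical import BonePose, decompose_rotation, helical_axis, mean_axis, relative_transform
from .mesh import TriMesh, load_mesh, mass_properties, unify_axis_signs
from .frames import canonical_axis_signs
from .registration import (
    PointCloud,
    cpd_rigid,
    inertia_prealign,
    propagate,
    stride_downsample,
)
from .transforms import RigidTransform

__all__ = ["RunManifest", "ScanEntry", "PipelineParams", "RunResult", "run_pipeline",
           "export_ha_segments"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanEntry:
    id: str
    subject: str
    hand: str
    motion: str
    position_deg: float
    radius: str
    landmarks: str
    bones: dict[str, str]


@dataclass
class RunManifest:
    """Scan inventory + per-hand reference scan ids, paths relative to base_dir."""

    scans: list[ScanEntry]
    reference: dict[str, str]
    base_dir: Path = field(default_factory=Path)

    @staticmethod
    def load(path: str | Path) -> "RunManifest":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        scans = [ScanEntry(**entry) for entry in data["scans"]]
        return RunManifest(scans=scans, reference=dict(data.get("reference", {})),
                           base_dir=path.parent)

    def validate(self) -> None:
        """Exactly one neutral scan per subject/hand/motion; references exist."""
        ids = {s.id for s in self.scans}
        if len(ids) != len(self.scans):
            raise ValueError("duplicate scan ids in manifest")
        neutral: dict[tuple[str, str, str], int] = {}
        for s in self.scans:
            if abs(s.position_deg) < 1e-9:
                key = (s.subject, s.hand, s.motion)
                neutral[key] = neutral.get(key, 0) + 1
        for s in self.scans:
            key = (s.subject, s.hand, s.motion)
            if neutral.get(key, 0) != 1:
                raise ValueError(
                    f"subject {s.subject} hand {s.hand} motion {s.motion}: "
                    f"expected exactly one neutral (0°) scan, found {neutral.get(key, 0)}"
                )
        hands = {s.hand for s in self.scans}
        for hand in hands:
            ref = self.reference.get(hand)
            if ref is None:
                # default: neutral FE scan of the first subject of this hand
                cands = sorted(
                    (s for s in self.scans
                     if s.hand == hand and s.motion == "FE" and abs(s.position_deg) < 1e-9),
                    key=lambda s: s.subject,
                )
                if not cands:
                    raise ValueError(f"hand {hand}: no reference scan and no neutral FE scan")
                self.reference[hand] = cands[0].id
            elif ref not in ids:
                raise ValueError(f"hand {hand}: reference scan {ref!r} not in manifest")

    def path(self, rel: str) -> Path:
        return self.base_dir / rel


@dataclass(frozen=True)
class PipelineParams:
    """Stage parameters (registration, decomposition, reporting)."""

    downsample_target: int = 3000
    outlier_weight: float = 0.1
    cpd_tol: float = 1e-8
    cpd_max_iter: int = 150
    prealign: bool = True  # inertia-based warm start for CPD
    sequence: str = "YZX"  # Cardan decomposition order (FE first)
    ha_segment_length_mm: float = 60.0


@dataclass
class RunResult:
    """In-memory result bundle of one pipeline run."""

    records: pd.DataFrame
    summary: SummaryResult
    volumes: pd.DataFrame
    radius_frames: dict[str, AnatomicalFrame]
    scan_transforms: dict[str, RigidTransform]
    run_log: dict
    out_dir: Path | None = None


def _bone_frame_from_props(mesh: TriMesh, reference_axes: np.ndarray | None):
    props = mass_properties(mesh)
    if reference_axes is None:
        axes = canonical_axis_signs(props.principal_axes)
    else:
        axes = unify_axis_signs(props.principal_axes, reference_axes)[0]
    return AnatomicalFrame.from_axes(props.centroid, axes), props


def run_pipeline(
    manifest: RunManifest | str | Path,
    out_dir: str | Path | None = None,
    params: PipelineParams | None = None,
) -> RunResult:
    """Execute the full analysis over a scan inventory.

    Deterministic given the manifest and parameters.  When ``out_dir``
    is given, writes ``kinematics.csv`` (full precision),
    ``summary.csv`` and ``volumes.csv`` (2 d.p.), ``ha_segments.obj``
    and ``run_log.json``.
    """
    t0 = time.time()
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.load(manifest)
    params = params or PipelineParams()
    manifest.validate()

    registration_log: dict[str, dict] = {}
    warnings_log: list[str] = []
    scan_transforms: dict[str, RigidTransform] = {}
    radius_frames: dict[str, AnatomicalFrame] = {}
    aligned_bones: dict[str, dict[str, TriMesh]] = {}
    scans_by_id = {s.id: s for s in manifest.scans}

    for hand in sorted({s.hand for s in manifest.scans}):
        hand_scans = [s for s in manifest.scans if s.hand == hand]
        ref_entry = scans_by_id[manifest.reference[hand]]
        ref_radius = load_mesh(manifest.path(ref_entry.radius))
        ref_marks = load_landmarks(manifest.path(ref_entry.landmarks))
        # stride (not voxel) down-sampling here: the identical selection rule
        # on every cloud keeps rigid copies in correspondence, whereas voxel
        # representatives are re-quantized per pose and bias the GMM fit
        ref_cloud = stride_downsample(
            PointCloud(ref_radius.vertices, ref_entry.id), params.downsample_target
        )

        # 1. register every scan's radius to the reference; propagate to bones
        for scan in hand_scans:
            if scan.id == ref_entry.id:
                transform = RigidTransform.identity()
                registration_log[scan.id] = {"reference": True}
            else:
                cloud = stride_downsample(
                    PointCloud(load_mesh(manifest.path(scan.radius)).vertices, scan.id),
                    params.downsample_target,
                )
                init = inertia_prealign(cloud, ref_cloud) if params.prealign else None
                res = cpd_rigid(
                    cloud,
                    ref_cloud,
                    outlier_weight=params.outlier_weight,
                    tol=params.cpd_tol,
                    max_iter=params.cpd_max_iter,
                    init=init,
                )
                transform = res.transform
                registration_log[scan.id] = {
                    "converged": res.converged,
                    "n_iter": res.n_iter,
                    "sigma2": res.sigma2,
                }
                if not res.converged:
                    warnings_log.append(f"registration of {scan.id} did not converge")
            scan_transforms[scan.id] = transform
            bones = {
                name: load_mesh(manifest.path(rel)) for name, rel in scan.bones.items()
            }
            aligned_bones[scan.id] = {
                name: propagate(transform, mesh) for name, mesh in bones.items()
            }

        # 2. anatomical frame on the reference; mirror left hands
        frame = radius_frame(ref_radius, ref_marks)
        if hand == "L":
            origin, normal = frame.origin, frame.y_axis
            ref_radius = mirror_mesh(ref_radius, origin, normal)
            ref_marks = Landmarks(
                mirror_points(ref_marks.styloid, origin, normal),
                mirror_points(ref_marks.distal_epicondyle, origin, normal),
            )
            for scan in hand_scans:
                aligned_bones[scan.id] = {
                    name: mirror_mesh(mesh, origin, normal)
                    for name, mesh in aligned_bones[scan.id].items()
                }
            frame = radius_frame(ref_radius, ref_marks)
        radius_frames[hand] = frame

    # 3. kinematics per subject/hand/motion against the neutral scan
    rows = []
    volume_rows = []
    for scan in manifest.scans:
        frame = radius_frames[scan.hand]
        for bone in scan.bones:
            props = mass_properties(aligned_bones[scan.id][bone])
            volume_rows.append(
                {"subject": scan.subject, "hand": scan.hand, "bone": bone,
                 "scan": scan.id, "volume_mm3": props.volume}
            )

    groups: dict[tuple[str, str, str], list[ScanEntry]] = {}
    for scan in manifest.scans:
        groups.setdefault((scan.subject, scan.hand, scan.motion), []).append(scan)

    for (subject, hand, motion), scans in sorted(groups.items()):
        frame = radius_frames[hand]
        ref_axis = frame.y_axis if motion == "FE" else frame.z_axis
        neutral = next(s for s in scans if abs(s.position_deg) < 1e-9)
        neutral_frames = {}
        for bone in neutral.bones:
            bframe, _ = _bone_frame_from_props(aligned_bones[neutral.id][bone], None)
            neutral_frames[bone] = bframe
        for scan in scans:
            if abs(scan.position_deg) < 1e-9:
                continue
            for bone in scan.bones:
                bframe, _ = _bone_frame_from_props(
                    aligned_bones[scan.id][bone], neutral_frames[bone].axes
                )
                pose_n = BonePose(neutral_frames[bone], subject, hand, motion, 0.0)
                pose_m = BonePose(bframe, subject, hand, motion, scan.position_deg)
                rel = relative_transform(pose_n, pose_m)
                ha = helical_axis(rel, ref_axis, degenerate_point=neutral_frames[bone].origin)
                try:
                    dec = decompose_rotation(rel.rotation, frame, params.sequence)
                    fe, rud, ps = dec.fe_deg, dec.rud_deg, dec.ps_deg
                except ValueError as exc:
                    warnings_log.append(f"{scan.id}/{bone}: {exc}")
                    fe = rud = ps = np.nan
                dir_local = frame.direction_to_local(ha.direction)
                point_local = frame.to_local(ha.axis_point)
                # re-apply the point . direction = 0 convention in frame coords
                if not ha.degenerate:
                    point_local = point_local - float(point_local @ dir_local) * dir_local
                rows.append(
                    {
                        "subject": subject,
                        "hand": hand,
                        "bone": bone,
                        "motion": motion,
                        "position_deg": scan.position_deg,
                        "position": descriptors.position_label(motion, scan.position_deg),
                        "ha_angle_deg": ha.angle_deg,
                        "ha_translation_mm": ha.translation_along,
                        "axis_dir_x": dir_local[0],
                        "axis_dir_y": dir_local[1],
                        "axis_dir_z": dir_local[2],
                        "axis_point_x": point_local[0],
                        "axis_point_y": point_local[1],
                        "axis_point_z": point_local[2],
                        "fe_deg": fe,
                        "rud_deg": rud,
                        "ps_deg": ps,
                        "ha_degenerate": ha.degenerate,
                        "bone_radius_distance_mm": bone_radius_distance(
                            bframe.origin, frame.origin
                        ),
                    }
                )

    records = pd.DataFrame(rows)
    summary = summarize(records)
    volumes = _volume_table(pd.DataFrame(volume_rows))
    run_log = {
        "params": asdict(params),
        "reference": dict(manifest.reference),
        "registration": registration_log,
        "warnings": warnings_log,
        "n_records": len(records),
        "elapsed_s": round(time.time() - t0, 3),
    }
    result = RunResult(
        records=records,
        summary=summary,
        volumes=volumes,
        radius_frames=radius_frames,
        scan_transforms=scan_transforms,
        run_log=run_log,
    )
    if out_dir is not None:
        result.out_dir = write_bundle(result, out_dir, params)
    return result


def _volume_table(volume_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean bone volume across positions/hands, plus mean and
    population-sd rows across subjects (study-style volume table)."""
    per_subject = (
        volume_rows.groupby(["subject", "bone"])["volume_mm3"].mean().unstack("bone")
    )
    order = [b for b in BONE_NAMES if b in per_subject.columns]
    per_subject = per_subject[order]
    mean_row = per_subject.mean(axis=0)
    sd_row = per_subject.std(axis=0, ddof=0)
    out = per_subject.copy()
    out.loc["mean"] = mean_row
    out.loc["SD"] = sd_row
    return out


def export_ha_segments(
    records: pd.DataFrame,
    length_mm: float,
    path: str | Path,
) -> Path:
    """Write helical axes as 2-point OBJ polylines in radius-frame coords.

    Each record becomes one segment of the given length centred on its
    axis point; per (bone, motion) group the sign-invariant mean axis is
    written as an extra segment anchored at the group's mean axis point.
    Degenerate (pure-translation) records are skipped with a note.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    half = length_mm / 2.0
    lines = ["# helical axis segments (radius-frame coordinates, mm)"]
    vtx_count = 0

    def add_segment(name: str, point: np.ndarray, direction: np.ndarray) -> None:
        nonlocal vtx_count
        a = point - half * direction
        b = point + half * direction
        lines.append(f"o {name}")
        for v in (a, b):
            lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
        lines.append(f"l {vtx_count + 1} {vtx_count + 2}")
        vtx_count += 2

    usable = records[~records.get("ha_degenerate", pd.Series(False, index=records.index))]
    skipped = len(records) - len(usable)
    if skipped:
        lines.append(f"# {skipped} degenerate (pure translation) records skipped")
        log.info("export_ha_segments: skipped %d degenerate records", skipped)
    for _, rec in usable.iterrows():
        d = np.array([rec["axis_dir_x"], rec["axis_dir_y"], rec["axis_dir_z"]])
        p = np.array([rec["axis_point_x"], rec["axis_point_y"], rec["axis_point_z"]])
        name = f"{rec['subject']}_{rec['hand']}_{rec['bone']}_{rec['motion']}_{rec['position']}"
        add_segment(name, p, d)
    for (bone, motion), grp in usable.groupby(["bone", "motion"], sort=False):
        dirs = grp[["axis_dir_x", "axis_dir_y", "axis_dir_z"]].to_numpy(dtype=float)
        ref = np.array([0.0, 1.0, 0.0]) if motion == "FE" else np.array([0.0, 0.0, 1.0])
        mean_dir = mean_axis(dirs, ref)
        anchor = grp[["axis_point_x", "axis_point_y", "axis_point_z"]].to_numpy(float).mean(axis=0)
        add_segment(f"mean_{bone}_{motion}", anchor, mean_dir)
    path.write_text("\n".join(lines) + "\n")
    return path


def write_bundle(result: RunResult, out_dir: str | Path, params: PipelineParams) -> Path:
    """Write the result bundle; floats are rounded only at serialization
    (full precision in kinematics.csv, 2 d.p. in the report tables)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out_dir / "kinematics.csv", index=False)
    result.summary.to_wide().round(2).to_csv(out_dir / "summary.csv", index=False)
    result.summary.pvalues.to_csv(out_dir / "pvalues.csv", index=False)
    result.volumes.round(2).to_csv(out_dir / "volumes.csv")
    export_ha_segments(result.records, params.ha_segment_length_mm,
                       out_dir / "ha_segments.obj")
    (out_dir / "run_log.json").write_text(json.dumps(result.run_log, indent=1))
    return out_dir
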