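"""Scalar descriptors and left/right statistics of carpal kinematics.

Per bone and wrist position the pipeline yields one record per subject
and hand: the helical-axis rotation angle (deg) and translation (mm),
its decomposed FE/RUD/PS angles, and the Euclidean bone-to-radius
distance.  This module summarises those records the way the study
reports them: mean and sample standard deviation per position for the
pooled, left and right groups, plus a paired (by subject) two-sided
t-test between hands for each bone x position x quantity — 8 bones x 8
non-neutral positions x 2 quantities = 128 p-values for a complete
protocol.  Bone volumes are summarised with the population (divisor n)
standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BONE_NAMES",
    "PairedTResult",
    "SummaryResult",
    "bone_radius_distance",
    "paired_t",
    "summarize",
    "volume_stats",
    "position_label",
]

log = logging.getLogger(__name__)

BONE_NAMES = (
    "scaphoid",
    "lunate",
    "triquetrum",
    "pisiform",
    "trapezium",
    "trapezoid",
    "capitate",
    "hamate",
)

#: column order of the per-position report (extension/ulnar deviation negative)
POSITION_LABELS = ("E60", "E30", "F30", "F60", "UD40", "UD20", "RD10", "RD20")


def position_label(motion: str, nominal_angle_deg: float) -> str:
    """Report label of a non-neutral protocol position, e.g. ('FE', -60) -> 'E60'."""
    a = round(float(nominal_angle_deg))
    if a == 0:
        raise ValueError("the neutral position has no report column")
    if motion == "FE":
        return ("F" if a > 0 else "E") + str(abs(a))
    if motion == "RUD":
        return ("RD" if a > 0 else "UD") + str(abs(a))
    raise ValueError(f"unknown motion {motion!r}")


def bone_radius_distance(centroid: np.ndarray, radius_origin: np.ndarray) -> float:
    """Euclidean distance between a bone centroid and the radius-frame origin (mm)."""
    diff = np.asarray(centroid, dtype=float).reshape(3) - np.asarray(
        radius_origin, dtype=float
    ).reshape(3)
    return float(np.linalg.norm(diff))


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    degenerate: bool = False  # zero-variance differences with nonzero mean


def paired_t(left: np.ndarray, right: np.ndarray) -> PairedTResult:
    """Paired-sample t-test of matched left/right values (two-sided).

    ``t = mean(D) / (sd(D) / sqrt(n))`` with ``D = left - right`` and the
    sample sd (divisor n-1); p from Student's t with n-1 df.  All-zero
    differences give t = 0, p = 1; zero sd with nonzero mean gives
    t = +-inf, p = 0, flagged degenerate.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape or left.ndim != 1:
        raise ValueError("left and right must be 1-D arrays of equal length")
    n = left.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = left - right
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, 1.0, df)
        return PairedTResult(math.copysign(math.inf, mean), 0.0, df, degenerate=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return PairedTResult(t, p, df)


REQUIRED_RECORD_COLUMNS = (
    "subject",
    "hand",
    "bone",
    "motion",
    "position_deg",
    "ha_angle_deg",
    "ha_translation_mm",
)


@dataclass(frozen=True)
class SummaryResult:
    """Per-position summary cells plus the left-vs-right p-value table.

    ``cells``: one row per (bone, position, group in Both/Left/Right)
    with n, avg and sd (sample sd) of the rotation angle and translation.
    ``pvalues``: one row per (bone, position, quantity) with the paired
    t-test across subjects.
    """

    cells: pd.DataFrame
    pvalues: pd.DataFrame

    def to_wide(self) -> pd.DataFrame:
        """Report-style layout: bones x (position, R/T) with avg/sd per group
        and the L-vs-R p-value row."""
        rows = []
        for bone in self.cells["bone"].unique():
            sub = self.cells[self.cells["bone"] == bone]
            psub = self.pvalues[self.pvalues["bone"] == bone]
            for group in ("Both", "Left", "Right"):
                g = sub[sub["group"] == group].set_index("position")
                for stat in ("avg", "sd"):
                    row = {"bone": bone, "row": f"{group}_{stat}"}
                    for pos in POSITION_LABELS:
                        if pos in g.index:
                            row[f"{pos}_R"] = g.loc[pos, f"angle_{stat}"]
                            row[f"{pos}_T"] = g.loc[pos, f"translation_{stat}"]
                    rows.append(row)
            prow = {"bone": bone, "row": "p_value"}
            for _, rec in psub.iterrows():
                key = f"{rec['position']}_{'R' if rec['quantity'] == 'angle' else 'T'}"
                prow[key] = rec["p"]
            rows.append(prow)
        return pd.DataFrame(rows)


def summarize(records: pd.DataFrame) -> SummaryResult:
    """Summarise kinematics records per bone x position.

    For every bone and non-neutral position: avg and sample sd (divisor
    n-1) of the helical angle and translation for the pooled (Both),
    Left and Right groups, and a paired t-test between hands pairing
    subjects.  Subjects missing one hand at a position are excluded from
    that pair test (logged).
    """
    missing = [c for c in REQUIRED_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    df = records[records["position_deg"].round() != 0].copy()
    df["position"] = [
        position_label(m, a) for m, a in zip(df["motion"], df["position_deg"])
    ]
    cells = []
    pvals = []
    quantities = (("angle", "ha_angle_deg"), ("translation", "ha_translation_mm"))
    for (bone, pos), grp in df.groupby(["bone", "position"], sort=False):
        for group, sel in (
            ("Both", grp),
            ("Left", grp[grp["hand"] == "L"]),
            ("Right", grp[grp["hand"] == "R"]),
        ):
            cell = {"bone": bone, "position": pos, "group": group, "n": len(sel)}
            for qname, col in quantities:
                vals = sel[col].to_numpy(dtype=float)
                cell[f"{qname}_avg"] = float(vals.mean()) if vals.size else np.nan
                cell[f"{qname}_sd"] = (
                    float(vals.std(ddof=1)) if vals.size > 1 else np.nan
                )
            cells.append(cell)
        lft = grp[grp["hand"] == "L"].set_index("subject")
        rgt = grp[grp["hand"] == "R"].set_index("subject")
        paired_subjects = sorted(set(lft.index) & set(rgt.index))
        dropped = (set(lft.index) | set(rgt.index)) - set(paired_subjects)
        if dropped:
            log.info("%s %s: subjects %s missing one hand, excluded from pair test",
                     bone, pos, sorted(dropped))
        for qname, col in quantities:
            if len(paired_subjects) >= 2:
                res = paired_t(
                    lft.loc[paired_subjects, col].to_numpy(dtype=float),
                    rgt.loc[paired_subjects, col].to_numpy(dtype=float),
                )
                pvals.append(
                    {
                        "bone": bone,
                        "position": pos,
                        "quantity": qname,
                        "t": res.t,
                        "p": res.p,
                        "df": res.df,
                        "n_pairs": len(paired_subjects),
                    }
                )
    pval_cols = ["bone", "position", "quantity", "t", "p", "df", "n_pairs"]
    return SummaryResult(
        cells=pd.DataFrame(cells),
        pvalues=pd.DataFrame(pvals, columns=pval_cols),
    )


def volume_stats(per_subject_volumes: np.ndarray) -> tuple[float, float]:
    """Mean and population (divisor n) standard deviation of bone volumes.

    The population convention is the one consistent with the study-style
    per-subject volume table; n = 1 gives sd 0.
    """
    vals = np.asarray(per_subject_volumes, dtype=float).ravel()
    if vals.size < 1:
        raise ValueError("need at least one volume")
    return float(vals.mean()), float(vals.std(ddof=0))
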