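"""Framewise-displacement motion QC and whole-subject exclusion rules.

Framewise displacement (FD) follows the Power formulation: the sum of absolute
frame-to-frame differences of the three translations (mm) and of the three
rotations, the latter converted to millimetres of arc on a sphere of assumed
head radius (default 50 mm). Subjects are excluded when mean FD exceeds
``fd_threshold`` (default 0.5 mm) or when the maximum absolute Euclidean
translation from the reference volume exceeds ``max_disp_threshold``
(default 4 mm); both comparisons are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MotionTrace",
    "MotionQC",
    "read_motion_file",
    "framewise_displacement",
    "apply_exclusions",
    "qc_table",
]

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_FD_THRESHOLD_MM = 0.5
DEFAULT_MAX_DISP_THRESHOLD_MM = 4.0


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters over time for one subject."""

    translations: np.ndarray  # (3, T) mm
    rotations: np.ndarray     # (3, T) radians
    tr_seconds: float = 0.906
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape[0] != 3 or self.rotations.shape[0] != 3:
            raise ValueError(
                "expected 3 translation and 3 rotation parameters, got "
                f"{self.translations.shape[0]} and {self.rotations.shape[0]}"
            )
        if self.translations.shape[1] != self.rotations.shape[1]:
            raise ValueError("translations and rotations must cover the same timepoints")
        if self.translations.shape[1] < 2:
            raise ValueError("motion trace needs at least 2 timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.translations.shape[1]


def read_motion_file(
    path: str | Path,
    tr_seconds: float = 0.906,
    rotations_first: bool = True,
    subject_id: str | None = None,
) -> MotionTrace:
    """Read a 6-column whitespace-delimited motion-parameter file (one row per volume).

    The default column order is the common realignment-output convention —
    rotations (radians) in columns 1-3, translations (mm) in columns 4-6;
    ``rotations_first=False`` flips it.
    """
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got shape {arr.shape}")
    a, b = arr[:, :3].T, arr[:, 3:].T
    rot, trans = (a, b) if rotations_first else (b, a)
    return MotionTrace(
        translations=trans, rotations=rot, tr_seconds=tr_seconds,
        subject_id=subject_id or Path(path).stem,
    )


@dataclass
class MotionQC:
    subject_id: str
    fd_series: np.ndarray          # (T-1,) mm
    mean_fd: float                 # mm
    max_abs_displacement: float    # mm, Euclidean translation from reference volume
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM
    excluded: bool = False
    reason: str = ""


def framewise_displacement(
    trace: MotionTrace,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    reference: str | int = "middle",
) -> MotionQC:
    """Compute the FD series, mean FD and maximum absolute displacement.

    FD_t = sum_i |Δtrans_i(t)| + r * sum_j |Δrot_j(t)|, t = 1..T-1.
    Maximum absolute displacement is the largest Euclidean distance of the
    translation vector from the reference volume (the middle volume by
    default, matching the usual motion-correction reference).
    """
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    dt = np.abs(np.diff(trace.translations, axis=1)).sum(axis=0)
    dr = np.abs(np.diff(trace.rotations, axis=1)).sum(axis=0)
    fd = dt + head_radius_mm * dr
    ref = trace.n_timepoints // 2 if reference == "middle" else int(reference)
    disp = np.linalg.norm(
        trace.translations - trace.translations[:, ref:ref + 1], axis=0
    )
    return MotionQC(
        subject_id=trace.subject_id,
        fd_series=fd,
        mean_fd=float(fd.mean()),
        max_abs_displacement=float(disp.max()),
        head_radius_mm=head_radius_mm,
    )


def apply_exclusions(
    qcs: list[MotionQC],
    fd_threshold: float = DEFAULT_FD_THRESHOLD_MM,
    max_disp_threshold: float = DEFAULT_MAX_DISP_THRESHOLD_MM,
) -> tuple[list[MotionQC], list[MotionQC]]:
    """Partition a cohort's QC records into (kept, excluded), annotating reasons.

    A subject is excluded when mean FD > fd_threshold (mm) or when the maximum
    absolute displacement from the reference volume > max_disp_threshold (mm);
    the triggering rule(s) are recorded on the record. The partition is
    exhaustive and disjoint.
    """
    if fd_threshold <= 0 or max_disp_threshold <= 0:
        raise ValueError("exclusion thresholds must be positive")
    if not qcs:
        raise ValueError("empty cohort: no QC records to partition")
    kept, excluded = [], []
    for qc in qcs:
        reasons = []
        if qc.mean_fd > fd_threshold:
            reasons.append(f"mean_fd {qc.mean_fd:.3f} > {fd_threshold}")
        if qc.max_abs_displacement > max_disp_threshold:
            reasons.append(
                f"max_abs_displacement {qc.max_abs_displacement:.3f} > {max_disp_threshold}"
            )
        qc.excluded = bool(reasons)
        qc.reason = "; ".join(reasons)
        (excluded if qc.excluded else kept).append(qc)
    return kept, excluded


def qc_table(qcs: list[MotionQC]) -> pd.DataFrame:
    """Cohort QC summary, one row per subject."""
    return pd.DataFrame(
        {
            "subject_id": [q.subject_id for q in qcs],
            "mean_fd": [q.mean_fd for q in qcs],
            "max_abs_displacement": [q.max_abs_displacement for q in qcs],
            "excluded": [q.excluded for q in qcs],
            "reason": [q.reason for q in qcs],
        }
    )
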