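"""Evaluation of findings masks against ground truth.

Implements the segmentation-overlap metrics used to validate voxel-based
lesion detection: Dice score, voxel-wise true/false-positive rates,
subject-level concordance, cohort sensitivity, and leave-one-out control
specificity.  "Visual concordance" between a thresholded p-map and the
ground truth is operationalized as a minimum voxel overlap (default 1
voxel) — the weakest objective surrogate for a human reader's judgment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .volume_io import BinaryMask

__all__ = [
    "MetricsReport",
    "SubjectMetrics",
    "dice_score",
    "voxelwise_rates",
    "subject_concordant",
    "cohort_sensitivity",
    "cohort_specificity",
    "leave_one_out_controls",
]


@dataclass
class SubjectMetrics:
    subject_id: str
    dice: float | None = None
    tp_rate: float | None = None   # percent
    fp_rate: float | None = None   # percent
    concordant: bool | None = None
    n_findings_voxels: int = 0


@dataclass
class MetricsReport:
    """Per-subject and cohort-level metrics for one analysis."""

    analysis: str                     # e.g. "NDI/decrease" or "NPC"
    subjects: list[SubjectMetrics] = field(default_factory=list)
    sensitivity: float | None = None  # percent, rounded to integer
    specificity: float | None = None  # percent, rounded to integer
    mean_dice: float | None = None
    mean_tp_rate: float | None = None
    mean_fp_rate: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2,
                                         sort_keys=True))

    def to_frame(self) -> pd.DataFrame:
        """One row per subject plus a summary row, Table-style."""
        rows = [asdict(s) for s in self.subjects]
        summary = {
            "subject_id": f"cohort:{self.analysis}",
            "dice": self.mean_dice, "tp_rate": self.mean_tp_rate,
            "fp_rate": self.mean_fp_rate, "concordant": None,
            "n_findings_voxels": sum(s.n_findings_voxels for s in self.subjects),
        }
        return pd.DataFrame(rows + [summary])


def _check_shapes(*masks: BinaryMask) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {shapes}")


def dice_score(findings: BinaryMask, truth: BinaryMask) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); both-empty is defined as 0."""
    _check_shapes(findings, truth)
    a, b = findings.n_voxels, truth.n_voxels
    if a + b == 0:
        warnings.warn("both masks empty; Dice defined as 0", stacklevel=2)
        return 0.0
    inter = int(np.count_nonzero(findings.data & truth.data))
    return 2.0 * inter / (a + b)


def voxelwise_rates(findings: BinaryMask, truth: BinaryMask,
                    brain: BinaryMask) -> tuple[float, float]:
    """Per-subject voxel-wise (true-positive %, false-positive %) rates.

    tp = 100 * |findings ∩ truth| / |truth|;
    fp = 100 * |findings \\ truth| / |brain|.
    """
    _check_shapes(findings, truth, brain)
    if truth.n_voxels == 0:
        raise ValueError("truth mask is empty")
    if np.any(findings.data & ~brain.data):
        raise ValueError("findings extend outside the brain mask")
    inter = int(np.count_nonzero(findings.data & truth.data))
    outside = int(np.count_nonzero(findings.data & ~truth.data))
    tp = 100.0 * inter / truth.n_voxels
    fp = 100.0 * outside / brain.n_voxels
    return tp, fp


def subject_concordant(findings: BinaryMask, truth: BinaryMask,
                       min_overlap_voxels: int = 1) -> bool:
    """Surrogate for visual concordance: true iff overlap >= min_overlap_voxels."""
    _check_shapes(findings, truth)
    inter = int(np.count_nonzero(findings.data & truth.data))
    return inter >= min_overlap_voxels


def cohort_sensitivity(concordance_flags: list[bool]) -> int:
    """Percent of subjects whose findings are concordant with ground truth,
    rounded to the nearest integer percent."""
    if not concordance_flags:
        raise ValueError("empty flag list")
    return round(100.0 * sum(bool(f) for f in concordance_flags)
                 / len(concordance_flags))


def cohort_specificity(has_findings_flags: list[bool]) -> int:
    """Percent of control subjects with no findings at all, rounded to the
    nearest integer percent."""
    if not has_findings_flags:
        raise ValueError("empty flag list")
    clean = sum(1 for f in has_findings_flags if not f)
    return round(100.0 * clean / len(has_findings_flags))


def leave_one_out_controls(controls, mask, run_analysis) -> tuple[list[bool], int]:
    """Leave-one-out specificity over the control group.

    Each control in turn becomes the pseudo-patient and is compared against
    the remaining controls with the configured analysis.  ``controls`` is a
    (n_subjects, nx, ny, nz) stack for a univariate analysis or a dict
    modality -> stack for NPC.  ``run_analysis(patient, rest)`` must return
    a :class:`~mvba.perm_stats.FindingsMask`-like object.

    Returns the per-control has-findings flags and the resulting
    specificity percentage.
    """
    if isinstance(controls, dict):
        n = next(iter(controls.values())).shape[0]
    else:
        n = controls.shape[0]
    if n < 3:
        raise ValueError("leave-one-out requires at least 3 controls")
    flags: list[bool] = []
    for i in range(n):
        keep = np.arange(n) != i
        if isinstance(controls, dict):
            patient = {m: stack[i] for m, stack in controls.items()}
            rest = {m: stack[keep] for m, stack in controls.items()}
        else:
            patient = controls[i]
            rest = controls[keep]
        result = run_analysis(patient, rest)
        flags.append(bool(result.findings.data.any()))
    return flags, cohort_specificity(flags)
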