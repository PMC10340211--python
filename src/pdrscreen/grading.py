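"""Image grading from surviving regions, and confusion-matrix evaluation.

Grading rule: an image with no surviving abnormal-vessel region is healthy
(grade 0); a region within one disc distance of the optic disc center marks
neovascularization on the disc (grade 2, NVD); a region farther out marks
neovascularization elsewhere (grade 1, NVE).  An image can carry both
grades.  The distance comparison at exactly 1dd is inclusive (NVD).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .optic_disc import OpticDisc
from .regions import CandidateRegion

__all__ = ["GradeReport", "ConfusionCounts", "grade_image", "evaluate",
           "metrics_from_counts", "evaluate_image_level"]


@dataclass(frozen=True)
class GradeReport:
    grades: frozenset[int]
    per_region: tuple[tuple[int, str, float], ...]  # (label_id, zone, distance px)
    od: OpticDisc | None
    status: str = "graded"          # graded | ungradable

    @property
    def is_healthy(self) -> bool:
        return self.grades == frozenset({0})


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def grade_image(regions: list[CandidateRegion], od: OpticDisc | None,
                distance_mode: str = "centroid") -> GradeReport:
    """Assemble the grade set from surviving regions and OD geometry.

    With no optic disc the image is ungradable.  The report is a pure
    function of the region zones: permuting region order never changes it.
    """
    if od is None:
        return GradeReport(grades=frozenset(), per_region=(), od=None,
                           status="ungradable")
    per_region = []
    grades: set[int] = set()
    for reg in regions:
        dist = reg.distance_to(od.center, mode=distance_mode)
        zone = "NVD" if dist <= od.one_dd else "NVE"
        per_region.append((reg.label_id, zone, dist))
        grades.add(2 if zone == "NVD" else 1)
    if not per_region:
        grades = {0}
    return GradeReport(grades=frozenset(grades),
                       per_region=tuple(per_region), od=od)


def evaluate(pred_regions: list[CandidateRegion], truth_mask: np.ndarray,
             truth_negatives: int = 0, overlap_frac: float = 0.2,
             ) -> tuple[ConfusionCounts, dict[str, float]]:
    """Region-level confusion counts against a ground-truth lesion mask.

    A predicted region is a true positive when at least ``overlap_frac`` of
    its pixels lie on the truth mask, else a false positive.  False
    negatives are truth lesion components touched by no true-positive
    region.  True negatives come from ``truth_negatives`` (labeled
    lesion-free regions or images).
    """
    if not (0 < overlap_frac <= 1):
        raise ValueError(f"overlap_frac must be in (0, 1], got {overlap_frac}")
    truth = truth_mask.astype(bool)
    tp = fp = 0
    matched = np.zeros_like(truth)
    for reg in pred_regions:
        on_truth = truth[reg.rows, reg.cols]
        if on_truth.sum() >= overlap_frac * reg.area:
            tp += 1
            matched[reg.rows[on_truth], reg.cols[on_truth]] = True
        else:
            fp += 1
    labels, n_lesions = ndimage.label(truth, structure=np.ones((3, 3)))
    fn = 0
    for lab in range(1, n_lesions + 1):
        if not matched[labels == lab].any():
            fn += 1
    counts = ConfusionCounts(tp=tp, tn=int(truth_negatives), fp=fp, fn=fn)
    return counts, metrics_from_counts(counts)


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, accuracy as fractions in [0, 1].

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    accuracy = (TP+TN)/(TP+TN+FP+FN).  Ratios with zero denominator are
    reported as NaN with a warning.
    """
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return math.nan
        return num / den

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": ratio(c.tn, c.tn + c.fp, "specificity"),
        "ppv": ratio(c.tp, c.tp + c.fp, "ppv"),
        "accuracy": ratio(c.tp + c.tn, c.total, "accuracy"),
    }


def evaluate_image_level(predicted: list[frozenset[int] | set[int]],
                         expected: list[frozenset[int] | set[int]],
                         ) -> tuple[ConfusionCounts, dict[str, float]]:
    """Image-level confusion: positive = any neovascular grade (1 or 2)."""
    if len(predicted) != len(expected):
        raise ValueError("prediction/truth lists differ in length")
    tp = tn = fp = fn = 0
    for p, e in zip(predicted, expected):
        p_pos = bool(set(p) & {1, 2})
        e_pos = bool(set(e) & {1, 2})
        if p_pos and e_pos:
            tp += 1
        elif p_pos:
            fp += 1
        elif e_pos:
            fn += 1
        else:
            tn += 1
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return counts, metrics_from_counts(counts)
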