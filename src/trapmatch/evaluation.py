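"""Confusion counting against ground truth and recall/precision/F-measure.

Detections are matched one-to-one to annotated insects by center distance
(greedy, closest pairs first, within a tolerance of half the template width
by default).  Counts follow the mosquito-detection convention:

* TP — a mosquito-labeled detection matched to a mosquito;
* FN — a mosquito annotation with no matching mosquito-labeled detection;
* FP — a mosquito-labeled detection matched to a non-mosquito or to nothing.

Metrics are the standard ratios recall = TP/(TP+FN), precision = TP/(TP+FP)
and the F-measure, their harmonic mean.  Zero denominators raise
:class:`UndefinedMetricError` rather than silently reporting 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detection import Detection, DetectionConfig, detect
from .errors import UndefinedMetricError

#: Default matching tolerance: half the nominal template width.
DEFAULT_MATCH_TOL = 100.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class Metrics:
    """Recall, precision and F-measure as fractions in [0, 1]."""

    recall: float
    precision: float
    f_measure: float

    def as_percent(self) -> dict[str, float]:
        """Values scaled to percent and rounded to one decimal for display."""
        return {
            "recall": round(100 * self.recall, 1),
            "precision": round(100 * self.precision, 1),
            "f_measure": round(100 * self.f_measure, 1),
        }


def pair_detections(
    detections: list[Detection],
    truth: list,
    tol: float = DEFAULT_MATCH_TOL,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections to annotations.

    Candidate pairs within ``tol`` of each other are accepted closest-first,
    each detection and each annotation at most once, so the result does not
    depend on the order detections are listed in (up to exact distance ties).
    Returns (detection index, truth index) pairs.
    """
    pairs = []
    for i, det in enumerate(detections):
        for j, t in enumerate(truth):
            d = float(np.hypot(det.center_x - t.center_x, det.center_y - t.center_y))
            if d <= tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        matches.append((i, j))
    return matches


def match_to_ground_truth(
    detections: list[Detection],
    truth: list,
    tol: float = DEFAULT_MATCH_TOL,
) -> ConfusionCounts:
    """Confusion counts for mosquito detection on one image (or batch)."""
    matches = pair_detections(detections, truth, tol)
    det_to_truth = dict(matches)
    tp = fp = 0
    for i, det in enumerate(detections):
        if det.label != "mosquito":
            continue
        j = det_to_truth.get(i)
        if j is not None and truth[j].species == "mosquito":
            tp += 1
        else:
            fp += 1
    # A mosquito annotation counts FN unless matched by a mosquito-labeled
    # detection.
    fn = 0
    truth_to_det = {j: i for i, j in matches}
    for j, t in enumerate(truth):
        if t.species != "mosquito":
            continue
        i = truth_to_det.get(j)
        if i is None or detections[i].label != "mosquito":
            fn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp)


def recall(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return counts.tp / (counts.tp + counts.fn)


def precision(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    return counts.tp / (counts.tp + counts.fp)


def f_measure(counts: ConfusionCounts) -> float:
    p, r = precision(counts), recall(counts)
    if p + r == 0:
        raise UndefinedMetricError("F-measure undefined: precision + recall = 0")
    return 2 * p * r / (p + r)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """All three metrics; raises if any denominator is zero."""
    return Metrics(recall=recall(counts), precision=precision(counts),
                   f_measure=f_measure(counts))


def detection_rate(
    scenes: list,
    template: np.ndarray,
    config: DetectionConfig,
    tol: float | None = None,
) -> float:
    """Fraction of annotated insects matched by any detection (label-blind)."""
    tol = tol if tol is not None else np.asarray(template).shape[1] / 2
    found = total = 0
    for image, annotations in scenes:
        dets = detect(image, template, config)
        found += len(pair_detections(dets, annotations, tol))
        total += len(annotations)
    if total == 0:
        raise ValueError("scene set contains no annotated insects")
    return found / total


def ablation_table(
    scenes: list,
    template: np.ndarray,
    config: DetectionConfig | None = None,
) -> pd.DataFrame:
    """Detection rates of the three operating modes on the same scenes.

    Rows: single-template matching (no covering, no padding), multi-target
    matching (covering only), and the full detector (covering + padding).
    """
    if not scenes:
        raise ValueError("empty scene set")
    config = config or DetectionConfig()
    modes = {
        "single_template": replace(config, enable_covering=False, enable_padding=False),
        "multi_target_covering": replace(config, enable_covering=True, enable_padding=False),
        "covering_and_padding": replace(config, enable_covering=True, enable_padding=True),
    }
    rates = {name: detection_rate(scenes, template, cfg)
             for name, cfg in modes.items()}
    return pd.DataFrame(
        {"detection_rate": list(rates.values())}, index=list(rates.keys())
    )


def distribution_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of samples a single threshold cannot separate.

    The minimum, over all cut points and both orientations, of the combined
    misclassification fraction; 0 means the two 1-D samples are perfectly
    separable.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    cuts = np.concatenate(([-np.inf], np.unique(np.concatenate((a, b))), [np.inf]))
    n = len(a) + len(b)
    best = 1.0
    for c in cuts:
        a_below = np.searchsorted(a, c, side="right")
        b_below = np.searchsorted(b, c, side="right")
        err_a_low = (len(a) - a_below) + b_below          # a below cut, b above
        err_b_low = a_below + (len(b) - b_below)          # b below cut, a above
        best = min(best, err_a_low / n, err_b_low / n)
    return best
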