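"""Accuracy metrics: object keypoint similarity (OKS), greedy instance
matching, VOC/PoseTrack-style mAP/mAR, localization-error summaries and
identity-switch counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Instance, LabeledFrame

logger = logging.getLogger(__name__)

__all__ = [
    "OKSParams",
    "FrameMatches",
    "EvalResult",
    "compute_oks",
    "match_frame_instances",
    "compute_map",
    "localization_errors",
    "count_id_switches",
    "OKS_THRESHOLDS",
    "RECALL_POINTS",
]

OKS_THRESHOLDS = np.arange(0.50, 1.00, 0.05)  # {0.50, 0.55, ..., 0.95}
RECALL_POINTS = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class OKSParams:
    """Per-node uncertainty and scale parameters for OKS."""

    sigma: float = 0.025  # identical per-node uncertainty factor
    min_area: float = 1.0  # floor for degenerate (zero-area) GT bboxes


@dataclass
class FrameMatches:
    pairs: list[tuple[Instance, Instance, float]] = field(default_factory=list)
    unmatched_gt: list[Instance] = field(default_factory=list)
    unmatched_pred: list[Instance] = field(default_factory=list)

    @property
    def n_gt(self) -> int:
        return len(self.pairs) + len(self.unmatched_gt)

    @property
    def n_pred(self) -> int:
        return len(self.pairs) + len(self.unmatched_pred)


@dataclass
class EvalResult:
    thresholds: np.ndarray
    ap_per_threshold: np.ndarray
    ar_per_threshold: np.ndarray
    mAP: float
    mAR: float
    precisions: list[np.ndarray] = field(default_factory=list)
    recalls: list[np.ndarray] = field(default_factory=list)


def _gt_bbox_area(gt: Instance, params: OKSParams) -> float:
    x0, y0, x1, y1 = gt.bbox()
    return max((x1 - x0) * (y1 - y0), params.min_area)


def compute_oks(
    gt: Instance,
    pred: Instance,
    params: OKSParams = OKSParams(),
) -> float:
    """Object keypoint similarity between a ground-truth and a predicted
    instance.

    ``sum_i exp(-||X_i - Xhat_i||^2 / (2 alpha sigma_i^2)) delta_i / sum_i delta_i``
    where ``delta_i`` is GT visibility, ``alpha`` the GT visible-bbox area
    (floored at ``min_area``), and a node the prediction misses
    contributes 0 to the numerator.
    """
    if gt.skeleton.nodes != pred.skeleton.nodes:
        raise ValueError("instances must share a skeleton")
    delta = gt.visible
    n_vis = int(delta.sum())
    if n_vis == 0:
        raise ValueError("ground-truth instance has no visible nodes")
    alpha = _gt_bbox_area(gt, params)
    both = delta & pred.visible
    d2 = np.sum((gt.points[both] - pred.points[both]) ** 2, axis=1)
    terms = np.exp(-d2 / (2.0 * alpha * params.sigma**2))
    return float(terms.sum() / n_vis)


def match_frame_instances(
    gt_list: Sequence[Instance],
    pred_list: Sequence[Instance],
    params: OKSParams = OKSParams(),
) -> FrameMatches:
    """Greedy one-to-one matching by descending OKS within one frame."""
    oks = np.zeros((len(gt_list), len(pred_list)))
    for i, gt in enumerate(gt_list):
        for j, pred in enumerate(pred_list):
            oks[i, j] = compute_oks(gt, pred, params)
    result = FrameMatches()
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    if oks.size:
        order = np.argsort(-oks, axis=None, kind="stable")
        for flat in order:
            i, j = np.unravel_index(flat, oks.shape)
            if i in used_gt or j in used_pred:
                continue
            used_gt.add(int(i))
            used_pred.add(int(j))
            result.pairs.append((gt_list[i], pred_list[j], float(oks[i, j])))
    result.unmatched_gt = [g for i, g in enumerate(gt_list) if i not in used_gt]
    result.unmatched_pred = [p for j, p in enumerate(pred_list) if j not in used_pred]
    return result


def compute_map(matches: Sequence[FrameMatches]) -> EvalResult:
    """mAP/mAR over ten OKS thresholds with 101-point interpolated precision.

    Per threshold, every prediction (matched pairs carry their OKS;
    unmatched predictions score 0) is sorted by OKS; cumulative TP/FP
    give precision/recall curves; AP is the mean over 101 evenly spaced
    recall points of the best precision achieved at recall >= that point,
    and AR is the best recall at that threshold.
    """
    if not matches:
        raise ValueError("need matches from at least one frame")
    pred_oks = np.array(
        [oks for m in matches for (_, _, oks) in m.pairs]
        + [0.0 for m in matches for _ in m.unmatched_pred]
    )
    n_gt = sum(m.n_gt for m in matches)
    if pred_oks.size == 0 or n_gt == 0:
        warnings.warn("no predictions or no ground truth; mAP is 0", stacklevel=2)
        z = np.zeros_like(OKS_THRESHOLDS)
        return EvalResult(OKS_THRESHOLDS.copy(), z, z.copy(), 0.0, 0.0)

    order = np.argsort(-pred_oks, kind="stable")
    sorted_oks = pred_oks[order]
    aps = np.zeros(len(OKS_THRESHOLDS))
    ars = np.zeros(len(OKS_THRESHOLDS))
    precisions, recalls = [], []
    for ti, thr in enumerate(OKS_THRESHOLDS):
        tp = (sorted_oks >= thr).astype(np.float64)
        cum_tp = np.cumsum(tp)
        ranks = np.arange(1, len(tp) + 1)
        precision = cum_tp / ranks
        recall = cum_tp / n_gt
        # Interpolated precision: best precision at any recall >= r.  The
        # running max from the right makes the curve monotone so a simple
        # search suffices.
        prec_interp = np.maximum.accumulate(precision[::-1])[::-1]
        ap_points = np.zeros(len(RECALL_POINTS))
        for ri, r in enumerate(RECALL_POINTS):
            idx = np.searchsorted(recall, r, side="left")
            if idx < len(prec_interp):
                ap_points[ri] = prec_interp[idx]
        aps[ti] = ap_points.mean()
        ars[ti] = recall[-1] if len(recall) else 0.0
        precisions.append(precision)
        recalls.append(recall)
    return EvalResult(
        thresholds=OKS_THRESHOLDS.copy(),
        ap_per_threshold=aps,
        ar_per_threshold=ars,
        mAP=float(aps.mean()),
        mAR=float(ars.mean()),
        precisions=precisions,
        recalls=recalls,
    )


def localization_errors(
    matches: Sequence[FrameMatches],
    percentiles: Sequence[float] = (50.0, 90.0, 95.0),
) -> tuple[np.ndarray, dict[float, float]]:
    """Euclidean error for every jointly visible node of every matched
    pair, plus percentile summaries."""
    errors = []
    for m in matches:
        for gt, pred, _ in m.pairs:
            both = gt.visible & pred.visible
            diffs = gt.points[both] - pred.points[both]
            errors.extend(np.linalg.norm(diffs, axis=1))
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        return errors, {p: float("nan") for p in percentiles}
    return errors, {p: float(np.percentile(errors, p)) for p in percentiles}


def count_id_switches(
    gt_frames: Sequence[LabeledFrame],
    pred_frames: Sequence[LabeledFrame],
    params: OKSParams = OKSParams(),
) -> tuple[int, float]:
    """Count identity switches between two tracked sessions.

    Instances are matched per frame by greedy OKS; a switch is counted
    whenever a GT track's assigned predicted track id differs from its
    most recent previous assignment (standard MOT definition).  The rate
    is per 100,000 frames.
    """
    if len(gt_frames) != len(pred_frames):
        raise ValueError("sessions must cover the same frames")
    last_assignment: dict[int, int] = {}
    switches = 0
    for gt_lf, pred_lf in zip(gt_frames, pred_frames):
        if gt_lf.frame_index != pred_lf.frame_index:
            raise ValueError("sessions must cover the same frames")
        m = match_frame_instances(gt_lf.instances, pred_lf.instances, params)
        for gt, pred, _ in m.pairs:
            if gt.track_id is None or pred.track_id is None:
                continue
            prev = last_assignment.get(gt.track_id)
            if prev is not None and prev != pred.track_id:
                switches += 1
            last_assignment[gt.track_id] = pred.track_id
    n_frames = len(gt_frames)
    rate = switches / n_frames * 100_000.0 if n_frames else 0.0
    return switches, rate
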