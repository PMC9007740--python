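"""Temporal identity association via flow-shift tracking.

Previous poses are advected onto the current frame with a sparse
pyramidal Lucas-Kanade flow estimated at each landmark, then matched to
new detections by minimum mean landmark distance (Hungarian).  Tracks
are never merged; a lost track stays dormant until it leaves the
sliding window.
"""

from __future__ import annotations

import dataclasses
from collections import deque
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import linear_sum_assignment

from .model import Instance, LabeledFrame, LabelsDataset, Track

__all__ = [
    "FlowParams",
    "TrackerParams",
    "TrackerState",
    "lucas_kanade",
    "flow_shift",
    "tracking_cost",
    "track_frame",
    "run_tracker",
]


@dataclass(frozen=True)
class FlowParams:
    levels: int = 3
    patch_size: int = 21
    iterations: int = 20
    min_eigenvalue: float = 1e-3  # structure-tensor threshold for trackability


@dataclass
class TrackerParams:
    window_size: int = 5
    cost_threshold: Optional[float] = None  # None: half median bbox diagonal at cold start
    flow: FlowParams = field(default_factory=FlowParams)

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class _WindowEntry:
    frame_index: int
    image: np.ndarray
    instances: list[Instance]


@dataclass
class TrackerState:
    params: TrackerParams
    window: deque = field(default_factory=deque)
    active_tracks: list[Track] = field(default_factory=list)
    next_track_id: int = 0


# ---------------------------------------------------------------------------
# Sparse pyramidal Lucas-Kanade optical flow
# ---------------------------------------------------------------------------


def _build_pyramid(img: np.ndarray, levels: int) -> list[np.ndarray]:
    pyr = [np.asarray(img, dtype=np.float64)]
    for _ in range(levels - 1):
        prev = pyr[-1]
        if min(prev.shape) < 16:
            break
        pyr.append(gaussian_filter(prev, 1.0)[::2, ::2])
    return pyr


def lucas_kanade(
    img_prev: np.ndarray,
    img_cur: np.ndarray,
    points: np.ndarray,
    params: FlowParams = FlowParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-point translation from ``img_prev`` to ``img_cur``.

    Parameters
    ----------
    points : (n, 2) array of (x, y) image coordinates in ``img_prev``.

    Returns
    -------
    shifted : (n, 2) array of advected coordinates (input coordinates
        where tracking failed).
    ok : (n,) boolean array, false where the local structure tensor was
        degenerate (textureless patch) or the point was out of frame.
    """
    if img_prev.shape != img_cur.shape:
        raise ValueError("images must have identical shapes")
    if img_prev.ndim != 2:
        raise ValueError("images must be grayscale (2D)")
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(points)
    flows = np.zeros((n, 2))
    ok = np.ones(n, dtype=bool)
    if n == 0:
        return points.copy(), ok

    pyr_prev = _build_pyramid(img_prev, params.levels)
    pyr_cur = _build_pyramid(img_cur, params.levels)
    half = params.patch_size // 2
    offs = np.arange(-half, half + 1, dtype=np.float64)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")

    grads = [np.gradient(im) for im in pyr_prev]  # (gy, gx) per level

    for pi in range(n):
        x, y = points[pi]
        d = np.zeros(2)  # flow at current level, (dx, dy)
        tracked = False
        for lvl in range(len(pyr_prev) - 1, -1, -1):
            scale = 2.0**lvl
            px, py = x / scale, y / scale
            im0, im1 = pyr_prev[lvl], pyr_cur[lvl]
            h, w = im0.shape
            if not (0 <= px < w and 0 <= py < h):
                continue
            coords0 = np.array([py + oy.ravel(), px + ox.ravel()])
            patch0 = map_coordinates(im0, coords0, order=1, mode="nearest")
            gy, gx = grads[lvl]
            ix = map_coordinates(gx, coords0, order=1, mode="nearest")
            iy = map_coordinates(gy, coords0, order=1, mode="nearest")
            gxx = float(np.dot(ix, ix))
            gyy = float(np.dot(iy, iy))
            gxy = float(np.dot(ix, iy))
            det = gxx * gyy - gxy * gxy
            trace = gxx + gyy
            lmin = 0.5 * (trace - np.sqrt(max((gxx - gyy) ** 2 + 4 * gxy * gxy, 0.0)))
            if lmin <= params.min_eigenvalue or det <= 0:
                if lvl > 0:
                    d *= 2.0
                continue
            d_init = d.copy()
            for _ in range(params.iterations):
                coords1 = np.array(
                    [py + d[1] + oy.ravel(), px + d[0] + ox.ravel()]
                )
                patch1 = map_coordinates(im1, coords1, order=1, mode="nearest")
                dt = patch0 - patch1
                bx = float(np.dot(ix, dt))
                by = float(np.dot(iy, dt))
                vx = (gyy * bx - gxy * by) / det
                vy = (gxx * by - gxy * bx) / det
                d += (vx, vy)
                if vx * vx + vy * vy < 1e-6:
                    break
            if np.linalg.norm(d - d_init) > params.patch_size / 2.0:
                d = d_init  # diverged at this level; keep the coarser estimate
            else:
                tracked = True
            if lvl > 0:
                d *= 2.0
        if tracked and np.all(np.isfinite(d)):
            # Residual sanity check: the flow must not fit worse than no
            # motion at all (guards against locking onto the wrong blob).
            coords_ref = np.array([y + oy.ravel(), x + ox.ravel()])
            patch_ref = map_coordinates(pyr_prev[0], coords_ref, order=1, mode="nearest")
            coords_new = np.array([y + d[1] + oy.ravel(), x + d[0] + ox.ravel()])
            ssd_new = float(
                np.sum((patch_ref - map_coordinates(pyr_cur[0], coords_new, order=1, mode="nearest")) ** 2)
            )
            ssd_zero = float(
                np.sum((patch_ref - map_coordinates(pyr_cur[0], coords_ref, order=1, mode="nearest")) ** 2)
            )
            if ssd_new <= ssd_zero + 1e-12:
                flows[pi] = d
            else:
                ok[pi] = False
        else:
            ok[pi] = False
    return points + flows, ok


def flow_shift(
    img_prev: np.ndarray,
    img_cur: np.ndarray,
    instances_prev: Sequence[Instance],
    params: FlowParams = FlowParams(),
) -> tuple[list[Instance], list[np.ndarray]]:
    """Advect each instance's visible points by sparse optical flow.

    Returns shifted instance copies and, per instance, the boolean flags
    marking which visible points were successfully tracked (untrackable
    points keep their previous coordinates).
    """
    shifted: list[Instance] = []
    flags: list[np.ndarray] = []
    for inst in instances_prev:
        pts = inst.points[inst.visible]
        new_pts, ok = lucas_kanade(img_prev, img_cur, pts, params)
        out = inst.points.copy()
        out[inst.visible] = new_pts
        shifted.append(dataclasses.replace(inst, points=out))
        flags.append(ok)
    return shifted, flags


def tracking_cost(
    shifted_candidates: Sequence[Instance],
    new_instances: Sequence[Instance],
) -> np.ndarray:
    """Cost matrix: mean Euclidean distance over jointly visible nodes,
    +inf where two instances share no visible node."""
    cost = np.full((len(shifted_candidates), len(new_instances)), np.inf)
    for i, cand in enumerate(shifted_candidates):
        for j, new in enumerate(new_instances):
            both = cand.visible & new.visible
            if not both.any():
                continue
            diffs = cand.points[both] - new.points[both]
            cost[i, j] = float(np.linalg.norm(diffs, axis=1).mean())
    return cost


def _default_cost_threshold(instances: Sequence[Instance]) -> float:
    diags = []
    for inst in instances:
        x0, y0, x1, y1 = inst.bbox()
        diags.append(np.hypot(x1 - x0, y1 - y0))
    return float(np.median(diags)) / 2.0 if diags else np.inf


def track_frame(
    state: TrackerState,
    new_instances: Sequence[Instance],
    img: np.ndarray,
    frame_index: int = 0,
) -> list[Instance]:
    """Assign track ids to the instances of one frame and advance the state.

    Candidates are the latest occurrence of each track within the window,
    flow-shifted frame-to-frame up to the current frame.  Matching is a
    one-to-one minimum-cost assignment; pairs above the cost threshold
    are rejected and unmatched new instances spawn fresh tracks.
    """
    params = state.params
    if params.cost_threshold is None and new_instances:
        params.cost_threshold = _default_cost_threshold(new_instances)

    # Latest occurrence of each track in the window, with its window position.
    latest: dict[int, tuple[int, Instance]] = {}
    entries = list(state.window)
    for wi, entry in enumerate(entries):
        for inst in entry.instances:
            if inst.track_id is not None:
                latest[inst.track_id] = (wi, inst)

    candidates: list[Instance] = []
    for tid, (wi, inst) in sorted(latest.items()):
        cur = inst
        for j in range(wi, len(entries) - 1):
            cur = flow_shift(
                entries[j].image, entries[j + 1].image, [cur], params.flow
            )[0][0]
        if entries:
            cur = flow_shift(entries[-1].image, img, [cur], params.flow)[0][0]
        candidates.append(cur)

    assigned: list[Instance] = [dataclasses.replace(inst) for inst in new_instances]
    matched_new: set[int] = set()
    if candidates and assigned:
        cost = tracking_cost(candidates, assigned)
        finite = np.where(np.isfinite(cost), cost, 1e12)
        rows, cols = linear_sum_assignment(finite)
        for i, j in zip(rows, cols):
            if np.isfinite(cost[i, j]) and cost[i, j] <= params.cost_threshold:
                assigned[j].track_id = candidates[i].track_id
                matched_new.add(j)
    for j, inst in enumerate(assigned):
        if j not in matched_new:
            inst.track_id = state.next_track_id
            state.active_tracks.append(Track(state.next_track_id))
            state.next_track_id += 1

    state.window.append(
        _WindowEntry(frame_index=frame_index, image=np.asarray(img), instances=assigned)
    )
    while len(state.window) > params.window_size:
        state.window.popleft()
    return assigned


def run_tracker(
    frames: Sequence[LabeledFrame],
    images: Sequence[np.ndarray],
    params: Optional[TrackerParams] = None,
    image_size: Optional[tuple[int, int]] = None,
    video_id: str = "tracked",
) -> tuple[LabelsDataset, dict]:
    """Track a whole session deterministically.

    ``frames`` must be ordered by strictly increasing ``frame_index`` and
    aligned one-to-one with ``images``.  Returns the tracked dataset and
    a summary with the track count and per-frame assignments.
    """
    if not frames:
        raise ValueError("empty session")
    if len(frames) != len(images):
        raise ValueError("need exactly one image per frame")
    indices = [lf.frame_index for lf in frames]
    if any(b <= a for a, b in zip(indices, indices[1:])):
        raise ValueError("frames must be ordered by strictly increasing frame_index")
    params = params or TrackerParams()
    state = TrackerState(params=params)
    out_frames: list[LabeledFrame] = []
    assignments: list[list[int]] = []
    for lf, img in zip(frames, images):
        tracked = track_frame(state, lf.instances, img, lf.frame_index)
        out_frames.append(LabeledFrame(lf.video_id, lf.frame_index, tracked))
        assignments.append([inst.track_id for inst in tracked])
    if image_size is None:
        image_size = images[0].shape[:2]
    skeleton = out_frames[0].instances[0].skeleton if out_frames[0].instances else None
    if skeleton is None:
        for lf in out_frames:
            if lf.instances:
                skeleton = lf.instances[0].skeleton
                break
    dataset = LabelsDataset(
        skeleton=skeleton,
        frames=out_frames,
        tracks=list(state.active_tracks),
        image_size=tuple(image_size),
        provenance=f"run_tracker(window={params.window_size})",
    )
    summary = {
        "n_tracks": len(state.active_tracks),
        "assignments": assignments,
        "cost_threshold": params.cost_threshold,
    }
    return dataset, summary
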