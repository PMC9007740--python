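"""Seeded synthetic scene and session generation.

Stands in for cameras and trained networks during testing: scenes are
sets of well-separated ground-truth instances, sessions move them along
constant-velocity trajectories with border reflection and optional
jitter, and rendered frames draw a textured Gaussian blob per landmark
so optical flow has something to grab onto.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import Instance, LabeledFrame, LabelsDataset, Skeleton, Track

__all__ = [
    "SceneSpec",
    "SessionSpec",
    "star_skeleton",
    "generate_scene",
    "generate_session",
    "session_to_dataset",
    "render_instances",
]

_PLACEMENT_ATTEMPTS = 10_000


def star_skeleton(n_nodes: int, name: str = "star") -> Skeleton:
    """A rooted star: node 0 is the hub, edges (0, k) for k = 1..n-1."""
    if n_nodes < 1:
        raise ValueError("skeleton needs at least one node")
    nodes = [f"part{k}" for k in range(n_nodes)]
    edges = [(0, k) for k in range(1, n_nodes)]
    return Skeleton(nodes=nodes, edges=edges, name=name)


@dataclass(frozen=True)
class SceneSpec:
    skeleton: Skeleton
    image_size: tuple[int, int] = (256, 256)  # (H, W)
    n_instances: int = 2
    min_separation: float = 64.0
    pose_scale: float = 16.0
    noise_sigma: float = 0.0
    occlude_prob: float = 0.0
    with_classes: bool = False
    blob_sigma: float = 2.0
    border_margin: float = 10.0  # keeps landmarks clear of refinement patches
    seed: int = 0

    def __post_init__(self):
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class SessionSpec:
    scene: SceneSpec
    n_frames: int = 100
    max_step: float = 2.0
    jitter_sigma: float = 0.0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.max_step < 0:
            raise ValueError("max_step must be >= 0")


def _pose_offsets(skeleton: Skeleton, pose_scale: float, theta: float) -> np.ndarray:
    """Node offsets from the centroid: hub at 0, others on a circle."""
    n = skeleton.n_nodes
    offs = np.zeros((n, 2))
    for k in range(1, n):
        ang = theta + 2.0 * math.pi * (k - 1) / max(n - 1, 1)
        offs[k] = (pose_scale * math.cos(ang), pose_scale * math.sin(ang))
    return offs


def _place_centroids(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_size
    margin = spec.pose_scale + spec.border_margin
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ValueError("image too small for the requested pose scale")
    centroids: list[np.ndarray] = []
    for _ in range(spec.n_instances):
        for _attempt in range(_PLACEMENT_ATTEMPTS):
            c = np.array(
                [
                    rng.uniform(margin, w - 1 - margin),
                    rng.uniform(margin, h - 1 - margin),
                ]
            )
            if all(
                np.linalg.norm(c - prev) >= spec.min_separation for prev in centroids
            ):
                centroids.append(c)
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_instances} instances with separation "
                f"{spec.min_separation} in a {w}x{h} frame"
            )
    return np.array(centroids)


def _build_instance(
    spec: SceneSpec,
    centroid: np.ndarray,
    rng: np.random.Generator,
    idx: int,
) -> Instance:
    theta = rng.uniform(0, 2 * math.pi)
    pts = centroid[None, :] + _pose_offsets(spec.skeleton, spec.pose_scale, theta)
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0, spec.noise_sigma, pts.shape)
    vis = np.ones(spec.skeleton.n_nodes, dtype=bool)
    if spec.occlude_prob > 0:
        # Hub (node 0) stays visible so every instance keeps >= 1 point.
        vis[1:] = rng.random(spec.skeleton.n_nodes - 1) >= spec.occlude_prob
    pts = pts.copy()
    pts[~vis] = np.nan
    return Instance(
        skeleton=spec.skeleton,
        points=pts,
        visible=vis,
        track_id=idx,
        class_id=idx if spec.with_classes else None,
    )


def render_instances(
    instances: list[Instance],
    image_size: tuple[int, int],
    blob_sigma: float = 2.0,
) -> np.ndarray:
    """Draw a Gaussian blob per visible landmark (amplitudes vary by node
    so patches are asymmetric and optical flow is well-conditioned)."""
    h, w = image_size
    img = np.zeros((h, w))
    ext = int(math.ceil(4 * blob_sigma))
    for inst in instances:
        n = inst.skeleton.n_nodes
        for ni in range(n):
            if not inst.visible[ni]:
                continue
            x, y = inst.points[ni]
            amp = 0.5 + 0.5 * (ni + 1) / n
            cx, cy = int(round(x)), int(round(y))
            x0, x1 = max(0, cx - ext), min(w, cx + ext + 1)
            y0, y1 = max(0, cy - ext), min(h, cy + ext + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            xs = np.arange(x0, x1)
            ys = np.arange(y0, y1)
            gx = np.exp(-((xs - x) ** 2) / (2 * blob_sigma**2))
            gy = np.exp(-((ys - y) ** 2) / (2 * blob_sigma**2))
            img[y0:y1, x0:x1] += amp * gy[:, None] * gx[None, :]
    return np.clip(img, 0.0, 1.0)


def generate_scene(
    spec: SceneSpec,
    render: bool = False,
) -> tuple[list[Instance], Optional[np.ndarray]]:
    """One frame of ground-truth instances; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    centroids = _place_centroids(spec, rng)
    instances = [
        _build_instance(spec, c, rng, i) for i, c in enumerate(centroids)
    ]
    img = render_instances(instances, spec.image_size, spec.blob_sigma) if render else None
    return instances, img


def generate_session(
    spec: SessionSpec,
    render: bool = False,
) -> tuple[list[list[Instance]], Optional[list[np.ndarray]]]:
    """A tracked session: constant-velocity trajectories with reflection
    at the borders plus optional Gaussian jitter.  Per-frame displacement
    never exceeds ``max_step``; identities are consistent by construction
    (``track_id`` = instance index in every frame)."""
    scene = spec.scene
    rng = np.random.default_rng(scene.seed)
    centroids = _place_centroids(scene, rng)
    base_instances = [
        _build_instance(scene, c, rng, i) for i, c in enumerate(centroids)
    ]
    h, w = scene.image_size
    margin = scene.pose_scale + scene.border_margin
    lo = np.array([margin, margin])
    hi = np.array([w - 1 - margin, h - 1 - margin])

    n = scene.n_instances
    angles = rng.uniform(0, 2 * math.pi, n)
    speeds = (
        rng.uniform(0.5, 1.0, n) * spec.max_step if spec.max_step > 0 else np.zeros(n)
    )
    vel = np.stack([speeds * np.cos(angles), speeds * np.sin(angles)], axis=1)
    pos = centroids.copy()

    frames: list[list[Instance]] = []
    images: Optional[list[np.ndarray]] = [] if render else None
    offsets = [inst.points - c[None, :] for inst, c in zip(base_instances, centroids)]
    visibles = [inst.visible for inst in base_instances]

    for _fi in range(spec.n_frames):
        insts = []
        for i in range(n):
            pts = pos[i][None, :] + offsets[i]
            insts.append(
                Instance(
                    skeleton=scene.skeleton,
                    points=pts,
                    visible=visibles[i].copy(),
                    track_id=i,
                    class_id=i if scene.with_classes else None,
                )
            )
        frames.append(insts)
        if render:
            images.append(render_instances(insts, scene.image_size, scene.blob_sigma))
        # Advance with a step capped at max_step, reflecting at borders.
        step = vel.copy()
        if spec.jitter_sigma > 0:
            step = step + rng.normal(0, spec.jitter_sigma, step.shape)
            norms = np.linalg.norm(step, axis=1, keepdims=True)
            if spec.max_step > 0:
                factor = np.minimum(1.0, spec.max_step / np.maximum(norms, 1e-12))
                step = step * factor
        pos = pos + step
        for i in range(n):
            for ax in range(2):
                if pos[i, ax] < lo[ax]:
                    pos[i, ax] = 2 * lo[ax] - pos[i, ax]
                    vel[i, ax] = -vel[i, ax]
                elif pos[i, ax] > hi[ax]:
                    pos[i, ax] = 2 * hi[ax] - pos[i, ax]
                    vel[i, ax] = -vel[i, ax]
    return frames, images


def session_to_dataset(
    frames: list[list[Instance]],
    spec: SessionSpec,
    video_id: str = "synth",
) -> LabelsDataset:
    scene = spec.scene
    labeled = [
        LabeledFrame(video_id=video_id, frame_index=i, instances=insts)
        for i, insts in enumerate(frames)
    ]
    tracks = [Track(i, f"animal{i}") for i in range(scene.n_instances)]
    class_names = (
        [f"class{i}" for i in range(scene.n_instances)] if scene.with_classes else None
    )
    return LabelsDataset(
        skeleton=scene.skeleton,
        frames=labeled,
        tracks=tracks,
        class_names=class_names,
        image_size=scene.image_size,
        provenance=f"synthetic session seed={scene.seed}",
    )
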