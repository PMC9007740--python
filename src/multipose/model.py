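"""Core data model for multi-animal pose data and its on-disk container.

Coordinates are (x, y), 0-based, full-image pixels, with pixel centers at
integer coordinates.  Invisible landmarks are stored as NaN with
``visible=False``; NaN never enters downstream computations unmasked.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Skeleton",
    "Instance",
    "LabeledFrame",
    "Track",
    "LabelsDataset",
    "validate_skeleton",
    "save_labels",
    "load_labels",
    "make_splits",
    "to_point_arrays",
    "point_arrays_to_frames",
    "export_points_csv",
]


@dataclass(frozen=True)
class Skeleton:
    """Directed graph of named body parts.

    Edges are ordered ``(source_index, dest_index)`` pairs into ``nodes``.
    A valid skeleton is a directed tree or forest (see
    :func:`validate_skeleton`).
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    name: str = "skeleton"

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Sequence[Sequence[int]] = (),
        name: str = "skeleton",
    ):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple((int(s), int(d)) for s, d in edges))
        object.__setattr__(self, "name", str(name))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, name: str) -> int:
        return self.nodes.index(name)

    def edge_names(self) -> list[tuple[str, str]]:
        return [(self.nodes[s], self.nodes[d]) for s, d in self.edges]

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "nodes": list(self.nodes), "edges": [list(e) for e in self.edges]}
        )

    @classmethod
    def from_json(cls, text: str) -> "Skeleton":
        d = json.loads(text)
        return cls(nodes=d["nodes"], edges=d["edges"], name=d.get("name", "skeleton"))


def validate_skeleton(skeleton: Skeleton) -> list[str]:
    """Check skeleton invariants, returning human-readable violations.

    An empty list means the skeleton is a valid directed tree/forest:
    node indices in range, no self-edges, edges unique, in-degree at most
    one per node, and no directed cycles.
    """
    violations: list[str] = []
    n = skeleton.n_nodes
    seen: set[tuple[int, int]] = set()
    in_deg = np.zeros(n, dtype=int)
    ok_edges = []
    for e in skeleton.edges:
        s, d = e
        if not (0 <= s < n) or not (0 <= d < n):
            violations.append(f"edge {e} has node index out of range [0, {n})")
            continue
        if s == d:
            violations.append(f"edge {e} is a self-edge")
            continue
        if e in seen:
            violations.append(f"edge {e} is duplicated")
            continue
        seen.add(e)
        in_deg[d] += 1
        ok_edges.append(e)
    for node in np.flatnonzero(in_deg > 1):
        violations.append(
            f"node {int(node)} ({skeleton.nodes[int(node)]}) has in-degree {int(in_deg[node])} > 1"
        )
    # Cycle check on remaining well-formed edges (Kahn's algorithm).
    adj: dict[int, list[int]] = {}
    deg = np.zeros(n, dtype=int)
    for s, d in ok_edges:
        adj.setdefault(s, []).append(d)
        deg[d] += 1
    queue = [i for i in range(n) if deg[i] == 0]
    visited = 0
    while queue:
        u = queue.pop()
        visited += 1
        for v in adj.get(u, []):
            deg[v] -= 1
            if deg[v] == 0:
                queue.append(v)
    if visited < n:
        cyclic = sorted(i for i in range(n) if deg[i] > 0)
        violations.append(f"directed cycle involving nodes {cyclic}")
    return violations


@dataclass
class Instance:
    """One animal's landmark set in a single frame."""

    skeleton: Skeleton
    points: np.ndarray  # (n_nodes, 2) float64, (x, y); NaN where invisible
    visible: np.ndarray  # (n_nodes,) bool
    track_id: Optional[int] = None
    class_id: Optional[int] = None
    point_scores: Optional[np.ndarray] = None  # (n_nodes,) in [0, 1]
    instance_score: Optional[float] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(
            self.skeleton.n_nodes, 2
        )
        self.visible = np.asarray(self.visible, dtype=bool).reshape(self.skeleton.n_nodes)
        if self.point_scores is not None:
            self.point_scores = np.asarray(self.point_scores, dtype=np.float64)
        finite = np.isfinite(self.points).all(axis=1)
        if np.any(finite != self.visible):
            raise ValueError("points row must be finite iff visible flag is true")
        if not self.visible.any():
            raise ValueError("instance must have at least one visible point")

    @classmethod
    def from_points(
        cls,
        skeleton: Skeleton,
        points: np.ndarray,
        **kwargs,
    ) -> "Instance":
        """Build an instance inferring visibility from finite rows."""
        pts = np.asarray(points, dtype=np.float64).reshape(skeleton.n_nodes, 2).copy()
        vis = np.isfinite(pts).all(axis=1)
        pts[~vis] = np.nan
        return cls(skeleton=skeleton, points=pts, visible=vis, **kwargs)

    def bbox(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) over visible points."""
        pts = self.points[self.visible]
        return (
            float(pts[:, 0].min()),
            float(pts[:, 1].min()),
            float(pts[:, 0].max()),
            float(pts[:, 1].max()),
        )

    def centroid(self) -> np.ndarray:
        x0, y0, x1, y1 = self.bbox()
        return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])

    def translated(self, dxy) -> "Instance":
        pts = self.points.copy()
        pts[self.visible] += np.asarray(dxy, dtype=np.float64)
        return dataclasses.replace(self, points=pts)

    def equals(self, other: "Instance") -> bool:
        if self.skeleton.nodes != other.skeleton.nodes:
            return False
        if not np.array_equal(self.visible, other.visible):
            return False
        if not np.array_equal(
            self.points[self.visible], other.points[other.visible]
        ):
            return False
        for a, b in ((self.track_id, other.track_id), (self.class_id, other.class_id)):
            if a != b:
                return False
        return True


@dataclass
class LabeledFrame:
    video_id: str
    frame_index: int
    instances: list[Instance] = field(default_factory=list)


@dataclass(frozen=True)
class Track:
    track_id: int
    name: str = ""


@dataclass
class LabelsDataset:
    """A self-contained multi-animal pose dataset."""

    skeleton: Skeleton
    frames: list[LabeledFrame] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)
    class_names: Optional[list[str]] = None
    image_size: tuple[int, int] = (0, 0)  # (H, W)
    provenance: str = ""

    def __post_init__(self) -> None:
        h, w = self.image_size
        if self.frames and (h <= 0 or w <= 0):
            raise ValueError("image_size must be positive (H, W)")
        track_ids = {t.track_id for t in self.tracks}
        if len(track_ids) != len(self.tracks):
            raise ValueError("track ids must be unique")
        for lf in self.frames:
            for inst in lf.instances:
                if inst.track_id is not None and inst.track_id not in track_ids:
                    raise ValueError(
                        f"frame {lf.frame_index}: track_id {inst.track_id} unresolved"
                    )
                if inst.class_id is not None:
                    if self.class_names is None or not (
                        0 <= inst.class_id < len(self.class_names)
                    ):
                        raise ValueError(
                            f"frame {lf.frame_index}: class_id {inst.class_id} unresolved"
                        )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def all_instances(self) -> list[Instance]:
        return [inst for lf in self.frames for inst in lf.instances]


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1
_STR = h5py.string_dtype(encoding="utf-8")


def save_labels(dataset: LabelsDataset, path) -> None:
    """Write a dataset to a single portable HDF5 container."""
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["format_version"] = _FORMAT_VERSION
        meta.attrs["image_height"] = int(dataset.image_size[0])
        meta.attrs["image_width"] = int(dataset.image_size[1])
        meta.attrs["provenance"] = dataset.provenance

        skel = f.create_group("skeleton")
        skel.attrs["json"] = dataset.skeleton.to_json()

        tracks = f.create_group("tracks")
        tracks.create_dataset(
            "track_id", data=np.array([t.track_id for t in dataset.tracks], dtype=np.int64)
        )
        tracks.create_dataset(
            "name", data=np.array([t.name for t in dataset.tracks], dtype=object), dtype=_STR
        )

        if dataset.class_names is not None:
            f.create_dataset(
                "class_names",
                data=np.array(dataset.class_names, dtype=object),
                dtype=_STR,
            )

        frames = f.create_group("frames")
        n_frames = len(dataset.frames)
        frames.create_dataset(
            "video_id",
            data=np.array([lf.video_id for lf in dataset.frames], dtype=object),
            dtype=_STR,
        )
        frames.create_dataset(
            "frame_index",
            data=np.array([lf.frame_index for lf in dataset.frames], dtype=np.int64),
        )
        counts = np.array([len(lf.instances) for lf in dataset.frames], dtype=np.int64)
        frames.create_dataset("n_instances", data=counts)

        insts = dataset.all_instances()
        n_nodes = dataset.skeleton.n_nodes
        n_inst = len(insts)
        points = np.full((n_inst, n_nodes, 2), np.nan)
        visible = np.zeros((n_inst, n_nodes), dtype=bool)
        track_id = np.full(n_inst, -1, dtype=np.int64)
        class_id = np.full(n_inst, -1, dtype=np.int64)
        point_scores = np.full((n_inst, n_nodes), np.nan)
        instance_score = np.full(n_inst, np.nan)
        for i, inst in enumerate(insts):
            points[i] = inst.points
            visible[i] = inst.visible
            if inst.track_id is not None:
                track_id[i] = inst.track_id
            if inst.class_id is not None:
                class_id[i] = inst.class_id
            if inst.point_scores is not None:
                point_scores[i] = inst.point_scores
            if inst.instance_score is not None:
                instance_score[i] = inst.instance_score
        g = f.create_group("instances")
        g.create_dataset("points", data=points)
        g.create_dataset("visible", data=visible)
        g.create_dataset("track_id", data=track_id)
        g.create_dataset("class_id", data=class_id)
        g.create_dataset("point_scores", data=point_scores)
        g.create_dataset("instance_score", data=instance_score)
        g.attrs["n_frames"] = n_frames


def load_labels(path) -> LabelsDataset:
    """Load a dataset written by :func:`save_labels`.

    Raises
    ------
    FileNotFoundError
        If the path does not exist.
    KeyError
        Naming the missing group if the container is malformed.
    """
    with h5py.File(path, "r") as f:
        for group in ("meta", "skeleton", "frames", "instances"):
            if group not in f:
                raise KeyError(f"container is missing required group '/{group}'")
        meta = f["meta"]
        skeleton = Skeleton.from_json(f["skeleton"].attrs["json"])
        tracks = []
        if "tracks" in f:
            tids = f["tracks/track_id"][()]
            tnames = [s.decode() if isinstance(s, bytes) else s for s in f["tracks/name"][()]]
            tracks = [Track(int(t), n) for t, n in zip(tids, tnames)]
        class_names = None
        if "class_names" in f:
            class_names = [
                s.decode() if isinstance(s, bytes) else s for s in f["class_names"][()]
            ]
        video_ids = [
            s.decode() if isinstance(s, bytes) else s for s in f["frames/video_id"][()]
        ]
        frame_indices = f["frames/frame_index"][()]
        counts = f["frames/n_instances"][()]
        g = f["instances"]
        points = g["points"][()]
        visible = g["visible"][()]
        track_id = g["track_id"][()]
        class_id = g["class_id"][()]
        point_scores = g["point_scores"][()]
        instance_score = g["instance_score"][()]

        frames: list[LabeledFrame] = []
        cursor = 0
        for vid, fidx, cnt in zip(video_ids, frame_indices, counts):
            insts = []
            for i in range(cursor, cursor + int(cnt)):
                ps = point_scores[i]
                insts.append(
                    Instance(
                        skeleton=skeleton,
                        points=points[i],
                        visible=visible[i],
                        track_id=int(track_id[i]) if track_id[i] >= 0 else None,
                        class_id=int(class_id[i]) if class_id[i] >= 0 else None,
                        point_scores=ps if np.isfinite(ps).any() else None,
                        instance_score=(
                            float(instance_score[i])
                            if np.isfinite(instance_score[i])
                            else None
                        ),
                    )
                )
            cursor += int(cnt)
            frames.append(LabeledFrame(video_id=vid, frame_index=int(fidx), instances=insts))
        return LabelsDataset(
            skeleton=skeleton,
            frames=frames,
            tracks=tracks,
            class_names=class_names,
            image_size=(int(meta.attrs["image_height"]), int(meta.attrs["image_width"])),
            provenance=str(meta.attrs["provenance"]),
        )


# ---------------------------------------------------------------------------
# Splits and array export
# ---------------------------------------------------------------------------


def make_splits(
    dataset: LabelsDataset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partition frame indices into disjoint train/val/test sets.

    Ratios must be strictly positive and sum to 1 (tolerance 1e-9).
    Deterministic for a given seed.
    """
    if len(ratios) != 3:
        raise ValueError("ratios must be a (train, val, test) triple")
    if any(r <= 0 for r in ratios):
        raise ValueError("all split ratios must be strictly positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {sum(ratios)}")
    n = dataset.n_frames
    if n < 3:
        raise ValueError(f"need at least 3 frames to split, have {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    # Largest-remainder apportionment so sizes are within rounding of ratios.
    raw = np.array(ratios) * n
    sizes = np.floor(raw).astype(int)
    frac_order = np.argsort(-(raw - sizes))
    for k in range(n - sizes.sum()):
        sizes[frac_order[k]] += 1
    a, b = sizes[0], sizes[0] + sizes[1]
    return (
        np.sort(order[:a]),
        np.sort(order[a:b]),
        np.sort(order[b:]),
    )


def to_point_arrays(dataset: LabelsDataset) -> tuple[np.ndarray, np.ndarray]:
    """Export tracked instances as a dense (frames, tracks, nodes, 2) array.

    Returns the array (NaN where a track is absent or a node invisible) and
    a boolean occupancy mask that is true exactly where a point is visible.
    Every instance must carry a ``track_id``.
    """
    missing = [
        lf.frame_index
        for lf in dataset.frames
        if any(inst.track_id is None for inst in lf.instances)
    ]
    if missing:
        raise ValueError(f"instances without track_id in frames {missing}")
    track_ids = [t.track_id for t in dataset.tracks]
    tid_to_col = {t: i for i, t in enumerate(track_ids)}
    n_nodes = dataset.skeleton.n_nodes
    arr = np.full((dataset.n_frames, len(track_ids), n_nodes, 2), np.nan)
    mask = np.zeros((dataset.n_frames, len(track_ids), n_nodes), dtype=bool)
    for fi, lf in enumerate(dataset.frames):
        for inst in lf.instances:
            col = tid_to_col[inst.track_id]
            arr[fi, col] = inst.points
            mask[fi, col] = inst.visible
    return arr, mask


def point_arrays_to_frames(
    arr: np.ndarray,
    dataset: LabelsDataset,
) -> list[LabeledFrame]:
    """Inverse of :func:`to_point_arrays`, for round-trip testing."""
    frames = []
    for fi, lf in enumerate(dataset.frames):
        insts = []
        for ti, track in enumerate(dataset.tracks):
            pts = arr[fi, ti]
            if np.isfinite(pts).any():
                insts.append(
                    Instance.from_points(dataset.skeleton, pts, track_id=track.track_id)
                )
        frames.append(LabeledFrame(lf.video_id, lf.frame_index, insts))
    return frames


def export_points_csv(dataset: LabelsDataset, path) -> pd.DataFrame:
    """Write tracked points as a long-format CSV (video, frame, track, node, x, y, score)."""
    rows = []
    for lf in dataset.frames:
        for inst in lf.instances:
            for ni, node in enumerate(dataset.skeleton.nodes):
                if not inst.visible[ni]:
                    continue
                score = (
                    float(inst.point_scores[ni]) if inst.point_scores is not None else math.nan
                )
                rows.append(
                    {
                        "video": lf.video_id,
                        "frame": lf.frame_index,
                        "track": inst.track_id if inst.track_id is not None else -1,
                        "node": node,
                        "x": inst.points[ni, 0],
                        "y": inst.points[ni, 1],
                        "score": score,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["video", "frame", "track", "node", "x", "y", "score"]
    )
    df.to_csv(path, index=False)
    return df
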