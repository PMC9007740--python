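"""Gridded training-target generation: confidence maps, part affinity
fields, class maps, and anchor-centered crops.

Grid pixel (row, col) corresponds to image coordinate
``(x, y) = (col * output_stride, row * output_stride)`` — no half-pixel
offset, so a stride-1 grid is identical to image coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Instance, LabelsDataset, Skeleton

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "ConfidenceMaps",
    "PAFs",
    "ClassMaps",
    "CropSet",
    "encode_confidence_maps",
    "encode_pafs",
    "encode_class_maps",
    "compute_crop_size",
    "make_anchor_crops",
    "select_anchor",
    "crop_topleft",
]

_VALID_STRIDES = (1, 2, 4, 8)


@dataclass(frozen=True)
class GridSpec:
    """Sampling grid relating image pixels to output-stride tensors."""

    height: int
    width: int
    output_stride: int = 1
    sigma_base: float = 1.0

    def __post_init__(self):
        if self.output_stride not in _VALID_STRIDES:
            raise ValueError(f"output_stride must be one of {_VALID_STRIDES}")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("grid image size must be positive")
        if self.sigma_base <= 0:
            raise ValueError("sigma_base must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        s = self.output_stride
        return (math.ceil(self.height / s), math.ceil(self.width / s))

    @property
    def sigma(self) -> float:
        """Effective Gaussian spread in image pixels (scaled by stride)."""
        return self.sigma_base * self.output_stride

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Image-coordinate meshes (X, Y) of the grid, each of shape ``self.shape``."""
        gh, gw = self.shape
        s = self.output_stride
        x = np.arange(gw, dtype=np.float64) * s
        y = np.arange(gh, dtype=np.float64) * s
        return np.meshgrid(x, y)

    def image_to_grid(self, xy: np.ndarray) -> np.ndarray:
        """Nearest grid (col, row) indices for image-space (x, y), clipped in-bounds."""
        gh, gw = self.shape
        idx = np.rint(np.asarray(xy, dtype=np.float64) / self.output_stride).astype(int)
        idx[..., 0] = np.clip(idx[..., 0], 0, gw - 1)
        idx[..., 1] = np.clip(idx[..., 1], 0, gh - 1)
        return idx


@dataclass
class ConfidenceMaps:
    tensor: np.ndarray  # (grid_h, grid_w, n_nodes)
    grid: GridSpec
    node_names: tuple[str, ...] = ()


@dataclass
class PAFs:
    tensor: np.ndarray  # (grid_h, grid_w, 2 * n_edges), x/y interleaved per edge
    grid: GridSpec
    edge_list: tuple[tuple[int, int], ...] = ()


@dataclass
class ClassMaps:
    tensor: np.ndarray  # (grid_h, grid_w, n_classes) in {0, 1}
    grid: GridSpec
    radius: float = 5.0


@dataclass
class CropSet:
    crops: list[np.ndarray] = field(default_factory=list)
    anchors: list[tuple[float, float]] = field(default_factory=list)
    source_indices: list[int] = field(default_factory=list)
    crop_size: int = 0


def encode_confidence_maps(
    instances: Sequence[Instance],
    grid: GridSpec,
) -> ConfidenceMaps:
    """Render per-node confidence maps, max-combined across instances.

    The value at grid pixel p for node i is
    ``max_instances exp(-||x_i - x_p||^2 / (2 sigma^2)) * delta_i`` with
    sigma the stride-scaled spread.  Invisible nodes contribute zeros.
    """
    node_names = instances[0].skeleton.nodes if instances else ()
    n_nodes = len(node_names)
    gh, gw = grid.shape
    X, Y = grid.mesh()
    tensor = np.zeros((gh, gw, n_nodes))
    two_sig2 = 2.0 * grid.sigma**2
    for inst in instances:
        for i in range(n_nodes):
            if not inst.visible[i]:
                continue
            x, y = inst.points[i]
            cm = np.exp(-((X - x) ** 2 + (Y - y) ** 2) / two_sig2)
            np.maximum(tensor[:, :, i], cm, out=tensor[:, :, i])
    return ConfidenceMaps(tensor=tensor, grid=grid, node_names=tuple(node_names))


def encode_pafs(
    instances: Sequence[Instance],
    skeleton: Skeleton,
    grid: GridSpec,
    paf_sigma: float = 5.0,
) -> PAFs:
    """Render part affinity fields, summed across instances.

    Per edge and instance the field is the edge unit vector weighted by a
    Gaussian of the point-to-segment distance (clamped projection), gated
    by both endpoint visibilities.  ``paf_sigma`` is in image pixels.
    """
    gh, gw = grid.shape
    X, Y = grid.mesh()
    tensor = np.zeros((gh, gw, 2 * skeleton.n_edges))
    two_sig2 = 2.0 * paf_sigma**2
    for inst in instances:
        for ei, (s, d) in enumerate(skeleton.edges):
            if not (inst.visible[s] and inst.visible[d]):
                continue
            xs, ys = inst.points[s]
            xd, yd = inst.points[d]
            dx, dy = xd - xs, yd - ys
            seg_len2 = dx * dx + dy * dy
            if seg_len2 == 0.0:
                logger.warning(
                    "zero-length edge %d (%s->%s); field left zero",
                    ei,
                    skeleton.nodes[s],
                    skeleton.nodes[d],
                )
                continue
            r = np.clip(((X - xs) * dx + (Y - ys) * dy) / seg_len2, 0.0, 1.0)
            px = xs + r * dx
            py = ys + r * dy
            m2 = (X - px) ** 2 + (Y - py) ** 2
            w = np.exp(-m2 / two_sig2)
            seg_len = math.sqrt(seg_len2)
            tensor[:, :, 2 * ei] += w * (dx / seg_len)
            tensor[:, :, 2 * ei + 1] += w * (dy / seg_len)
    return PAFs(tensor=tensor, grid=grid, edge_list=skeleton.edges)


def encode_class_maps(
    instances: Sequence[Instance],
    n_classes: int,
    radius: float,
    grid: GridSpec,
) -> ClassMaps:
    """Binary per-class masks: disks of ``radius`` (image px) around each
    visible node, collapsed per animal class.  Pixels claimed by more than
    one distinct class are zeroed in all channels (ambiguous region)."""
    gh, gw = grid.shape
    X, Y = grid.mesh()
    masks = np.zeros((gh, gw, n_classes), dtype=bool)
    r2 = radius**2
    for inst in instances:
        if inst.class_id is None:
            raise ValueError("instance lacks class_id, required for class maps")
        if not (0 <= inst.class_id < n_classes):
            raise ValueError(f"class_id {inst.class_id} out of range [0, {n_classes})")
        for i in range(inst.skeleton.n_nodes):
            if not inst.visible[i]:
                continue
            x, y = inst.points[i]
            masks[:, :, inst.class_id] |= (X - x) ** 2 + (Y - y) ** 2 <= r2
    ambiguous = masks.sum(axis=2) > 1
    tensor = masks.astype(np.float64)
    tensor[ambiguous] = 0.0
    return ClassMaps(tensor=tensor, grid=grid, radius=radius)


def compute_crop_size(
    dataset: LabelsDataset | Sequence[Instance],
    margin_px: float = 16.0,
    multiple: int = 32,
) -> int:
    """Smallest even multiple of ``multiple`` covering the largest instance
    bounding-box side plus margins on both sides."""
    instances = (
        dataset.all_instances() if isinstance(dataset, LabelsDataset) else list(dataset)
    )
    if not instances:
        raise ValueError("cannot compute crop size from an empty dataset")
    max_side = 0.0
    for inst in instances:
        x0, y0, x1, y1 = inst.bbox()
        max_side = max(max_side, x1 - x0, y1 - y0)
    target = max_side + 2.0 * margin_px
    k = max(1, math.ceil(target / multiple))
    while (k * multiple) % 2 != 0:
        k += 1
    return k * multiple


def crop_topleft(anchor: tuple[float, float], crop_size: int) -> tuple[int, int]:
    """Integer (x0, y0) of the crop window for a full-frame anchor."""
    cx = int(round(float(anchor[0])))
    cy = int(round(float(anchor[1])))
    half = crop_size // 2
    return cx - half, cy - half


def make_anchor_crops(
    image: np.ndarray,
    anchors: Sequence[tuple[float, float]],
    crop_size: int,
) -> CropSet:
    """Cut fixed-size square patches centered on each anchor.

    Out-of-frame regions are zero-padded; the full-precision anchor is
    recorded so decoded coordinates can be restored to the full frame.
    """
    if crop_size % 2 != 0:
        raise ValueError("crop_size must be even")
    h, w = image.shape[:2]
    out = CropSet(crop_size=crop_size)
    for idx, anchor in enumerate(anchors):
        x0, y0 = crop_topleft(anchor, crop_size)
        crop = np.zeros((crop_size, crop_size) + image.shape[2:], dtype=image.dtype)
        src_x0, src_x1 = max(0, x0), min(w, x0 + crop_size)
        src_y0, src_y1 = max(0, y0), min(h, y0 + crop_size)
        if src_x0 < src_x1 and src_y0 < src_y1:
            crop[src_y0 - y0 : src_y1 - y0, src_x0 - x0 : src_x1 - x0] = image[
                src_y0:src_y1, src_x0:src_x1
            ]
        out.crops.append(crop)
        out.anchors.append((float(anchor[0]), float(anchor[1])))
        out.source_indices.append(idx)
    return out


def select_anchor(
    instance: Instance,
    anchor_node: Optional[int] = None,
) -> tuple[float, float]:
    """Anchor point for centered cropping: the anchor node if visible,
    else the centroid of the bounding box of the visible parts."""
    if not instance.visible.any():
        raise ValueError("instance has no visible nodes")
    if anchor_node is not None and instance.visible[anchor_node]:
        x, y = instance.points[anchor_node]
        return float(x), float(y)
    cx, cy = instance.centroid()
    return float(cx), float(cy)
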