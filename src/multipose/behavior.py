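"""Pose-derived social-interaction features and the approach-trigger
predicate.

Angle convention: image coordinates are y-down; signed angles are
measured counterclockwise-positive in the mathematical sense on the raw
(x, y) values and wrapped to (-180, 180] degrees.  An animal's heading
is its thorax-to-head vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import Instance

__all__ = [
    "BodyNodes",
    "PosePairFeatures",
    "TriggerConfig",
    "pose_pair_features",
    "approach_trigger",
]


@dataclass(frozen=True)
class BodyNodes:
    """Node indices of the landmarks the features are built from."""

    head: int
    thorax: int
    abdomen_tip: int


@dataclass(frozen=True)
class PosePairFeatures:
    min_dist: Optional[float]  # mm, male head to female abdomen tip
    ang_f_rel_m: Optional[float]  # deg, female thorax relative to male heading
    ang_m_rel_f: Optional[float]  # deg, male thorax relative to female heading

    @property
    def available(self) -> bool:
        return None not in (self.min_dist, self.ang_f_rel_m, self.ang_m_rel_f)


@dataclass(frozen=True)
class TriggerConfig:
    dist_max_mm: float = 2.0
    ang_f_max_deg: float = 25.0
    ang_m_min_deg: float = 145.0
    eval_period_ms: float = 25.0
    px_per_mm: float = 1.0

    def __post_init__(self):
        for name in ("dist_max_mm", "ang_f_max_deg", "ang_m_min_deg", "eval_period_ms", "px_per_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _signed_angle_deg(v_from: np.ndarray, v_to: np.ndarray) -> Optional[float]:
    """Signed angle from v_from to v_to, wrapped to (-180, 180]."""
    if np.linalg.norm(v_from) == 0 or np.linalg.norm(v_to) == 0:
        return None
    ang = math.degrees(
        math.atan2(
            v_from[0] * v_to[1] - v_from[1] * v_to[0],
            v_from[0] * v_to[0] + v_from[1] * v_to[1],
        )
    )
    if ang <= -180.0:
        ang += 360.0
    return ang


def pose_pair_features(
    female: Instance,
    male: Instance,
    px_per_mm: float,
    nodes: BodyNodes,
) -> PosePairFeatures:
    """Social-approach features for a (female, male) pose pair.

    ``min_dist`` is the male-head to female-abdomen-tip distance in mm;
    the angular location of animal B relative to animal A is the signed
    angle between A's heading (thorax to head) and the A-thorax to
    B-thorax vector.  Features whose required landmarks are invisible or
    degenerate (coincident thoraxes, zero-length heading) are None.
    """
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")

    def pt(inst: Instance, node: int) -> Optional[np.ndarray]:
        return inst.points[node] if inst.visible[node] else None

    m_head, m_thor = pt(male, nodes.head), pt(male, nodes.thorax)
    f_head, f_thor = pt(female, nodes.head), pt(female, nodes.thorax)
    f_abd = pt(female, nodes.abdomen_tip)

    min_dist = None
    if m_head is not None and f_abd is not None:
        min_dist = float(np.linalg.norm(m_head - f_abd)) / px_per_mm

    ang_f_rel_m = None
    if m_head is not None and m_thor is not None and f_thor is not None:
        ang_f_rel_m = _signed_angle_deg(m_head - m_thor, f_thor - m_thor)

    ang_m_rel_f = None
    if f_head is not None and f_thor is not None and m_thor is not None:
        ang_m_rel_f = _signed_angle_deg(f_head - f_thor, m_thor - f_thor)

    return PosePairFeatures(min_dist, ang_f_rel_m, ang_m_rel_f)


def approach_trigger(features: PosePairFeatures, cfg: TriggerConfig) -> bool:
    """Approach predicate with strict inequalities:
    ``min_dist < dist_max`` and ``|ang_f_rel_m| < ang_f_max`` and
    ``|ang_m_rel_f| > ang_m_min``.  Unavailable features give False."""
    if not features.available:
        return False
    return (
        features.min_dist < cfg.dist_max_mm
        and abs(features.ang_f_rel_m) < cfg.ang_f_max_deg
        and abs(features.ang_m_rel_f) > cfg.ang_m_min_deg
    )
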