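"""Grouping peaks into per-animal instances.

Bottom-up: line-integral scoring of candidate connections on part
affinity fields, per-edge Hungarian matching, and greedy edge-wise
assembly over a validated tree/forest skeleton.  Top-down: centered-crop
decoding.  Appearance: one-to-one identity assignment from class maps or
a classification-probability matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .encode import ConfidenceMaps, PAFs, ClassMaps, crop_topleft
from .model import Instance, Skeleton, validate_skeleton
from .peaks import Peak, find_global_peaks, refine_peaks, DEFAULT_PEAK_THRESHOLD

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectionCandidate",
    "AssembledInstance",
    "score_connection",
    "make_connection_candidates",
    "match_edge",
    "assemble_instances",
    "bottomup_decode",
    "topdown_decode",
    "assign_ids_class_maps",
    "assign_ids_probabilities",
]

DEFAULT_MIN_CONNECTION_SCORE = 0.05
DEFAULT_N_LINE_SAMPLES = 10


@dataclass(frozen=True)
class ConnectionCandidate:
    edge_index: int
    source: Peak
    dest: Peak
    score: float


@dataclass
class AssembledInstance:
    instance: Instance
    peaks: dict[int, Peak] = field(default_factory=dict)  # node index -> Peak
    score: float = 0.0


def score_connection(
    pafs: PAFs,
    edge_index: int,
    src_xy: tuple[float, float],
    dst_xy: tuple[float, float],
    n_samples: int = DEFAULT_N_LINE_SAMPLES,
) -> float:
    """Line-integral connection score.

    The mean, over ``n_samples`` evenly spaced points from source to
    destination (endpoints inclusive), of the dot product between the
    candidate's unit direction vector and the PAF sampled at the nearest
    grid pixel.  A zero-length candidate scores 0.
    """
    src = np.asarray(src_xy, dtype=np.float64)
    dst = np.asarray(dst_xy, dtype=np.float64)
    delta = dst - src
    norm = float(np.linalg.norm(delta))
    if norm == 0.0:
        return 0.0
    unit = delta / norm
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = src[None, :] + ts[:, None] * delta[None, :]
    idx = pafs.grid.image_to_grid(pts)  # (n, 2) as (col, row)
    px = pafs.tensor[idx[:, 1], idx[:, 0], 2 * edge_index]
    py = pafs.tensor[idx[:, 1], idx[:, 0], 2 * edge_index + 1]
    return float(np.mean(px * unit[0] + py * unit[1]))


def make_connection_candidates(
    pafs: PAFs,
    skeleton: Skeleton,
    peaks: Sequence[Peak],
    n_samples: int = DEFAULT_N_LINE_SAMPLES,
) -> list[list[ConnectionCandidate]]:
    """Score every source x dest peak pair for each skeleton edge."""
    by_channel: dict[int, list[Peak]] = {}
    for pk in peaks:
        by_channel.setdefault(pk.channel, []).append(pk)
    out: list[list[ConnectionCandidate]] = []
    for ei, (s, d) in enumerate(skeleton.edges):
        cands = []
        for ps in by_channel.get(s, []):
            for pd in by_channel.get(d, []):
                score = score_connection(pafs, ei, ps.image_xy, pd.image_xy, n_samples)
                cands.append(ConnectionCandidate(ei, ps, pd, score))
        out.append(cands)
    return out


def match_edge(
    candidates: Sequence[ConnectionCandidate],
    min_connection_score: float = DEFAULT_MIN_CONNECTION_SCORE,
) -> list[ConnectionCandidate]:
    """One-to-one source/dest assignment maximizing total score for a single
    edge (Hungarian), dropping pairs below ``min_connection_score``."""
    if not candidates:
        return []
    edge = candidates[0].edge_index
    if any(c.edge_index != edge for c in candidates):
        raise ValueError("candidates must all belong to one edge")
    sources = list({id(c.source): c.source for c in candidates}.values())
    dests = list({id(c.dest): c.dest for c in candidates}.values())
    src_idx = {id(p): i for i, p in enumerate(sources)}
    dst_idx = {id(p): i for i, p in enumerate(dests)}
    scores = np.full((len(sources), len(dests)), -np.inf)
    lookup: dict[tuple[int, int], ConnectionCandidate] = {}
    for c in candidates:
        i, j = src_idx[id(c.source)], dst_idx[id(c.dest)]
        scores[i, j] = c.score
        lookup[(i, j)] = c
    # Guard against -inf rows/cols breaking the solver.
    finite = np.where(np.isfinite(scores), scores, -1e9)
    rows, cols = linear_sum_assignment(finite, maximize=True)
    accepted = []
    for i, j in zip(rows, cols):
        c = lookup.get((i, j))
        if c is not None and c.score >= min_connection_score:
            accepted.append(c)
    return accepted


def _edge_topological_order(skeleton: Skeleton) -> list[int]:
    """Edge indices ordered by source-node depth from the forest roots."""
    depth = {i: 0 for i in range(skeleton.n_nodes)}
    parents = {d: s for s, d in skeleton.edges}
    for node in range(skeleton.n_nodes):
        d, cur = 0, node
        while cur in parents:
            cur = parents[cur]
            d += 1
        depth[node] = d
    return sorted(range(skeleton.n_edges), key=lambda ei: (depth[skeleton.edges[ei][0]], ei))


def assemble_instances(
    peaks: Sequence[Peak],
    connections: Sequence[ConnectionCandidate],
    skeleton: Skeleton,
    max_instances: Optional[int] = None,
    allow_singletons: bool = False,
) -> list[AssembledInstance]:
    """Grow instances greedily edge by edge in skeleton topological order.

    Each accepted connection extends the partial instance containing its
    source peak, merges two disjoint partial instances, or seeds a new
    one.  When both sides conflict (a node slot already filled by a
    different peak), the higher-scoring connection — processed first —
    wins and the later one is discarded.  No peak is ever assigned twice.
    """
    violations = validate_skeleton(skeleton)
    if violations:
        raise ValueError(f"invalid skeleton: {violations}")

    by_edge: dict[int, list[ConnectionCandidate]] = {}
    for c in connections:
        by_edge.setdefault(c.edge_index, []).append(c)

    assemblies: list[dict[int, Peak]] = []
    scores: list[float] = []
    peak_home: dict[int, int] = {}  # id(peak) -> assembly index

    for ei in _edge_topological_order(skeleton):
        s_node, d_node = skeleton.edges[ei]
        for conn in sorted(by_edge.get(ei, []), key=lambda c: -c.score):
            a = peak_home.get(id(conn.source))
            b = peak_home.get(id(conn.dest))
            if a is None and b is None:
                assemblies.append({s_node: conn.source, d_node: conn.dest})
                scores.append(conn.score)
                peak_home[id(conn.source)] = len(assemblies) - 1
                peak_home[id(conn.dest)] = len(assemblies) - 1
            elif a is not None and b is None:
                if d_node in assemblies[a]:
                    continue  # slot taken by a higher-scoring connection
                assemblies[a][d_node] = conn.dest
                scores[a] += conn.score
                peak_home[id(conn.dest)] = a
            elif a is None and b is not None:
                if s_node in assemblies[b]:
                    continue
                assemblies[b][s_node] = conn.source
                scores[b] += conn.score
                peak_home[id(conn.source)] = b
            elif a != b:
                if assemblies[a].keys() & assemblies[b].keys():
                    continue  # merge conflict: earlier (higher) score wins
                assemblies[a].update(assemblies[b])
                for pk in assemblies[b].values():
                    peak_home[id(pk)] = a
                scores[a] += scores[b] + conn.score
                assemblies[b] = {}
                scores[b] = 0.0
            # a == b: connection closes a cycle within one instance; skip.

    results: list[AssembledInstance] = []
    for nodes, score in zip(assemblies, scores):
        if nodes:
            results.append(_finalize_assembly(nodes, score, skeleton))
    if allow_singletons:
        for pk in peaks:
            if id(pk) not in peak_home:
                results.append(
                    _finalize_assembly({pk.channel: pk}, 0.0, skeleton)
                )
    results.sort(key=lambda a: -a.score)
    if max_instances is not None:
        results = results[:max_instances]
    return results


def _finalize_assembly(
    nodes: dict[int, Peak], score: float, skeleton: Skeleton
) -> AssembledInstance:
    n = skeleton.n_nodes
    pts = np.full((n, 2), np.nan)
    vis = np.zeros(n, dtype=bool)
    pscores = np.full(n, np.nan)
    for ni, pk in nodes.items():
        pts[ni] = pk.image_xy
        vis[ni] = True
        pscores[ni] = pk.value
    inst = Instance(
        skeleton=skeleton,
        points=pts,
        visible=vis,
        point_scores=pscores,
        instance_score=float(score),
    )
    return AssembledInstance(instance=inst, peaks=dict(nodes), score=float(score))


def bottomup_decode(
    cms: ConfidenceMaps,
    pafs: PAFs,
    skeleton: Skeleton,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
    min_connection_score: float = DEFAULT_MIN_CONNECTION_SCORE,
    n_samples: int = DEFAULT_N_LINE_SAMPLES,
    max_instances: Optional[int] = None,
    allow_singletons: bool = False,
) -> list[AssembledInstance]:
    """Full bottom-up pipeline: local peaks -> refinement -> PAF scoring ->
    per-edge Hungarian matching -> greedy assembly."""
    from .peaks import find_local_peaks

    pks = refine_peaks(cms, find_local_peaks(cms, peak_threshold))
    per_edge = make_connection_candidates(pafs, skeleton, pks, n_samples)
    accepted: list[ConnectionCandidate] = []
    for cands in per_edge:
        accepted.extend(match_edge(cands, min_connection_score))
    return assemble_instances(
        pks, accepted, skeleton, max_instances=max_instances, allow_singletons=allow_singletons
    )


def topdown_decode(
    crop_cms: Sequence[ConfidenceMaps],
    anchors: Sequence[tuple[float, float]],
    crop_size: int,
    skeleton: Skeleton,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> list[Instance]:
    """Decode centered-crop confidence maps into full-frame instances.

    Per crop: global peak per channel, integral refinement, then
    translation back to the full frame by the crop's integer top-left
    corner.  Crops with no channel above threshold are dropped (logged).
    """
    if len(crop_cms) != len(anchors):
        raise ValueError("need exactly one confidence map stack per anchor")
    out: list[Instance] = []
    for cms, anchor in zip(crop_cms, anchors):
        gp = find_global_peaks(cms, peak_threshold)
        present = [p for p in gp if p is not None]
        if not present:
            logger.info("crop at anchor %s: all channels below threshold; dropped", anchor)
            continue
        refined = refine_peaks(cms, present)
        x0, y0 = crop_topleft(anchor, crop_size)
        n = skeleton.n_nodes
        pts = np.full((n, 2), np.nan)
        vis = np.zeros(n, dtype=bool)
        pscores = np.full(n, np.nan)
        for pk in refined:
            pts[pk.channel] = (pk.image_xy[0] + x0, pk.image_xy[1] + y0)
            vis[pk.channel] = True
            pscores[pk.channel] = pk.value
        out.append(
            Instance(
                skeleton=skeleton,
                points=pts,
                visible=vis,
                point_scores=pscores,
                instance_score=float(np.nanmean(pscores)),
            )
        )
    return out


def assign_ids_class_maps(
    instances: Sequence[Instance],
    class_maps: ClassMaps,
) -> list[Instance]:
    """Assign class identities by sampling class maps at instance peaks.

    The instance-to-class score is the mean class-map value at the
    instance's visible points (nearest grid pixel); a one-to-one
    assignment maximizing total score is computed.  Instances whose best
    assigned score is not positive (for example, entirely inside the
    zeroed ambiguous region) are left unassigned; with more instances
    than classes, the lowest-scoring surplus is unassigned (logged).
    """
    n_classes = class_maps.tensor.shape[2]
    if not instances:
        return []
    scores = np.zeros((len(instances), n_classes))
    for ii, inst in enumerate(instances):
        pts = inst.points[inst.visible]
        idx = class_maps.grid.image_to_grid(pts)
        scores[ii] = class_maps.tensor[idx[:, 1], idx[:, 0], :].mean(axis=0)
    rows, cols = linear_sum_assignment(scores, maximize=True)
    assigned = {}
    for i, j in zip(rows, cols):
        if scores[i, j] > 0:
            assigned[i] = int(j)
    if len(assigned) < len(instances):
        logger.info(
            "%d instance(s) left without class assignment", len(instances) - len(assigned)
        )
    out = []
    for ii, inst in enumerate(instances):
        import dataclasses as _dc

        out.append(_dc.replace(inst, class_id=assigned.get(ii)))
    return out


def assign_ids_probabilities(prob_matrix: np.ndarray) -> list[Optional[int]]:
    """Mutually exclusive identity assignment from an (instances x classes)
    probability matrix, maximizing total probability.  Returns the class
    index per instance (None for surplus instances)."""
    prob = np.asarray(prob_matrix, dtype=np.float64)
    if prob.size == 0:
        return []
    if prob.ndim != 2:
        raise ValueError("probability matrix must be 2D")
    if (prob < 0).any():
        raise ValueError("probabilities must be nonnegative")
    rows, cols = linear_sum_assignment(prob, maximize=True)
    out: list[Optional[int]] = [None] * prob.shape[0]
    for i, j in zip(rows, cols):
        out[i] = int(j)
    return out
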