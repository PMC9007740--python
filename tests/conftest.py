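import numpy as np
import pytest

from multipose.model import Instance, LabeledFrame, LabelsDataset, Skeleton, Track
from multipose.synth import star_skeleton

FLY_NODES = [
    "head", "thorax", "abdomen", "wingL", "wingR", "forelegL4", "forelegR4",
    "midlegL4", "midlegR4", "hindlegL4", "hindlegR4", "eyeL", "eyeR",
]
# 12 edges rooted at the thorax (legs/wings/abdomen/head) and head (eyes).
FLY_EDGES = [
    (1, 0), (1, 2), (1, 3), (1, 4), (1, 5), (1, 6),
    (1, 7), (1, 8), (1, 9), (1, 10), (0, 11), (0, 12),
]


@pytest.fixture
def fly_skeleton():
    return Skeleton(nodes=FLY_NODES, edges=FLY_EDGES, name="fly13")


@pytest.fixture
def toy_skeleton():
    """4-node chain-and-branch tree: 0 -> 1 -> 2, 1 -> 3."""
    return Skeleton(nodes=["a", "b", "c", "d"], edges=[(0, 1), (1, 2), (1, 3)], name="toy")


@pytest.fixture
def star5():
    return star_skeleton(5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(skeleton, points, **kwargs):
    return Instance.from_points(skeleton, np.asarray(points, dtype=float), **kwargs)


@pytest.fixture
def small_dataset(star5):
    """2 frames x 2 tracked instances, one invisible node."""
    pts_a = np.array([[10.0, 10.0], [14, 10], [10, 14], [6, 10], [10, 6]])
    pts_b = pts_a + 30.0
    pts_b2 = pts_b.copy()
    pts_b2[3] = np.nan
    frames = [
        LabeledFrame(
            "vid0",
            0,
            [
                make_instance(star5, pts_a, track_id=0),
                make_instance(star5, pts_b, track_id=1),
            ],
        ),
        LabeledFrame(
            "vid0",
            1,
            [
                make_instance(star5, pts_a + 1.5, track_id=0, point_scores=np.full(5, 0.9)),
                make_instance(star5, pts_b2, track_id=1, instance_score=0.8),
            ],
        ),
    ]
    return LabelsDataset(
        skeleton=star5,
        frames=frames,
        tracks=[Track(0, "animal0"), Track(1, "animal1")],
        image_size=(64, 64),
        provenance="fixture",
    )
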