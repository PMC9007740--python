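import itertools

import numpy as np
import pytest

from multipose.encode import (
    GridSpec,
    PAFs,
    ClassMaps,
    encode_class_maps,
    encode_confidence_maps,
    encode_pafs,
    make_anchor_crops,
    select_anchor,
)
from multipose.group import (
    ConnectionCandidate,
    assemble_instances,
    assign_ids_class_maps,
    assign_ids_probabilities,
    bottomup_decode,
    make_connection_candidates,
    match_edge,
    score_connection,
    topdown_decode,
)
from multipose.model import Skeleton
from multipose.peaks import Peak, find_local_peaks, refine_peaks
from multipose.synth import SceneSpec, generate_scene, star_skeleton

from conftest import make_instance


def make_peak(channel, x, y, value=1.0):
    return Peak(channel=channel, grid_xy=(int(x), int(y)), image_xy=(float(x), float(y)), value=value)


def uniform_pafs(shape, vec, edge_count=1):
    """PAF tensor equal to ``vec`` everywhere for every edge."""
    h, w = shape
    tensor = np.zeros((h, w, 2 * edge_count))
    tensor[:, :, 0::2] = vec[0]
    tensor[:, :, 1::2] = vec[1]
    return PAFs(tensor=tensor, grid=GridSpec(h, w), edge_list=((0, 1),))


class TestScoreConnection:
    def test_perfect_alignment_scores_one(self):
        pafs = uniform_pafs((32, 32), (1.0, 0.0))
        assert score_connection(pafs, 0, (4, 10), (24, 10)) == pytest.approx(1.0)

    def test_perpendicular_scores_zero(self):
        pafs = uniform_pafs((32, 32), (0.0, 1.0))
        assert score_connection(pafs, 0, (4, 10), (24, 10)) == pytest.approx(0.0)

    def test_antiparallel_scores_minus_one(self):
        pafs = uniform_pafs((32, 32), (-1.0, 0.0))
        assert score_connection(pafs, 0, (4, 10), (24, 10)) == pytest.approx(-1.0)

    def test_zero_length_candidate(self):
        pafs = uniform_pafs((32, 32), (1.0, 0.0))
        assert score_connection(pafs, 0, (4, 10), (4, 10)) == 0.0

    def test_two_fly_scene_true_edge_beats_swap(self):
        sk = Skeleton(nodes=["thorax", "head"], edges=[(0, 1)])
        a = make_instance(sk, [[10.0, 16], [20, 16]])
        b = make_instance(sk, [[10.0, 48], [20, 48]])
        grid = GridSpec(64, 64)
        pafs = encode_pafs([a, b], sk, grid)
        true_score = score_connection(pafs, 0, (10, 16), (20, 16))
        swap_score = score_connection(pafs, 0, (10, 16), (20, 48))
        assert true_score > swap_score
        assert true_score == pytest.approx(1.0, abs=0.01)

    def test_ten_point_mean_matches_dense_integration(self):
        # Oracle: dense 1000-point line integral agrees within 0.05.
        sk = Skeleton(nodes=["thorax", "head"], edges=[(0, 1)])
        a = make_instance(sk, [[10.0, 16], [22, 20]])
        b = make_instance(sk, [[40.0, 40], [52, 44]])
        grid = GridSpec(64, 64)
        pafs = encode_pafs([a, b], sk, grid)
        coarse = score_connection(pafs, 0, (10, 16), (22, 20), n_samples=10)
        dense = score_connection(pafs, 0, (10, 16), (22, 20), n_samples=1000)
        assert coarse == pytest.approx(dense, abs=0.05)


class TestMatchEdge:
    def test_single_pair_matched(self):
        c = ConnectionCandidate(0, make_peak(0, 1, 1), make_peak(1, 5, 5), 0.9)
        assert match_edge([c]) == [c]

    def test_below_min_score_dropped(self):
        c = ConnectionCandidate(0, make_peak(0, 1, 1), make_peak(1, 5, 5), 0.01)
        assert match_edge([c]) == []

    def test_rectangular_two_sources_three_dests(self):
        srcs = [make_peak(0, 0, i) for i in range(2)]
        dsts = [make_peak(1, 10, i) for i in range(3)]
        cands = [
            ConnectionCandidate(0, s, d, 0.5 + 0.01 * (i + j))
            for i, s in enumerate(srcs)
            for j, d in enumerate(dsts)
        ]
        accepted = match_edge(cands)
        assert len(accepted) == 2
        assert len({id(c.source) for c in accepted}) == 2
        assert len({id(c.dest) for c in accepted}) == 2

    def test_mixed_edges_rejected(self):
        a = ConnectionCandidate(0, make_peak(0, 1, 1), make_peak(1, 5, 5), 0.9)
        b = ConnectionCandidate(1, make_peak(1, 1, 1), make_peak(2, 5, 5), 0.9)
        with pytest.raises(ValueError):
            match_edge([a, b])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_equals_brute_force_permutations(self, n, rng):
        # Oracle: best of n! permutations.
        for trial in range(5):
            scores = rng.uniform(0.1, 1.0, (n, n))
            srcs = [make_peak(0, 0, i) for i in range(n)]
            dsts = [make_peak(1, 10, i) for i in range(n)]
            cands = [
                ConnectionCandidate(0, s, d, scores[i, j])
                for i, s in enumerate(srcs)
                for j, d in enumerate(dsts)
            ]
            accepted = match_edge(cands, min_connection_score=0.0)
            total = sum(c.score for c in accepted)
            best = max(
                sum(scores[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert total == pytest.approx(best)

    def test_empty_input(self):
        assert match_edge([]) == []


class TestAssembleInstances:
    def _decode(self, instances, skeleton, grid=None, **kwargs):
        grid = grid or GridSpec(128, 128)
        cms = encode_confidence_maps(instances, grid)
        pafs = encode_pafs(instances, skeleton, grid)
        return bottomup_decode(cms, pafs, skeleton, **kwargs)

    def test_single_fly_all_nodes(self, fly_skeleton):
        rng = np.random.default_rng(0)
        center = np.array([64.0, 64.0])
        pts = center + rng.uniform(-20, 20, (13, 2))
        inst = make_instance(fly_skeleton, pts)
        assembled = self._decode([inst], fly_skeleton)
        assert len(assembled) == 1
        got = assembled[0].instance
        assert got.visible.all()
        np.testing.assert_allclose(got.points, pts, atol=0.3)

    def test_three_flies_non_overlapping(self, star5):
        spec = SceneSpec(
            skeleton=star5, image_size=(192, 192), n_instances=3, min_separation=70,
            pose_scale=14, seed=11,
        )
        insts, _ = generate_scene(spec)
        grid = GridSpec(192, 192)
        assembled = self._decode(insts, star5, grid)
        assert len(assembled) == 3
        # Exact grouping: each assembly's nodes all come from one GT instance.
        for asm in assembled:
            dists = [
                np.nanmax(np.abs(asm.instance.points - gt.points)) for gt in insts
            ]
            assert min(dists) < 0.5

    def test_occluded_node_left_invisible(self, star5):
        pts = np.array([[64.0, 64], [80, 64], [64, 80], [48, 64], [64, 48]])
        pts[3] = np.nan
        inst = make_instance(star5, pts)
        assembled = self._decode([inst], star5)
        assert len(assembled) == 1
        got = assembled[0].instance
        assert not got.visible[3]
        assert got.visible[[0, 1, 2, 4]].all()

    def test_exhaustive_partition_oracle_toy(self, toy_skeleton):
        # 3 instances x 4-node tree; oracle: max-total-score partition by
        # brute force over all per-edge permutations.
        rng = np.random.default_rng(3)
        centers = np.array([[30.0, 30], [96, 40], [50, 96]])
        gt = []
        for c in centers:
            pts = c + rng.uniform(-12, 12, (4, 2))
            gt.append(make_instance(toy_skeleton, pts))
        grid = GridSpec(128, 128)
        cms = encode_confidence_maps(gt, grid)
        pafs = encode_pafs(gt, toy_skeleton, grid)
        peaks = refine_peaks(cms, find_local_peaks(cms))
        per_edge = make_connection_candidates(pafs, toy_skeleton, peaks)

        # Brute force: choose a permutation per edge independently
        # (valid here because each node appears in exactly 3 peaks).
        def edge_best(cands):
            srcs = list({id(c.source): c.source for c in cands}.values())
            dsts = list({id(c.dest): c.dest for c in cands}.values())
            table = {(id(c.source), id(c.dest)): c for c in cands}
            best, best_set = -np.inf, None
            for perm in itertools.permutations(range(len(dsts))):
                sel = [table[(id(srcs[i]), id(dsts[perm[i]]))] for i in range(len(srcs))]
                tot = sum(c.score for c in sel)
                if tot > best:
                    best, best_set = tot, sel
            return best_set

        oracle_conns = [c for cands in per_edge for c in edge_best(cands)]
        oracle_total = sum(c.score for c in oracle_conns)

        accepted = [c for cands in per_edge for c in match_edge(cands)]
        assembled = assemble_instances(peaks, accepted, toy_skeleton)
        assert len(assembled) == 3
        assert sum(a.score for a in assembled) == pytest.approx(oracle_total, abs=1e-9)
        for asm in assembled:
            dists = [np.nanmax(np.abs(asm.instance.points - g.points)) for g in gt]
            assert min(dists) < 0.5

    def test_max_instances_cap(self, star5):
        spec = SceneSpec(
            skeleton=star5, image_size=(192, 192), n_instances=3, min_separation=70,
            pose_scale=14, seed=2,
        )
        insts, _ = generate_scene(spec)
        assembled = self._decode(insts, star5, GridSpec(192, 192), max_instances=2)
        assert len(assembled) == 2

    def test_no_peak_used_twice(self, star5, rng):
        for seed in range(5):
            spec = SceneSpec(
                skeleton=star5, image_size=(256, 256), n_instances=4,
                min_separation=60, pose_scale=12, seed=seed,
            )
            insts, _ = generate_scene(spec)
            grid = GridSpec(256, 256)
            cms = encode_confidence_maps(insts, grid)
            pafs = encode_pafs(insts, star5, grid)
            assembled = bottomup_decode(cms, pafs, star5)
            used = [id(pk) for asm in assembled for pk in asm.peaks.values()]
            assert len(used) == len(set(used))

    def test_invalid_skeleton_rejected(self):
        sk = Skeleton(nodes=["a", "b"], edges=[(0, 0)])
        with pytest.raises(ValueError):
            assemble_instances([], [], sk)

    def test_singletons(self, star5):
        pk = make_peak(2, 40, 40, 0.9)
        got = assemble_instances([pk], [], star5, allow_singletons=True)
        assert len(got) == 1
        assert got[0].instance.visible[2]
        assert got[0].instance.visible.sum() == 1
        assert assemble_instances([pk], [], star5, allow_singletons=False) == []

    def test_grouping_exact_on_separated_scenes(self, star5):
        # Spacing > 4 sigma: grouping must be exact for 2-8 animals.
        for n, seed in [(2, 0), (5, 1), (8, 2)]:
            spec = SceneSpec(
                skeleton=star5, image_size=(360, 360), n_instances=n,
                min_separation=75, pose_scale=13, seed=seed,
            )
            insts, _ = generate_scene(spec)
            grid = GridSpec(360, 360)
            cms = encode_confidence_maps(insts, grid)
            pafs = encode_pafs(insts, star5, grid)
            assembled = bottomup_decode(cms, pafs, star5)
            assert len(assembled) == n
            for asm in assembled:
                dists = [np.nanmax(np.abs(asm.instance.points - g.points)) for g in insts]
                assert min(dists) < 0.5


class TestTopDownDecode:
    def test_round_trip_centered_crop(self, star5):
        pts = np.array([[64.0, 64], [80.2, 64], [64, 79.7], [48.4, 64], [64, 48.1]])
        inst = make_instance(star5, pts)
        anchor = select_anchor(inst, anchor_node=0)
        crop_size = 64
        from multipose.encode import crop_topleft

        x0, y0 = crop_topleft(anchor, crop_size)
        local = make_instance(star5, pts - (x0, y0))
        crop_cms = encode_confidence_maps([local], GridSpec(crop_size, crop_size, sigma_base=1.5))
        decoded = topdown_decode([crop_cms], [anchor], crop_size, star5)
        assert len(decoded) == 1
        np.testing.assert_allclose(decoded[0].points, pts, atol=0.25)

    def test_corner_anchor_padding_arithmetic(self, star5):
        # Oracle: points near the frame corner survive crop-and-restore.
        pts = np.array([[6.0, 6], [14, 6], [6, 14], [2, 6], [6, 2]])
        inst = make_instance(star5, pts)
        anchor = (6.0, 6.0)
        crop_size = 32
        from multipose.encode import crop_topleft

        x0, y0 = crop_topleft(anchor, crop_size)
        assert (x0, y0) == (-10, -10)
        local = make_instance(star5, pts - (x0, y0))
        crop_cms = encode_confidence_maps([local], GridSpec(crop_size, crop_size, sigma_base=1.5))
        decoded = topdown_decode([crop_cms], [anchor], crop_size, star5)
        np.testing.assert_allclose(decoded[0].points, pts, atol=0.25)

    def test_empty_crop_dropped(self, star5):
        crop_cms = encode_confidence_maps(
            [make_instance(star5, np.full((5, 2), 500.0))], GridSpec(32, 32)
        )
        assert topdown_decode([crop_cms], [(16.0, 16.0)], 32, star5) == []

    def test_mismatched_lengths(self, star5):
        with pytest.raises(ValueError):
            topdown_decode([], [(1.0, 1.0)], 32, star5)


class TestAssignIdsClassMaps:
    def test_one_hot_two_instances(self, star5):
        a = make_instance(star5, np.full((5, 2), 16.0) + np.arange(10).reshape(5, 2), class_id=0)
        b = make_instance(star5, np.full((5, 2), 48.0) + np.arange(10).reshape(5, 2), class_id=1)
        cmaps = encode_class_maps([a, b], n_classes=2, radius=8.0, grid=GridSpec(64, 64))
        # Strip labels and recover them.
        import dataclasses

        a2, b2 = dataclasses.replace(a, class_id=None), dataclasses.replace(b, class_id=None)
        out = assign_ids_class_maps([b2, a2], cmaps)
        assert out[0].class_id == 1
        assert out[1].class_id == 0

    def test_random_soft_maps_equal_permutation_oracle(self, star5, rng):
        n = 4
        insts = [
            make_instance(star5, np.full((5, 2), 8.0 + 12 * i) + rng.uniform(0, 3, (5, 2)))
            for i in range(n)
        ]
        tensor = rng.random((64, 64, n))
        cmaps = ClassMaps(tensor=tensor, grid=GridSpec(64, 64))
        scores = np.zeros((n, n))
        for i, inst in enumerate(insts):
            idx = cmaps.grid.image_to_grid(inst.points[inst.visible])
            scores[i] = tensor[idx[:, 1], idx[:, 0], :].mean(axis=0)
        best = max(
            (sum(scores[i, p[i]] for i in range(n)), p)
            for p in itertools.permutations(range(n))
        )[1]
        out = assign_ids_class_maps(insts, cmaps)
        assert [inst.class_id for inst in out] == list(best)

    def test_ambiguous_region_unassigned(self, star5):
        pts = np.full((5, 2), 16.0)
        a = make_instance(star5, pts, class_id=0)
        b = make_instance(star5, pts + 0.5, class_id=1)
        cmaps = encode_class_maps([a, b], n_classes=2, radius=10.0, grid=GridSpec(32, 32))
        # Both instances sit entirely inside the zeroed ambiguous region.
        import dataclasses

        out = assign_ids_class_maps([dataclasses.replace(a, class_id=None)], cmaps)
        assert out[0].class_id is None


class TestAssignIdsProbabilities:
    def test_identity_matrix(self):
        assert assign_ids_probabilities(np.eye(3)) == [0, 1, 2]

    def test_row_swapped_identity(self):
        m = np.eye(3)[[1, 0, 2]]
        assert assign_ids_probabilities(m) == [1, 0, 2]

    def test_random_4x4_equals_permutation_oracle(self, rng):
        m = rng.random((4, 4))
        got = assign_ids_probabilities(m)
        best = max(
            (sum(m[i, p[i]] for i in range(4)), p)
            for p in itertools.permutations(range(4))
        )[1]
        assert got == list(best)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_permutation_oracle_up_to_5(self, n, rng):
        for _ in range(5):
            m = rng.random((n, n))
            got = assign_ids_probabilities(m)
            total = sum(m[i, got[i]] for i in range(n))
            best = max(
                sum(m[i, p[i]] for i in range(n))
                for p in itertools.permutations(range(n))
            )
            assert total == pytest.approx(best)

    def test_surplus_instances_unassigned(self, rng):
        m = rng.random((4, 2))
        got = assign_ids_probabilities(m)
        assert sum(g is not None for g in got) == 2
        assert sorted(g for g in got if g is not None) == [0, 1]

    def test_empty_matrix(self):
        assert assign_ids_probabilities(np.zeros((0, 3))) == []

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_ids_probabilities(np.array([[-0.1, 0.5]]))
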