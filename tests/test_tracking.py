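"""Association similarity functions, pose embedding, pair sampling, tracker."""
import math

import numpy as np
import pytest

from handtrack.datamodel import BoundingBox, Keypoint, N_JOINTS
from handtrack.tracking import (
    GCNTrainConfig,
    PairSampler,
    PoseGCN,
    TrackerState,
    contrastive_loss,
    embed_pose,
    greedy_assign,
    iou,
    mean_keypoint_distance,
    normalize_pose,
    step_tracker,
    train_gcn,
)

from conftest import make_clip, make_pose, shift_pose


class TestIou:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 1, 1), BoundingBox(5, 5, 6, 6)) == 0.0

    def test_hand_arithmetic_third(self):
        """(0,0,2,2) vs (1,0,3,2): intersection 2, union 6 -> 1/3."""
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_symmetric(self, rng):
        for _ in range(20):
            a = BoundingBox(*np.sort(rng.uniform(0, 50, 2)) + [0, 1], *np.sort(rng.uniform(0, 50, 2)) + [60, 61])
            a = BoundingBox(rng.uniform(0, 20), rng.uniform(0, 20), rng.uniform(21, 50), rng.uniform(21, 50))
            b = BoundingBox(rng.uniform(0, 20), rng.uniform(0, 20), rng.uniform(21, 50), rng.uniform(21, 50))
            assert iou(a, b) == pytest.approx(iou(b, a))
            assert 0.0 <= iou(a, b) <= 1.0


class TestKeypointDistance:
    def test_identical_poses(self):
        p = make_pose(40, 40)
        assert mean_keypoint_distance(p, p) == 0.0

    def test_translation_is_345(self):
        p = make_pose(40, 40)
        q = shift_pose(p, 3.0, 4.0)
        assert mean_keypoint_distance(p, q) == pytest.approx(5.0)

    def test_masked_mean_over_shared_joints(self):
        """a annotated on 0-9, b on 5-14: distance averages joints 5-9."""
        a = make_pose(40, 40)
        b = shift_pose(a, 6.0, 8.0)
        for j in range(N_JOINTS):
            if j >= 10:
                a.keypoints[j].state = "unannotated"
            if j < 5 or j >= 15:
                b.keypoints[j].state = "unannotated"
        # brute-force oracle over the shared annotated set
        shared = [j for j in range(N_JOINTS) if 5 <= j <= 9]
        expect = np.mean(
            [
                math.hypot(
                    a.keypoints[j].x - b.keypoints[j].x,
                    a.keypoints[j].y - b.keypoints[j].y,
                )
                for j in shared
            ]
        )
        assert mean_keypoint_distance(a, b) == pytest.approx(expect) == pytest.approx(10.0)

    def test_no_shared_joints_is_sentinel(self):
        a = make_pose(40, 40)
        b = make_pose(40, 40)
        for j in range(N_JOINTS):
            a.keypoints[j].state = "unannotated" if j < 10 else "visible"
            b.keypoints[j].state = "visible" if j < 10 else "unannotated"
        assert mean_keypoint_distance(a, b) == math.inf


class TestNormalizePose:
    def test_corner_and_center(self):
        p = make_pose(50, 50)
        p.keypoints[0] = Keypoint(p.box.x0, p.box.y0, "visible")
        p.keypoints[1] = Keypoint(*p.box.center, "visible")
        x = normalize_pose(p, 2)
        np.testing.assert_allclose(x[0], [0.0, 0.0], atol=1e-7)
        np.testing.assert_allclose(x[1], [0.5, 0.5], atol=1e-7)

    def test_annotation_state_channel(self):
        states = ["visible"] * N_JOINTS
        states[3] = "unannotated"
        p = make_pose(50, 50, states=states)
        x = normalize_pose(p, 3)
        assert x[0, 2] == 1.0  # annotated ground truth
        assert x[3, 2] == 0.0  # unannotated
        q = make_pose(50, 50, confidence=0.4)
        assert normalize_pose(q, 3)[0, 2] == pytest.approx(0.4)

    def test_coordinates_clamped(self):
        p = make_pose(50, 50)
        p.keypoints[2] = Keypoint(p.box.x1 + 50, p.box.y0 - 50, "visible")
        x = normalize_pose(p, 2)
        assert x[2, 0] == 1.0 and x[2, 1] == 0.0

    def test_zero_area_box_rejected(self):
        p = make_pose(50, 50)
        p.box = BoundingBox(10, 10, 10 + 1e-12, 20)
        p.box.x1 = p.box.x0  # force degenerate
        with pytest.raises(ValueError):
            normalize_pose(p)

    def test_bad_channel_count_rejected(self):
        with pytest.raises(ValueError):
            normalize_pose(make_pose(), channels=4)


class TestEmbedding:
    def test_shape_finite_deterministic(self):
        model = PoseGCN(seed=3)
        x = normalize_pose(make_pose(40, 40), 3)
        e1 = embed_pose(model, x)
        e2 = embed_pose(model, x)
        assert e1.shape == (128,)
        assert np.isfinite(e1).all()
        np.testing.assert_array_equal(e1, e2)

    def test_shape_mismatch_rejected(self):
        model = PoseGCN(seed=3)
        with pytest.raises(ValueError):
            embed_pose(model, np.zeros((N_JOINTS, 2), dtype=np.float32))


class TestContrastiveLoss:
    def test_positive_identical_is_zero(self):
        e = np.ones(8)
        assert contrastive_loss(e, e, 1, 1.0, "as_printed") == 0.0
        assert contrastive_loss(e, e, 1, 1.0, "standard") == 0.0

    def test_negative_identical_as_printed(self):
        """y=0, d=0, m=1: 0.5 * max(0, (1-0)^2) = 0.5."""
        e = np.zeros(4)
        assert contrastive_loss(e, e, 0, 1.0, "as_printed") == pytest.approx(0.5)

    def test_positive_squared_distance_as_printed(self):
        """y=1, d=||e1-e2||^2=2: 0.5 * 2 = 1.0."""
        e1 = np.zeros(2)
        e2 = np.array([1.0, 1.0])  # squared L2 = 2
        assert contrastive_loss(e1, e2, 1, 1.0, "as_printed") == pytest.approx(1.0)

    def test_standard_mode_hinge(self):
        e1 = np.zeros(1)
        e2 = np.array([0.4])  # L2 = 0.4
        assert contrastive_loss(e1, e2, 0, 1.0, "standard") == pytest.approx(0.5 * 0.6**2)
        assert contrastive_loss(e1, e2, 1, 1.0, "standard") == pytest.approx(0.5 * 0.16)
        e3 = np.array([2.0])  # beyond margin
        assert contrastive_loss(e1, e3, 0, 1.0, "standard") == 0.0

    def test_invalid_mode_and_margin(self):
        e = np.zeros(2)
        with pytest.raises(ValueError):
            contrastive_loss(e, e, 1, 1.0, "nope")
        with pytest.raises(ValueError):
            contrastive_loss(e, e, 1, 0.0)


def _pair_dataset(n_clips=4, n_frames=5, hands=2):
    clips = []
    for c in range(n_clips):
        frames = []
        for t in range(n_frames):
            frames.append(
                [
                    make_pose(30 + 50 * h + 3 * t + 7 * c, 40 + 2 * t, track_id=h)
                    for h in range(hands)
                ]
            )
        clips.append(make_clip(frames, clip_id=f"clip{c}"))
    return clips


class TestPairSampling:
    def test_category_frequencies(self):
        """10,000 seeded draws land within +-0.02 of (0.5, 0.4, 0.1)."""
        sampler = PairSampler(_pair_dataset())
        rng = np.random.default_rng(77)
        counts = np.zeros(3)
        for _ in range(10_000):
            _a, _b, _y, cat = sampler.sample(rng)
            counts[cat] += 1
        freqs = counts / counts.sum()
        np.testing.assert_allclose(freqs, [0.5, 0.4, 0.1], atol=0.02)
        assert sampler.redraws == 0

    def test_positive_pairs_same_track_adjacent_frames(self):
        clips = _pair_dataset()
        sampler = PairSampler(clips)
        rng = np.random.default_rng(5)
        seen = 0
        while seen < 50:
            a, b, y, cat = sampler.sample(rng)
            if cat == 0:
                assert y == 1
                assert a.track_id == b.track_id
                seen += 1
            else:
                assert y == 0

    def test_cross_video_pairs_are_negative(self):
        sampler = PairSampler(_pair_dataset())
        rng = np.random.default_rng(6)
        for _ in range(200):
            _a, _b, y, cat = sampler.sample(rng)
            if cat == 2:
                assert y == 0

    def test_degenerate_dataset_redraws(self):
        # single clip -> cross-video draws must be redrawn, not crash
        sampler = PairSampler(_pair_dataset(n_clips=1))
        rng = np.random.default_rng(8)
        for _ in range(100):
            _a, _b, _y, cat = sampler.sample(rng)
            assert cat != 2
        assert sampler.redraws > 0


class TestTrainGcn:
    def test_zero_lr_accuracy_flat(self):
        clips = _pair_dataset(n_clips=5)
        cfg = GCNTrainConfig(epochs=3, lr=0.0, steps_per_epoch=5, n_val_pairs=40, seed=0)
        _m, history = train_gcn(clips, cfg)
        assert max(history) - min(history) < 1e-9

    def test_margins_train_without_blowup(self):
        clips = _pair_dataset(n_clips=5)
        for m in (1.0, 2.0):
            cfg = GCNTrainConfig(epochs=2, steps_per_epoch=10, margin=m, n_val_pairs=40, seed=0)
            model, history = train_gcn(clips, cfg)
            emb = model.forward(np.zeros((1, N_JOINTS, 3), dtype=np.float32))
            assert np.isfinite(emb).all()
            assert all(np.isfinite(history))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_gcn([], GCNTrainConfig())


class TestStepTracker:
    def test_cold_start_assigns_fresh_ids(self):
        state = TrackerState(strategy="iou")
        dets = [make_pose(30, 30), make_pose(100, 30), make_pose(30, 100)]
        ids = step_tracker(state, dets)
        assert ids == [0, 1, 2]
        assert state.next_id == 3

    def test_static_scene_keeps_ids(self):
        state = TrackerState(strategy="iou")
        dets = [make_pose(30, 30), make_pose(100, 30)]
        first = step_tracker(state, dets)
        for _ in range(5):
            assert step_tracker(state, dets) == first

    def test_assignment_injective(self, rng):
        for strategy in ("iou", "l2"):
            state = TrackerState(strategy=strategy)
            step_tracker(state, [make_pose(30, 30, radius=12), make_pose(60, 30, radius=12)])
            ids = step_tracker(
                state,
                [
                    make_pose(30 + rng.uniform(-3, 3), 30),
                    make_pose(60 + rng.uniform(-3, 3), 30),
                    make_pose(45, 60),
                ],
            )
            assert len(set(ids)) == len(ids)

    def test_unmatched_track_expires_at_max_age(self):
        state = TrackerState(strategy="iou", max_age=1)
        step_tracker(state, [make_pose(30, 30)])
        step_tracker(state, [])  # miss -> expired
        ids = step_tracker(state, [make_pose(30, 30)])
        assert ids == [1]  # id 0 never reused

    def test_gcn_strategy_requires_model(self):
        state = TrackerState(strategy="gcn")
        with pytest.raises(ValueError):
            step_tracker(state, [make_pose(30, 30)])

    def test_l2_distance_threshold_rejects_far_jumps(self):
        state = TrackerState(strategy="l2")
        step_tracker(state, [make_pose(30, 30, radius=10)])
        ids = step_tracker(state, [make_pose(150, 150, radius=10)])
        assert ids == [1]  # too far: new track


class TestGreedyAssign:
    def test_greedy_matches_hungarian_on_diagonal_dominant(self, rng):
        from scipy.optimize import linear_sum_assignment

        for _ in range(50):
            n = int(rng.integers(1, 5))
            sim = rng.uniform(0, 0.4, size=(n, n))
            perm = rng.permutation(n)
            for i, j in enumerate(perm):
                sim[i, j] = rng.uniform(0.6, 1.0)  # dominant entries
            floor = np.zeros((n, n))
            pairs = set(greedy_assign(sim, floor))
            rows, cols = linear_sum_assignment(-sim)
            assert pairs == set(zip(rows.tolist(), cols.tolist()))

    def test_one_by_one(self):
        assert greedy_assign(np.array([[0.7]]), np.array([[0.2]])) == [(0, 0)]
        assert greedy_assign(np.array([[0.1]]), np.array([[0.2]])) == []
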