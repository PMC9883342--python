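"""Conditional prediction head: curriculum, prior selection, inference."""
import numpy as np
import pytest

from handtrack.conditional import (
    CondConfig,
    ConditionalPoseNet,
    PriorHeatmap,
    Track,
    condpose_forward,
    curriculum_prob,
    infer_frame,
    select_prior,
    train_condpose,
)
from handtrack.heatmap import HeatmapStack
from handtrack.posenet import PoseNet, PoseNetConfig
from handtrack.synth import SynthConfig, generate_clip


class TestCurriculum:
    @pytest.mark.parametrize(
        "epoch, expected",
        [(0, 0.0), (1, 0.1), (5, 0.5), (9, 0.9), (10, 1.0), (12, 1.0), (100, 1.0)],
    )
    def test_probability_schedule(self, epoch, expected):
        """p = 0.10 * epoch, saturating at 1 from epoch 10 onward."""
        assert curriculum_prob(epoch, CondConfig()) == pytest.approx(expected)

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            curriculum_prob(-1, CondConfig())

    def test_custom_slope(self):
        cfg = CondConfig(curriculum_slope=0.25)
        assert curriculum_prob(2, cfg) == pytest.approx(0.5)
        assert curriculum_prob(4, cfg) == 1.0


def _stack_with_value(v, grid=(8, 8)):
    vals = np.full((21, *grid), v, dtype=np.float32)
    return HeatmapStack(vals, np.ones(21, bool))


class TestSelectPrior:
    GRID = (8, 8)

    def test_no_history_gives_zeros(self):
        prior = select_prior(Track(0), 0, 3, self.GRID)
        assert prior.is_zero
        assert prior.stack.values.sum() == 0.0
        prior2 = select_prior(None, 5, 3, self.GRID)
        assert prior2.is_zero

    def test_exact_delta_frame_preferred(self):
        tr = Track(0, heatmaps={2: _stack_with_value(0.2), 4: _stack_with_value(0.4)})
        prior = select_prior(tr, 5, 3, self.GRID)
        assert prior.source_frame == 2

    def test_forward_fallback_nearest_to_gap(self):
        """Absent at t-3 but present at t-2 and t-1 -> takes t-2."""
        tr = Track(0, heatmaps={3: _stack_with_value(0.3), 4: _stack_with_value(0.4)})
        prior = select_prior(tr, 5, 3, self.GRID)
        assert prior.source_frame == 3

    def test_backward_fallback_to_first_occurrence(self):
        tr = Track(0, heatmaps={0: _stack_with_value(0.1)})
        prior = select_prior(tr, 5, 3, self.GRID)
        assert prior.source_frame == 0

    def test_delta_below_one_rejected(self):
        with pytest.raises(ValueError):
            select_prior(Track(0), 2, 0, self.GRID)


@pytest.fixture(scope="module")
def tiny_cond_model():
    net_cfg = PoseNetConfig(seed=0)
    return ConditionalPoseNet(CondConfig(seed=0), net_cfg), net_cfg


class TestForward:
    def test_zeros_prior_shape_and_finiteness(self, tiny_cond_model):
        model, net_cfg = tiny_cond_model
        crop = np.random.default_rng(0).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        out = condpose_forward(model, crop, PriorHeatmap(HeatmapStack.zeros(21, (32, 32))))
        assert out.values.shape == (21, 32, 32)
        assert np.isfinite(out.values).all()

    def test_deterministic(self, tiny_cond_model):
        model, _ = tiny_cond_model
        crop = np.random.default_rng(1).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        prior = HeatmapStack(
            np.random.default_rng(2).random((21, 32, 32)).astype(np.float32),
            np.ones(21, bool),
        )
        o1 = condpose_forward(model, crop, prior)
        o2 = condpose_forward(model, crop, prior)
        np.testing.assert_array_equal(o1.values, o2.values)

    def test_grid_mismatch_rejected(self, tiny_cond_model):
        model, _ = tiny_cond_model
        crop = np.zeros((64, 64, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            condpose_forward(model, crop, PriorHeatmap(HeatmapStack.zeros(21, (16, 16))))

    def test_ablation_param_counts_distinct_and_smaller(self):
        net_cfg = PoseNetConfig(seed=0)
        counts = {}
        for name, (ua, uf) in {
            "full": (True, True),
            "nc": (True, False),
            "na": (False, True),
            "nc-na": (False, False),
        }.items():
            m = ConditionalPoseNet(
                CondConfig(use_attention=ua, use_feature_map=uf, seed=0), net_cfg
            )
            counts[name] = m.param_count()
        assert len(set(counts.values())) == 4
        assert all(counts[k] < counts["full"] for k in ("nc", "na", "nc-na"))

    def test_fusion_can_reproduce_baseline_pathway(self):
        """With fusion weights that copy the first J channels, the
        conditional forward under a zeros prior equals the trunk output."""
        net_cfg = PoseNetConfig(seed=3)
        model = ConditionalPoseNet(CondConfig(seed=3), net_cfg)
        j = net_cfg.n_joints
        # craft the fusion head into an identity on H'_t
        for layer in model.fus.layers:
            if hasattr(layer, "W"):
                layer.W.value[...] = 0.0
                layer.b.value[...] = 0.0
        c1, c2, c3 = (model.fus.layers[0], model.fus.layers[2], model.fus.layers[4])
        big = 1e3  # keep intermediate activations positive through the ReLUs
        for i in range(min(j, c1.W.value.shape[0])):
            c1.W.value[i, i, 1, 1] = 1.0
            c1.b.value[i] = big
            c2.W.value[i, i, 1, 1] = 1.0
            c3.W.value[i, i, 1, 1] = 1.0
            c3.b.value[i] = -big
        crop = np.random.default_rng(4).integers(0, 255, (64, 64, 3), dtype=np.uint8)
        from handtrack.posenet import pose_forward

        base, _ = pose_forward(model.trunk, crop)
        out = condpose_forward(
            model, crop, PriorHeatmap(HeatmapStack.zeros(j, (32, 32)))
        )
        sel = np.s_[: min(j, c1.W.value.shape[0])]
        np.testing.assert_allclose(out.values[sel], base.values[sel], atol=2e-3)


class _StubModel:
    """Emits a constant heatmap per prior identity (via the prior's mean)."""

    def __init__(self, mapping, grid=(8, 8)):
        self.mapping = mapping  # prior mean value -> output mean-max level
        self.net_config = PoseNetConfig(
            input_size=(16, 16), heatmap_size=grid, n_joints=21
        )
        self.cond = CondConfig(seed=0)

    def forward(self, x, prior):
        key = round(float(prior.mean()), 3)
        level = self.mapping.get(key, 0.05)
        return np.full((1, 21, *self.net_config.heatmap_size), level, dtype=np.float32)


class TestInferFrame:
    def test_no_priors_uses_zeros(self):
        model = _StubModel({0.0: 0.7})
        crop = np.zeros((16, 16, 3), dtype=np.uint8)
        results = infer_frame(model, [crop], [], model.cond)
        assert len(results) == 1
        assert results[0][1] is None

    def test_highest_mean_max_candidate_wins(self):
        """Candidates with mean-max 0.6 / 0.4 / 0.3 -> the 0.6 one wins."""
        grid = (8, 8)
        p1 = PriorHeatmap(_stack_with_value(0.111, grid), 1)
        p2 = PriorHeatmap(_stack_with_value(0.222, grid), 2)
        model = _StubModel({0.111: 0.4, 0.222: 0.6, 0.0: 0.3})
        crop = np.zeros((16, 16, 3), dtype=np.uint8)
        results = infer_frame(model, [crop], [p1, p2], model.cond)
        stack, idx = results[0]
        assert idx == 1  # p2 is at list index 1
        assert stack.values.max() == pytest.approx(0.6)

    def test_output_invariant_to_prior_ordering(self):
        grid = (8, 8)
        p1 = PriorHeatmap(_stack_with_value(0.111, grid), 1)
        p2 = PriorHeatmap(_stack_with_value(0.222, grid), 2)
        model = _StubModel({0.111: 0.4, 0.222: 0.6, 0.0: 0.3})
        crop = np.zeros((16, 16, 3), dtype=np.uint8)
        a = infer_frame(model, [crop], [p1, p2], model.cond)[0][0]
        b = infer_frame(model, [crop], [p2, p1], model.cond)[0][0]
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_detections(self):
        model = _StubModel({})
        assert infer_frame(model, [], [], model.cond) == []


@pytest.fixture(scope="module")
def tracked_clips():
    return [
        generate_clip(SynthConfig(n_frames=5, n_hands=2, seed=400 + i), f"t{i}")
        for i in range(2)
    ]


class TestTrainCondpose:
    def test_zero_slope_always_ground_truth_priors(self, tracked_clips):
        net_cfg = PoseNetConfig(seed=0)
        cfg = CondConfig(curriculum_slope=0.0, seed=0)
        model = ConditionalPoseNet(cfg, net_cfg)
        _m, history = train_condpose(tracked_clips, model, cfg, epochs=2, lr=1e-3)
        assert all(h["pred_priors"] == 0 for h in history)

    def test_saturated_epochs_never_use_ground_truth(self, tracked_clips):
        net_cfg = PoseNetConfig(seed=0)
        cfg = CondConfig(curriculum_slope=0.5, saturation_epoch=2, seed=0)
        model = ConditionalPoseNet(cfg, net_cfg)
        _m, history = train_condpose(tracked_clips, model, cfg, epochs=4, lr=1e-3)
        assert history[0]["pred_priors"] == 0  # epoch 0: p = 0
        for h in history[2:]:  # epochs >= 1/slope: p = 1
            assert h["gt_priors"] == 0

    def test_loss_decreases(self, tracked_clips):
        net_cfg = PoseNetConfig(seed=1)
        cfg = CondConfig(seed=1)
        model = ConditionalPoseNet(cfg, net_cfg)
        _m, history = train_condpose(tracked_clips, model, cfg, epochs=3, lr=1e-3)
        assert history[-1]["loss"] < history[0]["loss"]

    def test_clip_without_track_ids_rejected(self, tracked_clips):
        frames, clip = tracked_clips[0]
        import copy

        stripped = copy.deepcopy(clip)
        for fr in stripped.frames:
            for p in fr.poses:
                p.track_id = None
        net_cfg = PoseNetConfig(seed=0)
        cfg = CondConfig(seed=0)
        model = ConditionalPoseNet(cfg, net_cfg)
        with pytest.raises(ValueError):
            train_condpose([(frames, stripped)], model, cfg, epochs=1)
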