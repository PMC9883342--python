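"""Temporally conditioned pose prediction from heatmap priors.

Instead of regressing each hand crop independently, the conditional model
fuses the current frame's initial estimate with the same track's heatmap
from delta frames earlier:

    H_t = M_fus(P(I_t); M_att(v_t; H_{t-delta}))

where P is the frame-wise pose network, v_t its early conv feature map,
M_att an attention head that re-weights the prior heatmap in the context
of the current image, and M_fus the fusion head producing the final
stack. When a track has no stored estimate the prior is an all-zeros
stack (always the case at frame one). Two ablation switches drop the
feature map from the attention input (NC) or the attention head entirely
(NA; the raw prior and the feature map then feed the fusion directly).

Training uses a curriculum: the prior for a sample at epoch e is the
model's own stored prediction with probability p = slope * e (default
0.10, saturating at 1 by epoch 10) and the encoded ground-truth heatmap
otherwise. At inference the association between detections and priors is
unknown, so each detection is paired with every live track's prior (plus
the zeros prior) and the candidate with the highest mean per-joint
confidence wins.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import HandPose, N_JOINTS
from .heatmap import (
    HeatmapStack,
    encode_heatmaps,
    make_crop,
    masked_mse,
    masked_mse_grad,
)
from .nn import Adam, Conv2d, ReLU
from .posenet import PoseNet, PoseNetConfig, _crop_to_input

__all__ = [
    "CondConfig",
    "PriorHeatmap",
    "Track",
    "curriculum_prob",
    "select_prior",
    "ConditionalPoseNet",
    "condpose_forward",
    "infer_frame",
    "train_condpose",
]


@dataclass
class CondConfig:
    delta: int = 3
    use_attention: bool = True
    use_feature_map: bool = True
    curriculum_slope: float = 0.10
    saturation_epoch: int = 10
    include_zero_prior: bool = True  # zeros prior always a candidate at inference
    head_channels: int = 16
    seed: int = 0

    def validate(self) -> None:
        if self.delta < 1:
            raise ValueError("delta must be >= 1")


@dataclass
class PriorHeatmap:
    """A track's earlier heatmap estimate, or all-zeros when none exists."""

    stack: HeatmapStack
    source_frame: int | None = None

    @property
    def is_zero(self) -> bool:
        return self.source_frame is None


@dataclass
class Track:
    """Time-indexed pose + heatmap history of one tracked hand."""

    track_id: int
    poses: dict[int, HandPose] = field(default_factory=dict)
    heatmaps: dict[int, HeatmapStack] = field(default_factory=dict)

    def add(self, frame: int, pose: HandPose | None, stack: HeatmapStack) -> None:
        if pose is not None:
            self.poses[frame] = pose
        self.heatmaps[frame] = stack


def curriculum_prob(epoch: int, config: CondConfig) -> float:
    """Probability of drawing a predicted (vs ground-truth) prior."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return min(config.curriculum_slope * epoch, 1.0)


def select_prior(
    track: Track | None,
    t: int,
    delta: int,
    grid_size: tuple[int, int],
    n_joints: int = N_JOINTS,
) -> PriorHeatmap:
    """Pick the prior heatmap for frame ``t`` from a track's history.

    Uses frame ``t - delta`` when stored. Otherwise the nearest stored
    frame is taken, scanning ``t-delta+1 .. t-1`` first (nearest to the
    intended gap first) and then backwards from ``t-delta-1`` to the
    track's first occurrence. A track with no stored frame before ``t``
    (e.g. at frame one) yields the zeros prior.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if track is not None:
        have = track.heatmaps
        if t - delta in have:
            return PriorHeatmap(have[t - delta], t - delta)
        for f in range(t - delta + 1, t):
            if f in have:
                return PriorHeatmap(have[f], f)
        for f in range(t - delta - 1, -1, -1):
            if f in have:
                return PriorHeatmap(have[f], f)
    return PriorHeatmap(HeatmapStack.zeros(n_joints, grid_size), None)


class _Head:
    """Two 3x3 convs + a final stride-1 3x3 up-projection, ReLU between."""

    def __init__(self, c_in: int, c_mid: int, c_out: int, rng):
        self.layers = [
            Conv2d(c_in, c_mid, 3, rng=rng),
            ReLU(),
            Conv2d(c_mid, c_mid, 3, rng=rng),
            ReLU(),
            Conv2d(c_mid, c_out, 3, rng=rng, init_scale=0.01),
        ]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, d):
        for l in reversed(self.layers):
            d = l.backward(d)
        return d


class ConditionalPoseNet:
    """Pose trunk + attention and fusion heads over a heatmap prior."""

    def __init__(
        self,
        cond: CondConfig,
        net: PoseNetConfig,
        rng: np.random.Generator | None = None,
        trunk: PoseNet | None = None,
    ):
        cond.validate()
        rng = rng or np.random.default_rng(cond.seed)
        self.cond = cond
        self.net_config = net
        self.trunk = trunk if trunk is not None else PoseNet(net, rng)
        if trunk is not None and trunk.config.backbone != net.backbone:
            raise ValueError("trunk backbone does not match config")
        j = net.n_joints
        f = self.trunk.feature_channels
        ch = cond.head_channels
        self.att = None
        if cond.use_attention:
            c_in = j + (f if cond.use_feature_map else 0)
            self.att = _Head(c_in, ch, j, rng)
        fus_in = 2 * j + (
            f if (cond.use_feature_map and not cond.use_attention) else 0
        )
        self.fus = _Head(fus_in, ch, j, rng)
        self._cache = None

    # -- parameters ---------------------------------------------------
    def params(self):
        ps = self.trunk.params() + self.fus.params()
        if self.att is not None:
            ps += self.att.params()
        return ps

    def param_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state_dict(self) -> dict:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(f"param {i}: shape mismatch")
            p.value = arr.copy()
            p.grad = np.zeros_like(p.value)

    # -- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, prior: np.ndarray) -> np.ndarray:
        """x: (N, 3, H, W); prior: (N, J, H', W') -> fused (N, J, H', W')."""
        hm0, vp = self.trunk.forward(x)
        if prior.shape != hm0.shape:
            raise ValueError(f"prior grid {prior.shape} != heatmap grid {hm0.shape}")
        prior = prior.astype(np.float32)
        cond = self.cond
        if cond.use_attention:
            a_in = (
                np.concatenate([vp, prior], axis=1) if cond.use_feature_map else prior
            )
            wprior = self.att.forward(a_in)
        else:
            wprior = prior
        parts = [hm0, wprior]
        if cond.use_feature_map and not cond.use_attention:
            parts.append(vp)
        out = self.fus.forward(np.concatenate(parts, axis=1))
        self._cache = hm0.shape
        return out

    def backward(self, d_out: np.ndarray) -> None:
        j = self.net_config.n_joints
        f = self.trunk.feature_channels
        cond = self.cond
        d_fin = self.fus.backward(d_out)
        d_hm0 = d_fin[:, :j]
        d_wprior = d_fin[:, j : 2 * j]
        d_v = None
        if cond.use_feature_map and not cond.use_attention:
            d_v = d_fin[:, 2 * j : 2 * j + f]
        if cond.use_attention:
            d_ain = self.att.backward(d_wprior)
            if cond.use_feature_map:
                d_v = d_ain[:, :f] if d_v is None else d_v + d_ain[:, :f]
        self.trunk.backward(np.ascontiguousarray(d_hm0), d_v)


def condpose_forward(
    model: ConditionalPoseNet,
    crop: np.ndarray,
    prior: PriorHeatmap | HeatmapStack,
) -> HeatmapStack:
    """Single-crop conditional prediction (eval path, deterministic)."""
    h, w = model.net_config.input_size
    if crop.shape[:2] != (h, w):
        raise ValueError(f"crop is {crop.shape[:2]}, expected {(h, w)}")
    pv = prior.stack.values if isinstance(prior, PriorHeatmap) else prior.values
    out = model.forward(_crop_to_input(crop)[None], pv[None])
    return HeatmapStack(out[0], np.ones(model.net_config.n_joints, dtype=bool))


def _mean_max_confidence(stack: HeatmapStack) -> float:
    """Average confidence: mean over joints of each channel's max response."""
    return float(stack.values.reshape(stack.values.shape[0], -1).max(axis=1).mean())


def infer_frame(
    model: ConditionalPoseNet,
    crops: list[np.ndarray],
    priors: list[PriorHeatmap],
    config: CondConfig | None = None,
) -> list[tuple[HeatmapStack, int | None]]:
    """Conditional inference for all detections of one frame.

    Every detection is paired with every available prior (plus the zeros
    prior) and the candidate heatmap with the highest average confidence
    is kept; ties go to the lowest prior index, with the zeros prior
    considered last. Returns ``(stack, chosen prior index or None)`` per
    detection.
    """
    config = config or model.cond
    grid = model.net_config.heatmap_size
    j = model.net_config.n_joints
    results: list[tuple[HeatmapStack, int | None]] = []
    for crop in crops:
        candidates: list[tuple[HeatmapStack, int | None]] = []
        for i, p in enumerate(priors):
            candidates.append((condpose_forward(model, crop, p), i))
        if config.include_zero_prior or not priors:
            zp = PriorHeatmap(HeatmapStack.zeros(j, grid), None)
            candidates.append((condpose_forward(model, crop, zp), None))
        scores = np.array([_mean_max_confidence(c[0]) for c in candidates])
        results.append(candidates[int(np.argmax(scores))])
    return results


def train_condpose(
    clips: list[tuple[list[np.ndarray], "ClipAnnotation"]],
    model: ConditionalPoseNet,
    config: CondConfig,
    epochs: int = 10,
    lr: float = 1e-3,
    batch_size: int = 16,
    scale_factor: float = 2.2,
    seed: int | None = None,
) -> tuple[ConditionalPoseNet, list[dict]]:
    """Curriculum finetuning on tracked clips.

    Per sample the prior is the model's own stored prediction at the
    prior frame with probability p(epoch), else the encoded ground-truth
    heatmap there; the loss is the masked MSE on the fused output.
    Returns the model and a per-epoch history of
    ``{"loss", "gt_priors", "pred_priors"}``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    net_cfg = model.net_config
    grid = net_cfg.heatmap_size

    # Precompute crops and ground-truth stacks once (no augmentation here:
    # the prior must stay geometrically consistent with the crop).
    prepared = []  # per clip: list of (t, tid, crop, gt_stack)
    for frames, clip in clips:
        samples = []
        gt_stacks: dict[int, dict[int, HeatmapStack]] = {}
        for img, fr in zip(frames, clip.frames):
            for pose in fr.poses:
                if pose.track_id is None:
                    raise ValueError(
                        f"clip {clip.clip_id}: pose without track_id at frame"
                        f" {fr.frame_index}"
                    )
                crop, geom = make_crop(
                    img, pose.box, scale_factor, net_cfg.input_size
                )
                gt = encode_heatmaps(pose, geom, net_cfg.sigma_hm, grid)
                samples.append((fr.frame_index, pose.track_id, crop, gt))
                gt_stacks.setdefault(pose.track_id, {})[fr.frame_index] = gt
        prepared.append((samples, gt_stacks))

    opt = Adam(model.params(), lr=lr)
    history: list[dict] = []
    for epoch in range(epochs):
        p = curriculum_prob(epoch, config)
        losses = []
        n_gt = n_pred = 0
        buffer: list[tuple[np.ndarray, np.ndarray, HeatmapStack, int, int]] = []

        def flush(pred_store):
            nonlocal losses
            if not buffer:
                return
            xb = np.stack([b[0] for b in buffer])
            pb = np.stack([b[1] for b in buffer])
            out = model.forward(xb, pb)
            opt.zero_grad()
            d = np.zeros_like(out)
            total = 0.0
            for b, (_, _, gt, tid, t) in enumerate(buffer):
                total += masked_mse(out[b], gt)
                d[b] = masked_mse_grad(out[b], gt) / len(buffer)
                pred_store.setdefault(tid, Track(tid)).add(
                    t, None, HeatmapStack(out[b].copy(), gt.mask.copy())
                )
            model.backward(d)
            opt.step()
            losses.append(total / len(buffer))
            buffer.clear()

        for samples, gt_stacks in prepared:
            pred_store: dict[int, Track] = {}
            for t, tid, crop, gt in samples:
                use_pred = rng.random() < p
                if use_pred:
                    track = pred_store.get(tid)
                    n_pred += 1
                else:
                    track = Track(
                        tid,
                        heatmaps={f: s for f, s in gt_stacks[tid].items() if f < t},
                    )
                    n_gt += 1
                prior = select_prior(track, t, config.delta, grid, net_cfg.n_joints)
                buffer.append((_crop_to_input(crop), prior.stack.values, gt, tid, t))
                if len(buffer) >= batch_size:
                    flush(pred_store)
            flush(pred_store)
        history.append(
            {"loss": float(np.mean(losses)), "gt_priors": n_gt, "pred_priors": n_pred}
        )
    return model, history
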