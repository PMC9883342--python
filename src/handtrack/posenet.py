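"""Frame-wise pose estimation network and its training loop.

A small convolutional encoder predicts the J-channel heatmap stack from a
fixed-size hand crop. Two desk-scale backbones are provided (``tiny`` and
``small``); both expose the first conv block's activations as the image
feature map consumed by the conditional attention head. Training follows
the standard top-down recipe: masked MSE against Gaussian target
heatmaps, Adam, random rotations and horizontal flips as augmentation.

A horizontal flip mirrors the crop and heatmap x-axis and (semantically)
swaps handedness; with the per-finger joint ordering no joint index
permutation is needed, as a single hand has no left/right-paired joints.
"""
from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage

from .datamodel import N_JOINTS
from .heatmap import HeatmapStack, masked_mse, masked_mse_grad
from .nn import Adam, AvgPool2d, Conv2d, ReLU, Upsample2d

__all__ = [
    "PoseNetConfig",
    "PoseNet",
    "pose_forward",
    "train_posenet",
    "save_checkpoint",
    "load_checkpoint",
]

_BACKBONES = {
    # name -> (feature channels, encoder channels c2/c3)
    "tiny": (8, 16, 32),
    "small": (12, 24, 48),
}


@dataclass
class PoseNetConfig:
    backbone: str = "tiny"
    input_size: tuple[int, int] = (64, 64)
    heatmap_size: tuple[int, int] = (32, 32)
    n_joints: int = N_JOINTS
    batch_size: int = 16
    epochs: int = 30
    lr: float = 1e-3
    sigma_hm: float = 2.0
    augment: bool = True
    rotation_deg: float = 30.0
    seed: int = 0

    @property
    def stride(self) -> int:
        s = self.input_size[0] // self.heatmap_size[0]
        if (
            self.input_size[0] != s * self.heatmap_size[0]
            or self.input_size[1] // self.heatmap_size[1] != s
            or self.input_size[1] != s * self.heatmap_size[1]
            or s < 2
        ):
            raise ValueError("heatmap size must divide input size by a common stride >= 2")
        return s


class PoseNet:
    """Conv encoder-decoder: crop -> (heatmap stack, early feature map).

    conv1 (stride 2) + ReLU yields the feature map v, average-pooled
    exactly onto the heatmap grid. Two further stride-2 convs and one
    stride-1 conv form a bottleneck whose receptive field spans most of
    the crop (needed to tell fingers apart); two nearest-upsample +
    conv stages with skip connections decode it back to the grid, and
    a final conv regresses the J response channels.
    """

    def __init__(self, config: PoseNetConfig, rng: np.random.Generator | None = None):
        if config.backbone not in _BACKBONES:
            raise ValueError(f"unknown backbone {config.backbone!r}")
        rng = rng or np.random.default_rng(config.seed)
        c_feat, c2, c3 = _BACKBONES[config.backbone]
        self.config = config
        self.feature_channels = c_feat
        self.conv1 = Conv2d(3, c_feat, 3, stride=2, rng=rng)
        self.relu1 = ReLU()
        self.pool = AvgPool2d(config.stride // 2)
        self.conv2 = Conv2d(c_feat, c2, 3, stride=2, rng=rng)
        self.relu2 = ReLU()
        self.conv3 = Conv2d(c2, c3, 3, stride=2, rng=rng)
        self.relu3 = ReLU()
        self.conv4 = Conv2d(c3, c3, 3, rng=rng)
        self.relu4 = ReLU()
        self.up1 = Upsample2d(2)
        self.convd1 = Conv2d(c3 + c2, c2, 3, rng=rng)
        self.relud1 = ReLU()
        self.up2 = Upsample2d(2)
        self.convd2 = Conv2d(c2 + c_feat, c2, 3, rng=rng)
        self.relud2 = ReLU()
        # near-zero head init: response maps start flat instead of driving
        # an initial collapse through the ReLU decoder
        self.head = Conv2d(c2, config.n_joints, 3, rng=rng, init_scale=0.01)

    def params(self):
        return (
            self.conv1.params()
            + self.conv2.params()
            + self.conv3.params()
            + self.conv4.params()
            + self.convd1.params()
            + self.convd2.params()
            + self.head.params()
        )

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """x: (N, 3, H, W) in [0, 1]. Returns (heatmaps, grid-sized features)."""
        v = self.relu1.forward(self.conv1.forward(x))
        vp = self.pool.forward(v)
        e2 = self.relu2.forward(self.conv2.forward(vp))
        b = self.relu3.forward(self.conv3.forward(e2))
        b = self.relu4.forward(self.conv4.forward(b))
        d1 = self.relud1.forward(
            self.convd1.forward(np.concatenate([self.up1.forward(b), e2], axis=1))
        )
        d2 = self.relud2.forward(
            self.convd2.forward(np.concatenate([self.up2.forward(d1), vp], axis=1))
        )
        return self.head.forward(d2), vp

    def backward(self, d_hm: np.ndarray, d_v: np.ndarray | None = None) -> None:
        """Accumulate gradients; ``d_v`` is an extra gradient on the
        grid-sized feature map (used by the conditional head)."""
        c2 = self.conv2.W.value.shape[0]
        c3 = self.conv4.W.value.shape[0]
        d_d2 = self.relud2.backward(self.head.backward(d_hm))
        d_cat2 = self.convd2.backward(d_d2)
        d_d1 = self.up2.backward(np.ascontiguousarray(d_cat2[:, :c2]))
        d_vp_skip = d_cat2[:, c2:]
        d_cat1 = self.convd1.backward(self.relud1.backward(d_d1))
        d_b = self.up1.backward(np.ascontiguousarray(d_cat1[:, :c3]))
        d_e2_skip = d_cat1[:, c3:]
        d_b = self.conv4.backward(self.relu4.backward(d_b))
        d_e2 = self.conv3.backward(self.relu3.backward(d_b)) + d_e2_skip
        d_vp = self.conv2.backward(self.relu2.backward(d_e2)) + d_vp_skip
        if d_v is not None:
            d_vp = d_vp + d_v
        self.conv1.backward(self.relu1.backward(self.pool.backward(d_vp)))

    def state_dict(self) -> dict:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(f"param {i}: shape {arr.shape} != {p.value.shape}")
            p.value = arr.copy()
            p.grad = np.zeros_like(p.value)


def _crop_to_input(crop: np.ndarray) -> np.ndarray:
    x = np.asarray(crop, dtype=np.float32)
    if x.max() > 1.5:
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def pose_forward(model: PoseNet, crop: np.ndarray) -> tuple[HeatmapStack, np.ndarray]:
    """Run a single crop through the network (eval path, deterministic)."""
    h, w = model.config.input_size
    if crop.shape[:2] != (h, w):
        raise ValueError(f"crop is {crop.shape[:2]}, expected {(h, w)}")
    hm, v = model.forward(_crop_to_input(crop)[None])
    stack = HeatmapStack(hm[0], np.ones(model.config.n_joints, dtype=bool))
    return stack, v[0]


def augment_sample(crop, values, rng, rotation_deg: float = 30.0):
    """Random rotation + horizontal flip applied jointly to crop and targets."""
    crop = np.asarray(crop, dtype=np.float32)
    values = np.asarray(values, dtype=np.float32)
    if rng.random() < 0.5:
        crop = crop[:, ::-1].copy()
        values = values[:, :, ::-1].copy()
    if rotation_deg > 0:
        ang = float(rng.uniform(-rotation_deg, rotation_deg))
        crop = ndimage.rotate(crop, ang, axes=(1, 0), reshape=False, order=1, mode="constant")
        values = ndimage.rotate(values, ang, axes=(2, 1), reshape=False, order=1, mode="constant")
    return crop, values


def train_posenet(
    dataset: list[tuple[np.ndarray, HeatmapStack]],
    config: PoseNetConfig,
    model: PoseNet | None = None,
    log_path: str | None = None,
) -> tuple[PoseNet, list[float]]:
    """Train on (crop, target stack) pairs; returns model + per-epoch loss."""
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = PoseNet(config, rng)
    opt = Adam(model.params(), lr=config.lr)
    history: list[float] = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xs, ts, ms = [], [], []
            for i in idx:
                crop, stack = dataset[i]
                x = _crop_to_input(crop)
                vals = stack.values
                if config.augment:
                    x, vals = augment_sample(x, vals, rng, config.rotation_deg)
                xs.append(x)
                ts.append(vals)
                ms.append(stack.mask)
            xb = np.stack(xs)
            hm, _ = model.forward(xb)
            opt.zero_grad()
            dhm = np.zeros_like(hm)
            batch_loss = 0.0
            for b in range(len(idx)):
                gt = HeatmapStack(ts[b], ms[b])
                batch_loss += masked_mse(hm[b], gt)
                dhm[b] = masked_mse_grad(hm[b], gt) / len(idx)
            model.backward(dhm)
            opt.step()
            losses.append(batch_loss / len(idx))
        history.append(float(np.mean(losses)))
    if log_path:
        with open(log_path, "w", newline="", encoding="utf-8") as fh:
            wr = csv.writer(fh)
            wr.writerow(["epoch", "loss"])
            for e, l in enumerate(history):
                wr.writerow([e, f"{l:.8f}"])
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz with a JSON header describing kind + config.
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str | os.PathLike, kind: str, config, state: dict) -> None:
    meta = json.dumps(
        {"version": CHECKPOINT_VERSION, "kind": kind, "config": _cfg_dict(config)},
        sort_keys=True,
    )
    np.savez(path, __meta__=np.array(meta), **state)


def _cfg_dict(config) -> dict:
    d = dict(config) if isinstance(config, dict) else asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def load_checkpoint(path: str | os.PathLike) -> tuple[str, dict, dict]:
    """Returns (kind, config dict, state arrays)."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return meta["kind"], meta["config"], state
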