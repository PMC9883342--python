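"""Crop geometry, Gaussian heatmap encoding/decoding, and the masked MSE.

Top-down pose estimation regresses each hand from a crop around its
bounding box. The crop covers ``scale_factor`` times the box area (2.2 by
default), i.e. each box side is stretched by sqrt(scale_factor), and is
resampled to a fixed input size. Ground truth is a stack of J per-joint
response grids, each an unnormalized 2D Gaussian peaking at 1.0 at the
joint's grid cell; joints that are unannotated or fall outside the crop
are masked out of the loss. Decoding takes each channel's argmax cell
back through the affine map into frame coordinates, with the channel
maximum as the joint confidence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import BoundingBox, HandPose, Keypoint, N_JOINTS

__all__ = [
    "CropGeometry",
    "HeatmapStack",
    "make_crop",
    "encode_heatmaps",
    "decode_heatmaps",
    "pose_from_stack",
    "masked_mse",
    "masked_mse_grad",
]


@dataclass
class CropGeometry:
    """Affine relation between a crop raster and frame coordinates.

    Output pixel center (u, v) maps to frame point
    ``x = x0 + (u + 0.5) * sx - 0.5`` (same for y), where (x0, y0) is the
    crop box origin and sx, sy are crop-box-pixels per output-pixel. With
    scale 1 and matching sizes this is a pure translation.
    """

    source_box: BoundingBox
    scale_factor: float
    crop_box: BoundingBox
    out_size: tuple[int, int]  # (height, width)

    @property
    def sx(self) -> float:
        return self.crop_box.width / self.out_size[1]

    @property
    def sy(self) -> float:
        return self.crop_box.height / self.out_size[0]

    def crop_to_frame(self, pts: np.ndarray) -> np.ndarray:
        """Map (N, 2) crop-pixel (u, v) points to frame (x, y)."""
        pts = np.asarray(pts, dtype=float)
        out = np.empty_like(pts)
        out[..., 0] = self.crop_box.x0 + (pts[..., 0] + 0.5) * self.sx - 0.5
        out[..., 1] = self.crop_box.y0 + (pts[..., 1] + 0.5) * self.sy - 0.5
        return out

    def frame_to_crop(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        out = np.empty_like(pts)
        out[..., 0] = (pts[..., 0] + 0.5 - self.crop_box.x0) / self.sx - 0.5
        out[..., 1] = (pts[..., 1] + 0.5 - self.crop_box.y0) / self.sy - 0.5
        return out

    def grid_to_frame(self, pts: np.ndarray, grid_size: tuple[int, int]) -> np.ndarray:
        """Map heatmap-grid (u, v) points (grid of shape (gh, gw)) to frame."""
        gh, gw = grid_size
        pts = np.asarray(pts, dtype=float)
        crop_pts = np.empty_like(pts)
        crop_pts[..., 0] = (pts[..., 0] + 0.5) * (self.out_size[1] / gw) - 0.5
        crop_pts[..., 1] = (pts[..., 1] + 0.5) * (self.out_size[0] / gh) - 0.5
        return self.crop_to_frame(crop_pts)

    def frame_to_grid(self, pts: np.ndarray, grid_size: tuple[int, int]) -> np.ndarray:
        gh, gw = grid_size
        crop_pts = self.frame_to_crop(pts)
        out = np.empty_like(crop_pts)
        out[..., 0] = (crop_pts[..., 0] + 0.5) * (gw / self.out_size[1]) - 0.5
        out[..., 1] = (crop_pts[..., 1] + 0.5) * (gh / self.out_size[0]) - 0.5
        return out


@dataclass
class HeatmapStack:
    """J response channels on a common grid plus a per-joint loss mask."""

    values: np.ndarray  # (J, H', W') float32
    mask: np.ndarray  # (J,) bool — False channels are excluded from the loss

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"heatmap stack must be (J, H', W'), got {self.values.shape}")
        if self.mask.shape != (self.values.shape[0],):
            raise ValueError("mask must have one entry per channel")

    @property
    def grid_size(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    @classmethod
    def zeros(cls, n_joints: int, grid_size: tuple[int, int]) -> "HeatmapStack":
        return cls(
            np.zeros((n_joints, *grid_size), dtype=np.float32),
            np.ones(n_joints, dtype=bool),
        )


def make_crop(
    image: np.ndarray,
    box: BoundingBox,
    scale_factor: float = 2.2,
    out_size: tuple[int, int] = (256, 256),
) -> tuple[np.ndarray, CropGeometry]:
    """Extract a crop covering ``scale_factor`` times the box area.

    The crop is centered on the box center with each side stretched by
    sqrt(scale_factor), then resampled bilinearly to ``out_size``.
    Regions outside the image are zero-padded.
    """
    box.validate()
    image = np.asarray(image)
    h, w = image.shape[:2]
    if box.x1 <= -0.5 or box.y1 <= -0.5 or box.x0 >= w - 0.5 or box.y0 >= h - 0.5:
        raise ValueError("box lies entirely outside the image")
    s = math.sqrt(scale_factor)
    cx, cy = box.center
    cw, ch = box.width * s, box.height * s
    crop_box = BoundingBox(cx - cw / 2, cy - ch / 2, cx + cw / 2, cy + ch / 2)
    geom = CropGeometry(box, scale_factor, crop_box, out_size)

    oh, ow = out_size
    u, v = np.meshgrid(np.arange(ow), np.arange(oh))
    pts = geom.crop_to_frame(np.stack([u, v], axis=-1).reshape(-1, 2))
    coords = np.stack([pts[:, 1].reshape(oh, ow), pts[:, 0].reshape(oh, ow)])
    if image.ndim == 2:
        crop = ndimage.map_coordinates(image.astype(np.float32), coords, order=1, cval=0.0)
    else:
        crop = np.stack(
            [
                ndimage.map_coordinates(
                    image[..., c].astype(np.float32), coords, order=1, cval=0.0
                )
                for c in range(image.shape[2])
            ],
            axis=-1,
        )
    if np.issubdtype(image.dtype, np.integer):
        crop = np.clip(np.rint(crop), 0, np.iinfo(image.dtype).max).astype(image.dtype)
    return crop, geom


def encode_heatmaps(
    pose: HandPose,
    geom: CropGeometry,
    sigma_hm: float = 2.0,
    grid_size: tuple[int, int] = (64, 64),
) -> HeatmapStack:
    """Encode a pose as per-joint Gaussian response grids.

    Each annotated joint is mapped into the grid and its channel set to an
    unnormalized Gaussian centered on the joint's (quantized) cell, so the
    peak is exactly 1.0 there. Unannotated joints and joints landing
    outside the grid get a zero channel and ``mask=False``.
    """
    if sigma_hm <= 0:
        raise ValueError("sigma_hm must be positive")
    gh, gw = grid_size
    values = np.zeros((N_JOINTS, gh, gw), dtype=np.float32)
    mask = np.zeros(N_JOINTS, dtype=bool)
    grid_pts = geom.frame_to_grid(pose.points(), grid_size)
    rows, cols = np.mgrid[0:gh, 0:gw]
    for j, kp in enumerate(pose.keypoints):
        if not kp.annotated:
            continue
        u, v = grid_pts[j]
        c, r = int(round(u)), int(round(v))
        if not (0 <= c < gw and 0 <= r < gh):
            continue
        mask[j] = True
        values[j] = np.exp(
            -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * sigma_hm**2)
        ).astype(np.float32)
    return HeatmapStack(values, mask)


def decode_heatmaps(
    stack: HeatmapStack, geom: CropGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Decode a stack to frame-coordinate joints and per-joint confidences.

    Per channel the argmax cell (first occurrence in row-major order on
    ties, so an all-zero channel decodes to cell (0, 0)) is mapped back to
    frame coordinates; confidence is the channel maximum.
    """
    vals = stack.values
    if vals.size == 0:
        raise ValueError("empty heatmap stack")
    j = vals.shape[0]
    flat = vals.reshape(j, -1)
    idx = flat.argmax(axis=1)
    conf = flat[np.arange(j), idx]
    gh, gw = stack.grid_size
    rr, cc = np.divmod(idx, gw)
    pts = geom.grid_to_frame(
        np.stack([cc, rr], axis=-1).astype(float), (gh, gw)
    )
    return pts, conf.astype(float)


def pose_from_stack(
    stack: HeatmapStack,
    geom: CropGeometry,
    box: BoundingBox,
    handedness: str = "right",
    track_id: int | None = None,
) -> HandPose:
    """Convenience: decode a predicted stack into a HandPose with confidences."""
    pts, conf = decode_heatmaps(stack, geom)
    kps = [
        Keypoint(float(x), float(y), "visible", float(np.clip(c, 0.0, 1.0)))
        for (x, y), c in zip(pts, conf)
    ]
    return HandPose(keypoints=kps, box=box, handedness=handedness, track_id=track_id)


def _as_stack_pair(pred, gt):
    pv = pred.values if isinstance(pred, HeatmapStack) else np.asarray(pred)
    gv = gt.values
    if pv.shape != gv.shape:
        raise ValueError(f"shape mismatch: {pv.shape} vs {gv.shape}")
    return pv, gv


def masked_mse(pred: "HeatmapStack | np.ndarray", gt: HeatmapStack) -> float:
    """Mean squared error over cells of the masked-in channels.

    Channels with ``gt.mask[j] == False`` contribute neither to the sum
    nor to the denominator; if every channel is masked out the loss is 0.
    """
    pv, gv = _as_stack_pair(pred, gt)
    m = gt.mask
    n = int(m.sum())
    if n == 0:
        return 0.0
    diff = (pv[m] - gv[m]).astype(np.float64)
    return float(np.mean(diff**2))


def masked_mse_grad(pred, gt: HeatmapStack) -> np.ndarray:
    """Gradient of ``masked_mse`` with respect to the predicted values."""
    pv, gv = _as_stack_pair(pred, gt)
    m = gt.mask
    grad = np.zeros_like(pv, dtype=np.float32)
    n = int(m.sum())
    if n == 0:
        return grad
    cells = n * pv.shape[1] * pv.shape[2]
    grad[m] = (2.0 / cells) * (pv[m] - gv[m])
    return grad
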