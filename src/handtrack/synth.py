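"""Synthetic multi-instance articulated-hand video clips with ground truth.

Every downstream stage (pose network training, conditional finetuning,
embedding training, tracking, evaluation) runs on clips from this module,
so no external dataset is needed. Each hand is a planar 21-joint skeleton
(wrist + five 4-joint finger chains) rendered as filled capsules in a
glove-like color over a textured background. Per frame the generator
knows the exact joint positions, so annotations are exact: per-joint
state (``occluded`` under an opaque "instrument" rectangle or a hand
drawn on top, ``unannotated`` off-image), tight boxes, and persistent
track ids.

Default instance statistics emulate a surgical scene: the per-clip hand
count is drawn from a categorical over 1..7 with mean ~2.9 and median 3,
capped at 7. Motion is a bounded random walk per hand (each hand wanders
around a home cell, so hands do not cover each other unless trajectories
are scripted to cross, e.g. via :func:`generate_crossing_clip`); finger
flexion angles evolve as bounded random walks, giving the temporal
coherence that a temporally conditioned model can exploit.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .datamodel import (
    BoundingBox,
    ClipAnnotation,
    FrameAnnotation,
    HandPose,
    Keypoint,
    N_JOINTS,
    save_clip,
    load_clip,
)

__all__ = [
    "SynthConfig",
    "HAND_COUNT_PROBS",
    "hand_keypoints",
    "generate_clip",
    "generate_crossing_clip",
    "generate_dataset",
    "load_dataset",
]

#: P(n hands in a clip), n = 1..7 — mean 2.92, median 3, max 7.
HAND_COUNT_PROBS = (0.16, 0.25, 0.30, 0.16, 0.08, 0.03, 0.02)

_DEFAULT_PALETTE = (
    (205, 180, 160),  # bare skin
    (235, 235, 225),  # white latex
    (90, 170, 110),  # green glove
    (70, 110, 180),  # blue glove
)

# Finger geometry relative to the hand scale: angular offset from the hand
# orientation, wrist-to-base distance, and the three segment lengths.
_FINGER_OFFSET = (-1.15, -0.45, 0.0, 0.40, 0.80)  # radians
_FINGER_PALM = (0.70, 1.00, 1.05, 1.00, 0.88)
_FINGER_SEG = (
    (0.40, 0.32, 0.26),
    (0.44, 0.30, 0.24),
    (0.48, 0.32, 0.25),
    (0.44, 0.30, 0.24),
    (0.38, 0.26, 0.21),
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic clip generator.

    ``n_hands`` may be an int, an inclusive (lo, hi) range, or None to
    sample from :data:`HAND_COUNT_PROBS`. ``occlusion_prob`` is the
    per-hand probability of being assigned a moving instrument occluder.
    """

    n_frames: int = 16
    image_size: tuple[int, int] = (128, 176)  # (H, W)
    n_hands: int | tuple[int, int] | None = None
    max_hands: int = 7
    motion_speed: float = 2.0  # pixels/frame
    flexion_rate: float = 0.06  # radians/frame
    occlusion_prob: float = 0.15
    glove_palette: tuple = _DEFAULT_PALETTE
    hand_scale: tuple[float, float] = (6.0, 8.5)
    fps: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.occlusion_prob <= 1.0):
            raise ValueError("occlusion_prob must be in [0, 1]")
        h, w = self.image_size
        if h < 8 * self.hand_scale[1] / 2 or w < 8 * self.hand_scale[1] / 2:
            raise ValueError("image size too small for the skeleton extent")


def hand_keypoints(
    wrist: tuple[float, float],
    theta: float,
    scale: float,
    flexion: np.ndarray,
    curl_sign: float = 1.0,
) -> np.ndarray:
    """Joint positions (21, 2) of a planar hand skeleton.

    ``theta`` is the palm orientation (middle-finger direction), ``scale``
    the base bone length in pixels, ``flexion`` five per-finger curl
    angles in radians (each chain segment rotates by an extra increment).
    """
    pts = np.empty((N_JOINTS, 2), dtype=float)
    pts[0] = wrist
    for f in range(5):
        base_dir = theta + _FINGER_OFFSET[f]
        d = np.array([math.cos(base_dir), math.sin(base_dir)])
        p = np.asarray(wrist, dtype=float) + _FINGER_PALM[f] * scale * d
        pts[1 + 4 * f] = p
        ang = base_dir
        for i in range(3):
            ang += curl_sign * flexion[f]
            step = np.array([math.cos(ang), math.sin(ang)])
            p = p + _FINGER_SEG[f][i] * scale * step
            pts[2 + 4 * f + i] = p
    return pts


def _hand_radius(scale: float) -> float:
    return scale * (max(_FINGER_PALM) + sum(max(s) for s in zip(*_FINGER_SEG)))


def _silhouette(pts: np.ndarray, scale: float, shape) -> np.ndarray:
    """Boolean mask of the rendered hand (capsules along every bone)."""
    h, w = shape
    r_f = max(1.4, 0.20 * scale)
    r_p = max(2.0, 0.34 * scale)
    bones = [(0, 1 + 4 * f, r_p) for f in range(5)]
    for f in range(5):
        for i in range(3):
            bones.append((1 + 4 * f + i, 2 + 4 * f + i, r_f))
    pad = r_p + 1.5
    x0 = max(0, int(pts[:, 0].min() - pad))
    x1 = min(w, int(pts[:, 0].max() + pad) + 1)
    y0 = max(0, int(pts[:, 1].min() - pad))
    y1 = min(h, int(pts[:, 1].max() + pad) + 1)
    mask = np.zeros(shape, dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sub = np.zeros(yy.shape, dtype=bool)
    for a, b, r in bones:
        pa, pb = pts[a], pts[b]
        ab = pb - pa
        denom = float(ab @ ab) or 1.0
        t = np.clip(((xx - pa[0]) * ab[0] + (yy - pa[1]) * ab[1]) / denom, 0.0, 1.0)
        dx = xx - (pa[0] + t * ab[0])
        dy = yy - (pa[1] + t * ab[1])
        sub |= dx * dx + dy * dy <= r * r
    mask[y0:y1, x0:x1] = sub
    return mask


def _background(rng: np.random.Generator, shape) -> np.ndarray:
    h, w = shape
    coarse = rng.uniform(55.0, 125.0, size=(6, 8, 3))
    zoom = (h / 6, w / 8, 1)
    bg = ndimage.zoom(coarse, zoom, order=1, mode="nearest")
    return bg[:h, :w].astype(np.float32)


@dataclass
class _HandState:
    track_id: int
    home: np.ndarray
    wander: np.ndarray  # max |offset| from home, per axis
    pos: np.ndarray
    vel: np.ndarray
    theta: float
    scale: float
    flexion: np.ndarray
    curl_sign: float
    color: np.ndarray
    handedness: str


def _init_hands(cfg: SynthConfig, rng: np.random.Generator) -> list[_HandState]:
    if cfg.n_hands is None:
        n = int(rng.choice(np.arange(1, 8), p=HAND_COUNT_PROBS))
    elif isinstance(cfg.n_hands, tuple):
        n = int(rng.integers(cfg.n_hands[0], cfg.n_hands[1] + 1))
    else:
        n = int(cfg.n_hands)
    n = min(n, cfg.max_hands)
    h, w = cfg.image_size
    rows = 1 if n == 1 else 2
    cols = int(math.ceil(n / rows))
    cell_h, cell_w = h / rows, w / cols
    order = rng.permutation(rows * cols)[:n]
    hands = []
    for i, cell in enumerate(sorted(int(c) for c in order)):
        r, c = divmod(cell, cols)
        home = np.array([(c + 0.5) * cell_w, (r + 0.5) * cell_h])
        scale = float(rng.uniform(*cfg.hand_scale))
        rad = _hand_radius(scale)
        wander = np.maximum(
            [cell_w / 2 - rad - 2.0, cell_h / 2 - rad - 2.0], 1.5
        )
        color = np.asarray(
            cfg.glove_palette[int(rng.integers(len(cfg.glove_palette)))], dtype=float
        )
        color = np.clip(color + rng.uniform(-12, 12, size=3), 0, 255)
        hands.append(
            _HandState(
                track_id=i,
                home=home,
                wander=wander,
                pos=home + rng.uniform(-0.5, 0.5, size=2) * wander,
                vel=rng.uniform(-1, 1, size=2) * cfg.motion_speed * 0.5,
                theta=float(rng.uniform(0, 2 * math.pi)),
                scale=scale,
                flexion=rng.uniform(0.08, 0.45, size=5),
                curl_sign=1.0,
                color=color,
                handedness=("left", "right")[int(rng.integers(2))],
            )
        )
    return hands


def _advance(hand: _HandState, cfg: SynthConfig, rng: np.random.Generator) -> None:
    hand.vel = np.clip(
        hand.vel + rng.normal(0.0, 0.5 * cfg.motion_speed, size=2),
        -cfg.motion_speed,
        cfg.motion_speed,
    )
    hand.pos = hand.pos + hand.vel
    # reflect into the wander box around home
    for ax in range(2):
        lo, hi = hand.home[ax] - hand.wander[ax], hand.home[ax] + hand.wander[ax]
        if hand.pos[ax] < lo:
            hand.pos[ax] = 2 * lo - hand.pos[ax]
            hand.vel[ax] = -hand.vel[ax]
        elif hand.pos[ax] > hi:
            hand.pos[ax] = 2 * hi - hand.pos[ax]
            hand.vel[ax] = -hand.vel[ax]
        hand.pos[ax] = float(np.clip(hand.pos[ax], lo, hi))
    if cfg.motion_speed > 0:
        hand.theta += float(rng.normal(0.0, 0.04))
    if cfg.flexion_rate > 0:
        hand.flexion = np.clip(
            hand.flexion + rng.normal(0.0, cfg.flexion_rate, size=5), 0.05, 0.55
        )


@dataclass
class _Occluder:
    center: np.ndarray
    size: np.ndarray  # (w, h)
    axis: np.ndarray  # oscillation direction (unit)
    amplitude: float
    omega: float
    phase: float

    def rect(self, t: int) -> tuple[float, float, float, float]:
        c = self.center + self.axis * self.amplitude * math.sin(
            self.omega * t + self.phase
        )
        return (
            c[0] - self.size[0] / 2,
            c[1] - self.size[1] / 2,
            c[0] + self.size[0] / 2,
            c[1] + self.size[1] / 2,
        )


def _init_occluders(
    hands: list[_HandState], cfg: SynthConfig, rng: np.random.Generator
) -> list[_Occluder]:
    occs = []
    for hand in hands:
        if rng.random() >= cfg.occlusion_prob:
            continue
        ang = rng.uniform(0, 2 * math.pi)
        occs.append(
            _Occluder(
                center=hand.home.copy(),
                size=np.array(
                    [rng.uniform(2.0, 3.2) * hand.scale, rng.uniform(0.8, 1.4) * hand.scale]
                ),
                axis=np.array([math.cos(ang), math.sin(ang)]),
                amplitude=float(rng.uniform(1.0, 2.5) * hand.scale),
                omega=float(rng.uniform(0.3, 0.9)),
                phase=float(rng.uniform(0, 2 * math.pi)),
            )
        )
    return occs


def _render_and_annotate(
    hands: list[_HandState],
    occluders: list[_Occluder],
    bg: np.ndarray,
    t: int,
    cfg: SynthConfig,
) -> tuple[np.ndarray, list[HandPose]]:
    h, w = cfg.image_size
    canvas = bg.copy()
    all_pts = [
        hand_keypoints(hd.pos, hd.theta, hd.scale, hd.flexion, hd.curl_sign)
        for hd in hands
    ]
    sils = [_silhouette(p, hd.scale, (h, w)) for p, hd in zip(all_pts, hands)]
    for sil, hd in zip(sils, hands):
        canvas[sil] = hd.color
    rects = [o.rect(t) for o in occluders]
    for rx0, ry0, rx1, ry1 in rects:
        ix0, iy0 = max(0, int(rx0)), max(0, int(ry0))
        ix1, iy1 = min(w, int(rx1) + 1), min(h, int(ry1) + 1)
        if ix1 > ix0 and iy1 > iy0:
            canvas[iy0:iy1, ix0:ix1] = (45.0, 45.0, 52.0)

    poses = []
    for i, (hd, pts) in enumerate(zip(hands, all_pts)):
        on_image = (
            (pts[:, 0] >= 0) & (pts[:, 0] <= w - 1) & (pts[:, 1] >= 0) & (pts[:, 1] <= h - 1)
        )
        if not on_image.any():
            continue
        states = []
        for j in range(N_JOINTS):
            if not on_image[j]:
                states.append("unannotated")
                continue
            x, y = pts[j]
            occ = any(
                r[0] <= x <= r[2] and r[1] <= y <= r[3] for r in rects
            )
            if not occ:
                # covered by a hand drawn on top?
                px, py = int(round(x)), int(round(y))
                occ = any(sils[k][py, px] for k in range(i + 1, len(sils)))
            states.append("occluded" if occ else "visible")
        ann = np.array([s != "unannotated" for s in states])
        pad = max(2.0, 0.34 * hd.scale) + 1.0
        bx0 = max(0.0, float(pts[ann, 0].min()) - pad)
        by0 = max(0.0, float(pts[ann, 1].min()) - pad)
        bx1 = min(float(w), float(pts[ann, 0].max()) + pad)
        by1 = min(float(h), float(pts[ann, 1].max()) + pad)
        poses.append(
            HandPose(
                keypoints=[
                    Keypoint(float(pts[j, 0]), float(pts[j, 1]), states[j])
                    for j in range(N_JOINTS)
                ],
                box=BoundingBox(bx0, by0, bx1, by1),
                handedness=hd.handedness,
                track_id=hd.track_id,
            )
        )
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8), poses


def generate_clip(
    config: SynthConfig, clip_id: str = "clip_000"
) -> tuple[list[np.ndarray], ClipAnnotation]:
    """Render one clip; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    hands = _init_hands(config, rng)
    occluders = _init_occluders(hands, config, rng)
    bg = _background(rng, config.image_size)
    # one advance-draw per frame; draws consumed in fixed order
    frames, anns = [], []
    for t in range(config.n_frames):
        if t > 0:
            for hd in hands:
                if config.motion_speed > 0 or config.flexion_rate > 0:
                    _advance(hd, config, rng)
        img, poses = _render_and_annotate(hands, occluders, bg, t, config)
        frames.append(img)
        anns.append(
            FrameAnnotation(
                frame_index=t, image_path=f"frames/{t:06d}.png", poses=poses
            )
        )
    clip = ClipAnnotation(clip_id=clip_id, fps=config.fps, frames=anns)
    clip.validate()
    return frames, clip


def generate_crossing_clip(
    seed: int = 0,
    n_frames: int = 9,
    image_size: tuple[int, int] = (96, 160),
    scale: float = 7.0,
) -> tuple[list[np.ndarray], ClipAnnotation]:
    """Two hands with distinct flexion whose wrists swap sides mid-clip.

    Their boxes overlap heavily at the crossing, which defeats pure box
    overlap matching, while the finger configurations stay distinct —
    the stress case for pose-embedding association.
    """
    rng = np.random.default_rng(seed)
    h, w = image_size
    cfg = SynthConfig(
        n_frames=n_frames, image_size=image_size, n_hands=2, occlusion_prob=0.0,
        seed=seed,
    )
    y = h / 2
    xa0, xa1 = 0.22 * w, 0.78 * w
    flex = [np.full(5, 0.10), np.full(5, 0.50)]
    thetas = [0.3, 2.6]
    colors = [np.array((230, 230, 220.0)), np.array((95, 170, 115.0))]
    bg = _background(rng, image_size)
    frames, anns = [], []
    for t in range(n_frames):
        a = t / max(1, n_frames - 1)
        hands = []
        for i in range(2):
            x = (1 - a) * (xa0 if i == 0 else xa1) + a * (xa1 if i == 0 else xa0)
            yy = y + (4.0 if i == 0 else -4.0) * math.sin(math.pi * a)
            hands.append(
                _HandState(
                    track_id=i, home=np.array([x, yy]), wander=np.ones(2),
                    pos=np.array([x, yy]), vel=np.zeros(2), theta=thetas[i],
                    scale=scale, flexion=flex[i], curl_sign=1.0,
                    color=colors[i], handedness="right",
                )
            )
        img, poses = _render_and_annotate(hands, [], bg, t, cfg)
        frames.append(img)
        anns.append(
            FrameAnnotation(frame_index=t, image_path=f"frames/{t:06d}.png", poses=poses)
        )
    clip = ClipAnnotation(clip_id=f"crossing_{seed}", fps=8.0, frames=anns)
    clip.validate()
    return frames, clip


def generate_dataset(
    n_clips: int,
    config: SynthConfig,
    out_dir: str | os.PathLike,
    overwrite: bool = False,
    val_fraction: float = 0.2,
) -> dict:
    """Write ``n_clips`` independent clips plus a manifest to ``out_dir``.

    Clip i uses seed ``(config.seed + i) mod 2^31``. The manifest lists
    each clip's directory, annotation file and train/val split (the last
    ``val_fraction`` of clips are validation).
    """
    import imageio.v3 as iio

    out_dir = os.fspath(out_dir)
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise FileExistsError(f"{out_dir} exists and is not empty (use overwrite)")
    os.makedirs(out_dir, exist_ok=True)
    n_val = int(round(n_clips * val_fraction))
    entries = []
    for i in range(n_clips):
        cid = f"clip_{i:03d}"
        cfg_i = replace(config, seed=(config.seed + i) % (2**31))
        frames, clip = generate_clip(cfg_i, clip_id=cid)
        cdir = os.path.join(out_dir, cid)
        os.makedirs(os.path.join(cdir, "frames"), exist_ok=True)
        for t, img in enumerate(frames):
            iio.imwrite(os.path.join(cdir, f"frames/{t:06d}.png"), img)
        save_clip(clip, os.path.join(cdir, "annotation.json"))
        entries.append(
            {
                "clip_id": cid,
                "dir": cid,
                "annotation": f"{cid}/annotation.json",
                "split": "val" if i >= n_clips - n_val else "train",
                "seed": cfg_i.seed,
            }
        )
    manifest = {"n_clips": n_clips, "clips": entries}
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return manifest


def load_dataset(
    out_dir: str | os.PathLike, split: str | None = None
) -> list[tuple[list[np.ndarray], ClipAnnotation]]:
    """Load clips (frame arrays + annotations) written by generate_dataset."""
    import imageio.v3 as iio

    out_dir = os.fspath(out_dir)
    with open(os.path.join(out_dir, "manifest.json"), "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    out = []
    for e in manifest["clips"]:
        if split is not None and e["split"] != split:
            continue
        clip = load_clip(os.path.join(out_dir, e["annotation"]))
        cdir = os.path.join(out_dir, e["dir"])
        frames = [
            np.asarray(iio.imread(os.path.join(cdir, fr.image_path)))
            for fr in clip.frames
        ]
        out.append((frames, clip))
    return out
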