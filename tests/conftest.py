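"""Shared fixtures and pose-construction helpers."""
from __future__ import annotations

import math

import numpy as np
import pytest

from handtrack.datamodel import (
    BoundingBox,
    ClipAnnotation,
    FrameAnnotation,
    HandPose,
    Keypoint,
    N_JOINTS,
)


def make_pose(
    cx: float = 50.0,
    cy: float = 50.0,
    radius: float = 20.0,
    track_id: int | None = None,
    confidence: float | None = None,
    states: list[str] | None = None,
    handedness: str = "right",
) -> HandPose:
    """A deterministic radial 21-joint pose centered on (cx, cy)."""
    kps = []
    for j in range(N_JOINTS):
        ang = 2 * math.pi * j / N_JOINTS
        r = radius * (0.2 + 0.8 * (j % 5) / 4)
        kps.append(
            Keypoint(
                cx + r * math.cos(ang),
                cy + r * math.sin(ang),
                states[j] if states else "visible",
                confidence,
            )
        )
    box = BoundingBox(cx - radius - 2, cy - radius - 2, cx + radius + 2, cy + radius + 2)
    return HandPose(keypoints=kps, box=box, handedness=handedness, track_id=track_id)


def shift_pose(pose: HandPose, dx: float, dy: float, track_id=...) -> HandPose:
    kps = [
        Keypoint(k.x + dx, k.y + dy, k.state, k.confidence) for k in pose.keypoints
    ]
    b = pose.box
    return HandPose(
        keypoints=kps,
        box=BoundingBox(b.x0 + dx, b.y0 + dy, b.x1 + dx, b.y1 + dy),
        handedness=pose.handedness,
        track_id=pose.track_id if track_id is ... else track_id,
    )


def make_clip(frame_poses: list[list[HandPose]], clip_id: str = "clip") -> ClipAnnotation:
    clip = ClipAnnotation(
        clip_id=clip_id,
        fps=8.0,
        frames=[
            FrameAnnotation(t, f"frames/{t:06d}.png", poses)
            for t, poses in enumerate(frame_poses)
        ],
    )
    clip.validate()
    return clip


@pytest.fixture(scope="session")
def tiny_net_config():
    from handtrack.posenet import PoseNetConfig

    return PoseNetConfig(backbone="tiny", epochs=2, augment=False, seed=0)


@pytest.fixture(scope="session")
def small_synth_clip():
    from handtrack.synth import SynthConfig, generate_clip

    cfg = SynthConfig(n_frames=6, n_hands=2, occlusion_prob=0.0, seed=5)
    return generate_clip(cfg, "fixture_clip")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_scenario(rng: np.random.Generator):
    """A randomized multi-track tracking scenario for metric cross-checks.

    Ground truth: up to 5 tracks over up to 20 frames with intermittent
    presence and occasional unannotated joints. Predictions: jittered
    copies (some joints pushed past the PCK gate), dropped poses, spurious
    poses, and occasional identity swaps.
    """
    n_tracks = int(rng.integers(1, 6))
    n_frames = int(rng.integers(2, 21))
    centers = rng.uniform(60, 400, size=(n_tracks, 2))
    gt_frames, pred_frames = [], []
    id_map = {t: t for t in range(n_tracks)}
    for _t in range(n_frames):
        gts, preds = [], []
        if rng.random() < 0.15:  # occasional global id shuffle
            perm = rng.permutation(n_tracks)
            id_map = {t: int(n_tracks + perm[t]) for t in range(n_tracks)}
        for tr in range(n_tracks):
            if rng.random() < 0.2:  # track absent this frame
                continue
            centers[tr] += rng.uniform(-4, 4, size=2)
            cx, cy = centers[tr]
            states = [
                "unannotated" if rng.random() < 0.1 else "visible"
                for _ in range(N_JOINTS)
            ]
            gt = make_pose(cx, cy, radius=18, track_id=tr, states=states)
            gts.append(gt)
            if rng.random() < 0.15:  # missed detection
                continue
            pred = shift_pose(gt, 0, 0, track_id=id_map[tr])
            for k in pred.keypoints:
                k.confidence = float(rng.uniform(0.3, 1.0))
                k.state = "visible"
                k.x += float(rng.normal(0, 2.0))
                k.y += float(rng.normal(0, 2.0))
                if rng.random() < 0.15:  # push past the gate
                    k.x += 60.0
            preds.append(pred)
        if rng.random() < 0.1:  # spurious detection
            sp = make_pose(*rng.uniform(500, 700, 2), track_id=90 + int(rng.integers(10)))
            for k in sp.keypoints:
                k.confidence = float(rng.uniform(0.1, 0.9))
            preds.append(sp)
        gt_frames.append(gts)
        pred_frames.append(preds)
    cid = f"scenario_{int(rng.integers(1 << 30))}"
    return [make_clip(gt_frames, cid)], [make_clip(pred_frames, cid)]
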