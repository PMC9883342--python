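"""End-to-end orchestration: train, track, evaluate, reproduce.

Ties the stages together the way the method is meant to run: generate
(or load) clips, train the frame-wise pose network, finetune the
conditional model on clip sequences, run detect-then-track inference
with one of the matching strategies, and score detection (PCK, mAP) and
tracking (MOTA, MOTP) quality. Also hosts the seeded synthetic benchmark
comparing the conditional model against the frame-independent baseline,
and the small end-to-end demo used to check bit-for-bit reproducibility.
"""
from __future__ import annotations

import copy
import csv
import hashlib
import json
import os
from dataclasses import asdict, replace

import numpy as np

from .conditional import (
    CondConfig,
    ConditionalPoseNet,
    PriorHeatmap,
    Track,
    condpose_forward,
    infer_frame,
    select_prior,
    train_condpose,
)
from .datamodel import ClipAnnotation, FrameAnnotation, save_clip
from .heatmap import HeatmapStack, encode_heatmaps, make_crop, pose_from_stack
from .metrics import EvalConfig, evaluate_all, pck_match
from .posenet import PoseNet, PoseNetConfig, pose_forward, train_posenet
from .synth import SynthConfig, generate_clip
from .tracking import GCNTrainConfig, PoseGCN, TrackerState, step_tracker, train_gcn

__all__ = [
    "build_pose_dataset",
    "mean_pck",
    "track_clip",
    "run_benchmark",
    "run_demo",
    "write_report_files",
]


def build_pose_dataset(clips_data, net_cfg: PoseNetConfig, scale_factor: float = 2.2):
    """(crop, target stack) pairs from every annotated hand in the clips."""
    out = []
    for frames, clip in clips_data:
        for img, fr in zip(frames, clip.frames):
            for pose in fr.poses:
                crop, geom = make_crop(img, pose.box, scale_factor, net_cfg.input_size)
                stack = encode_heatmaps(pose, geom, net_cfg.sigma_hm, net_cfg.heatmap_size)
                out.append((crop, stack))
    return out


def mean_pck(
    model,
    clips_data,
    eval_cfg: EvalConfig | None = None,
    cond_cfg: CondConfig | None = None,
    prior_mode: str = "none",
    scale_factor: float = 2.2,
) -> float:
    """Mean per-pose PCK over all annotated hands, using ground-truth boxes.

    ``prior_mode``: "none" runs the frame-independent network; "true"
    conditions on the encoded ground-truth heatmap selected from the
    track's earlier frames; "zeros" conditions on the zeros prior.
    """
    eval_cfg = eval_cfg or EvalConfig()
    net_cfg = model.net_config if isinstance(model, ConditionalPoseNet) else model.config
    grid = net_cfg.heatmap_size
    scores = []
    for frames, clip in clips_data:
        gt_tracks: dict[int, Track] = {}
        for img, fr in zip(frames, clip.frames):
            t = fr.frame_index
            for pose in fr.poses:
                crop, geom = make_crop(img, pose.box, scale_factor, net_cfg.input_size)
                if prior_mode == "none":
                    stack, _ = pose_forward(model, crop)
                else:
                    if prior_mode == "true" and pose.track_id is not None:
                        prior = select_prior(
                            gt_tracks.get(pose.track_id), t, cond_cfg.delta, grid
                        )
                    else:
                        prior = PriorHeatmap(HeatmapStack.zeros(net_cfg.n_joints, grid))
                    stack = condpose_forward(model, crop, prior)
                pred = pose_from_stack(stack, geom, pose.box)
                scores.append(pck_match(pred, pose, eval_cfg)[1])
                if pose.track_id is not None:
                    gt = encode_heatmaps(pose, geom, net_cfg.sigma_hm, grid)
                    gt_tracks.setdefault(pose.track_id, Track(pose.track_id)).add(
                        t, pose, gt
                    )
    return float(np.mean(scores)) if scores else float("nan")


def track_clip(
    model,
    frames,
    clip: ClipAnnotation,
    boxes_by_frame: dict[int, list] | None = None,
    strategy: str = "iou",
    gcn: PoseGCN | None = None,
    cond_cfg: CondConfig | None = None,
    scale_factor: float = 2.2,
    tracker_kwargs: dict | None = None,
) -> ClipAnnotation:
    """Run detect-then-track inference over one clip.

    Boxes come from ``boxes_by_frame`` (an external detector) or, when
    None, from the clip's annotated poses ("perfect detections"). With a
    conditional model each detection is paired with every live track's
    stored heatmap plus the zeros prior; the most confident candidate is
    kept. Returns a prediction clip with track ids and confidences.
    """
    conditional = isinstance(model, ConditionalPoseNet)
    net_cfg = model.net_config if conditional else model.config
    state = TrackerState(strategy=strategy, **(tracker_kwargs or {}))
    out_frames = []
    for img, fr in zip(frames, clip.frames):
        if boxes_by_frame is not None:
            boxes = [b for b, _s in boxes_by_frame.get(fr.frame_index, [])]
        else:
            boxes = [p.box for p in fr.poses]
        crops, geoms = [], []
        for box in boxes:
            crop, geom = make_crop(img, box, scale_factor, net_cfg.input_size)
            crops.append(crop)
            geoms.append(geom)
        if conditional:
            _ids, hmaps = state.live_priors()
            priors = [PriorHeatmap(h, 0) for h in hmaps if h is not None]
            results = infer_frame(model, crops, priors, cond_cfg or model.cond)
            stacks = [r[0] for r in results]
        else:
            stacks = [pose_forward(model, c)[0] for c in crops]
        poses = [
            pose_from_stack(s, g, b) for s, g, b in zip(stacks, geoms, boxes)
        ]
        ids = step_tracker(state, poses, heatmaps=stacks, gcn=gcn)
        for pose, tid in zip(poses, ids):
            pose.track_id = tid
        out_frames.append(
            FrameAnnotation(fr.frame_index, fr.image_path, poses)
        )
    pred = ClipAnnotation(clip.clip_id, clip.fps, out_frames)
    pred.validate()
    return pred


# ---------------------------------------------------------------------------
# Seeded benchmark: conditional model vs frame-independent baseline
# ---------------------------------------------------------------------------


def _make_clips(n_clips, synth_cfg: SynthConfig):
    return [
        generate_clip(
            replace(synth_cfg, seed=(synth_cfg.seed + i) % 2**31), f"clip_{i:03d}"
        )
        for i in range(n_clips)
    ]


def run_benchmark(
    seed: int = 0,
    n_clips: int = 30,
    occlusion_prob: float = 0.3,
    n_frames: int = 10,
    baseline_epochs: int = 8,
    cond_epochs: int = 12,
    val_clips: int = 6,
    strategy: str = "iou",
) -> dict:
    """Train baseline and conditional models on one synthetic dataset and
    score both on held-out clips: mean PCK@0.2 (ground-truth boxes; the
    conditional model conditioned on true priors) and MOTA/mAP from the
    full tracking pipeline (the conditional model selecting priors from
    its own tracks). Returns a flat dict of scores.
    """
    synth_cfg = SynthConfig(
        seed=seed % 2**31, occlusion_prob=occlusion_prob, n_frames=n_frames
    )
    clips = _make_clips(n_clips, synth_cfg)
    train, val = clips[: n_clips - val_clips], clips[n_clips - val_clips :]

    net_cfg = PoseNetConfig(
        backbone="tiny", epochs=baseline_epochs, augment=False, seed=seed % 2**31
    )
    dataset = build_pose_dataset(train, net_cfg)
    baseline, _hist = train_posenet(dataset, net_cfg)

    cond_cfg = CondConfig(seed=seed % 2**31)
    trunk = PoseNet(net_cfg, np.random.default_rng(seed % 2**31))
    trunk.load_state_dict(baseline.state_dict())
    cond_model = ConditionalPoseNet(
        cond_cfg, net_cfg, np.random.default_rng((seed + 1) % 2**31), trunk=trunk
    )
    cond_model, _chist = train_condpose(
        train, cond_model, cond_cfg, epochs=cond_epochs, lr=5e-4
    )

    eval_cfg = EvalConfig()
    out = {
        "pck_baseline": mean_pck(baseline, val, eval_cfg),
        "pck_cond_true_prior": mean_pck(
            cond_model, val, eval_cfg, cond_cfg, prior_mode="true"
        ),
        "pck_cond_zero_prior": mean_pck(
            cond_model, val, eval_cfg, cond_cfg, prior_mode="zeros"
        ),
    }
    gt_val = [c for _f, c in val]
    preds_b = [track_clip(baseline, f, c, strategy=strategy) for f, c in val]
    preds_c = [
        track_clip(cond_model, f, c, strategy=strategy, cond_cfg=cond_cfg)
        for f, c in val
    ]
    rep_b, _ = evaluate_all(gt_val, preds_b, eval_cfg)
    rep_c, _ = evaluate_all(gt_val, preds_c, eval_cfg)
    out.update(
        {
            "mota_baseline": rep_b.mota_total,
            "mota_cond": rep_c.mota_total,
            "map_baseline": rep_b.map,
            "map_cond": rep_c.map,
            "motp_cond": rep_c.motp,
            "n_val_poses": sum(c.n_poses() for c in gt_val),
        }
    )
    return out


def run_gcn_benchmark(
    seed: int = 0, n_clips: int = 20, epochs: int = 20, n_frames: int = 12
) -> tuple[dict, PoseGCN]:
    """Train the pose-embedding GCN on synthetic clips.

    Returns the held-out pair classification accuracy and the trained
    embedder (so callers can reuse it for association experiments).
    """
    synth_cfg = SynthConfig(seed=seed % 2**31, n_frames=n_frames, n_hands=(2, 4))
    clips = [c for _f, c in _make_clips(n_clips, synth_cfg)]
    cfg = GCNTrainConfig(epochs=epochs, seed=seed % 2**31)
    model, history = train_gcn(clips, cfg)
    return {"gcn_pair_accuracy": history[-1], "n_epochs": epochs}, model


# ---------------------------------------------------------------------------
# Demo: small end-to-end run writing reproducible artifacts
# ---------------------------------------------------------------------------


def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_report_files(report, counts, out_dir: str) -> None:
    with open(os.path.join(out_dir, "metrics.json"), "w", encoding="utf-8") as fh:
        payload = report.to_dict()
        payload["counts"] = counts.totals
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")
    with open(
        os.path.join(out_dir, "metrics_per_joint.csv"), "w", newline="", encoding="utf-8"
    ) as fh:
        from .datamodel import JOINT_NAMES

        wr = csv.writer(fh)
        wr.writerow(["metric"] + JOINT_NAMES + ["total"])
        if report.ap is not None:
            wr.writerow(
                ["AP"] + [f"{v:.2f}" for v in report.ap] + [f"{report.map:.2f}"]
            )
        wr.writerow(
            ["MOTA"]
            + [("" if np.isnan(v) else f"{v:.2f}") for v in report.mota_joint]
            + [f"{report.mota_total:.2f}"]
        )


def run_demo(out_dir: str, seed: int = 0, strategy: str = "iou") -> dict:
    """Tiny end-to-end pipeline; every artifact is byte-stable given the seed."""
    os.makedirs(out_dir, exist_ok=True)
    seed = seed % 2**31
    n_clips, n_val = 6, 2
    synth_cfg = SynthConfig(seed=seed, n_frames=8, n_hands=(2, 3), occlusion_prob=0.2)
    clips = _make_clips(n_clips, synth_cfg)
    train, val = clips[: n_clips - n_val], clips[n_clips - n_val :]

    net_cfg = PoseNetConfig(backbone="tiny", epochs=3, augment=False, seed=seed)
    baseline, _ = train_posenet(build_pose_dataset(train, net_cfg), net_cfg)
    cond_cfg = CondConfig(seed=seed)
    trunk = PoseNet(net_cfg, np.random.default_rng(seed))
    trunk.load_state_dict(baseline.state_dict())
    cond_model = ConditionalPoseNet(
        cond_cfg, net_cfg, np.random.default_rng((seed + 1) % 2**31), trunk=trunk
    )
    cond_model, _ = train_condpose(train, cond_model, cond_cfg, epochs=2, lr=5e-4)

    preds = []
    for f, c in val:
        pred = track_clip(cond_model, f, c, strategy=strategy, cond_cfg=cond_cfg)
        save_clip(pred, os.path.join(out_dir, f"pred_{c.clip_id}.json"))
        preds.append(pred)
    gt_val = [c for _f, c in val]
    for _f, c in val:
        save_clip(c, os.path.join(out_dir, f"gt_{c.clip_id}.json"))
    report, counts = evaluate_all(gt_val, preds, EvalConfig())
    write_report_files(report, counts, out_dir)

    from . import __version__

    manifest = {
        "seed": seed,
        "strategy": strategy,
        "versions": {"handtrack": __version__, "numpy": np.__version__},
        "synth": asdict(synth_cfg),
        "posenet": asdict(net_cfg),
        "cond": asdict(cond_cfg),
    }
    manifest["config_hash"] = _config_hash(manifest)
    with open(os.path.join(out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return {
        "mota": report.mota_total,
        "map": report.map,
        "files": sorted(os.listdir(out_dir)),
    }
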