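"""Detection and tracking evaluation: PCK, per-joint AP / mAP, MOTA / MOTP.

Detection quality follows the keypoint-AP protocol used in pose
tracking benchmarks: predictions are matched to ground-truth poses per
frame by highest PCK (Probability of Correct Keypoints: a joint is
correct when its distance to the annotated joint is below
``sigma * norm(gt box)``, sigma = 0.2 by default), predicted keypoints
are ranked dataset-wide by confidence per joint, and AP is the area
under the interpolated precision-recall curve; mAP averages over joints.

Tracking quality is Multiple Object Tracking Accuracy at joint level:

    MOTA = 1 - sum_t(FN_t + FP_t + IDSW_t) / sum_t G_t

with false negatives (annotated joints missed or mislocalized), false
positives (predicted joints with no correct real joint), identity
switches (a ground-truth track matched to a different predicted id than
before; counted once per annotated joint of the switching pose) and G
the number of annotated ground-truth joints. MOTA lies in (-inf, 100]
on the percent scale. MOTP here scores localization of the correctly
matched joints as ``100 * mean(1 - d / threshold)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ClipAnnotation, HandPose, N_JOINTS, JOINT_NAMES

__all__ = [
    "EvalConfig",
    "MotaCounts",
    "MetricsReport",
    "pck_match",
    "assign_poses",
    "evaluate_map",
    "evaluate_mota",
    "evaluate_all",
]


@dataclass
class EvalConfig:
    sigma: float = 0.2
    normalization: str = "max_side"  # or "diagonal"

    def validate(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.normalization not in ("max_side", "diagonal"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def norm_length(self, pose: HandPose) -> float:
        box = pose.box
        if self.normalization == "max_side":
            return max(box.width, box.height)
        return box.diagonal


@dataclass
class MotaCounts:
    """Per-joint FN / FP / IDSW / G accumulators."""

    fn: np.ndarray = field(default_factory=lambda: np.zeros(N_JOINTS, dtype=int))
    fp: np.ndarray = field(default_factory=lambda: np.zeros(N_JOINTS, dtype=int))
    idsw: np.ndarray = field(default_factory=lambda: np.zeros(N_JOINTS, dtype=int))
    g: np.ndarray = field(default_factory=lambda: np.zeros(N_JOINTS, dtype=int))

    @property
    def totals(self) -> dict:
        return {
            "FN": int(self.fn.sum()),
            "FP": int(self.fp.sum()),
            "IDSW": int(self.idsw.sum()),
            "G": int(self.g.sum()),
        }


@dataclass
class MetricsReport:
    """All scores on the 0-100 scale; per-joint arrays have length 21."""

    ap: np.ndarray | None = None
    map: float | None = None
    mota_joint: np.ndarray | None = None
    mota_total: float | None = None
    motp: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else [None if np.isnan(v) else float(v) for v in a]

        return {
            "ap_per_joint": arr(self.ap),
            "mAP": self.map,
            "mota_per_joint": arr(self.mota_joint),
            "MOTA": self.mota_total,
            "MOTP": self.motp,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "joint_names": JOINT_NAMES,
        }


def pck_match(
    pred: HandPose, gt: HandPose, cfg: EvalConfig | None = None
) -> tuple[np.ndarray, float]:
    """Per-joint correctness flags and the pose's PCK score in [0, 1].

    Joint j is correct iff the ground-truth joint is annotated and the
    prediction lies within ``sigma * norm(gt box)`` of it; PCK is the
    fraction of annotated joints that are correct.
    """
    cfg = cfg or EvalConfig()
    cfg.validate()
    ann = gt.annotated_mask()
    n_ann = int(ann.sum())
    if n_ann == 0:
        return np.zeros(N_JOINTS, dtype=bool), 0.0
    thr = cfg.sigma * cfg.norm_length(gt)
    d = np.linalg.norm(pred.points() - gt.points(), axis=1)
    correct = ann & (d <= thr)
    return correct, float(correct.sum() / n_ann)


def assign_poses(
    preds: list[HandPose], gts: list[HandPose], cfg: EvalConfig | None = None
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy one-to-one matching of predictions to ground truth by PCK.

    Pairs with PCK 0 are never matched. Returns (matched (pred_i, gt_i)
    pairs, unmatched pred indices, unmatched gt indices).
    """
    cfg = cfg or EvalConfig()
    scores = np.zeros((len(preds), len(gts)))
    for i, p in enumerate(preds):
        for k, g in enumerate(gts):
            scores[i, k] = pck_match(p, g, cfg)[1]
    pairs: list[tuple[int, int]] = []
    used_p: set[int] = set()
    used_g: set[int] = set()
    if scores.size:
        for flat in np.argsort(scores, axis=None)[::-1]:
            i, k = divmod(int(flat), len(gts))
            if scores[i, k] <= 0.0:
                break
            if i in used_p or k in used_g:
                continue
            pairs.append((i, k))
            used_p.add(i)
            used_g.add(k)
    return (
        pairs,
        [i for i in range(len(preds)) if i not in used_p],
        [k for k in range(len(gts)) if k not in used_g],
    )


def _paired_frames(gts: list[ClipAnnotation], preds: list[ClipAnnotation]):
    """Yield (clip_id, gt frame poses, pred frame poses) aligned by index."""
    pred_by_id = {c.clip_id: c for c in preds}
    for gclip in sorted(gts, key=lambda c: c.clip_id):
        if gclip.clip_id not in pred_by_id:
            raise ValueError(f"predictions missing clip {gclip.clip_id!r}")
        pclip = pred_by_id[gclip.clip_id]
        pframes = {fr.frame_index: fr.poses for fr in pclip.frames}
        for fr in gclip.frames:
            yield gclip.clip_id, fr.poses, pframes.get(fr.frame_index, [])


def evaluate_map(
    preds: list[ClipAnnotation],
    gts: list[ClipAnnotation],
    cfg: EvalConfig | None = None,
) -> tuple[np.ndarray, float]:
    """Per-joint AP and mAP (x100) over a whole dataset.

    Requires confidences on every predicted keypoint. Predicted joints
    of unmatched poses count as false positives at every joint; matched
    joints whose ground-truth counterpart is unannotated are ignored.
    Joints never annotated in the ground truth are excluded from the
    mAP mean.
    """
    cfg = cfg or EvalConfig()
    cfg.validate()
    entries: list[list[tuple[float, bool]]] = [[] for _ in range(N_JOINTS)]
    npos = np.zeros(N_JOINTS, dtype=int)

    def conf(kp):
        if kp.confidence is None:
            raise ValueError("predicted keypoint without confidence")
        return kp.confidence

    for _cid, gposes, pposes in _paired_frames(gts, preds):
        for g in gposes:
            npos += g.annotated_mask()
        pairs, un_p, _un_g = assign_poses(pposes, gposes, cfg)
        for pi, gi in pairs:
            correct, _ = pck_match(pposes[pi], gposes[gi], cfg)
            ann = gposes[gi].annotated_mask()
            for j in range(N_JOINTS):
                if ann[j]:
                    entries[j].append((conf(pposes[pi].keypoints[j]), bool(correct[j])))
        for pi in un_p:
            for j in range(N_JOINTS):
                entries[j].append((conf(pposes[pi].keypoints[j]), False))

    ap = np.full(N_JOINTS, np.nan)
    for j in range(N_JOINTS):
        if npos[j] == 0:
            continue
        if not entries[j]:
            ap[j] = 0.0
            continue
        order = sorted(range(len(entries[j])), key=lambda i: -entries[j][i][0])
        tps = np.array([entries[j][i][1] for i in order], dtype=float)
        tp_cum = np.cumsum(tps)
        fp_cum = np.cumsum(1.0 - tps)
        recall = tp_cum / npos[j]
        precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
        # interpolated precision envelope (monotone from the right)
        penv = np.maximum.accumulate(precision[::-1])[::-1]
        prev_r = 0.0
        area = 0.0
        for i in range(len(order)):
            if tps[i]:
                area += (recall[i] - prev_r) * penv[i]
                prev_r = recall[i]
        ap[j] = 100.0 * area
    valid = ~np.isnan(ap)
    m_ap = float(ap[valid].mean()) if valid.any() else 0.0
    return ap, m_ap


def evaluate_mota(
    gts: list[ClipAnnotation],
    preds: list[ClipAnnotation],
    cfg: EvalConfig | None = None,
) -> tuple[MetricsReport, MotaCounts]:
    """Joint-level MOTA / MOTP / precision / recall / F1 over clips.

    Both sides must carry track ids. Per frame, poses are matched by
    highest PCK; an annotated ground-truth joint that is unmatched or
    mislocalized is a FN, predicted joints of unmatched poses or
    mislocalized matched joints are FPs, and a ground-truth track whose
    matched predicted id changes adds one IDSW per annotated joint.
    """
    cfg = cfg or EvalConfig()
    cfg.validate()
    counts = MotaCounts()
    tp = np.zeros(N_JOINTS, dtype=int)
    motp_sum = 0.0
    motp_n = 0
    last_pred_id: dict[tuple[str, int], int] = {}

    for cid, gposes, pposes in _paired_frames(gts, preds):
        for pose in gposes + pposes:
            if pose.track_id is None:
                raise ValueError(f"clip {cid!r}: pose without track id")
        for g in gposes:
            counts.g += g.annotated_mask()
        pairs, un_p, un_g = assign_poses(pposes, gposes, cfg)
        for pi, gi in pairs:
            gpose, ppose = gposes[gi], pposes[pi]
            correct, _ = pck_match(ppose, gpose, cfg)
            ann = gpose.annotated_mask()
            counts.fn += ann & ~correct
            counts.fp += ann & ~correct
            tp += correct
            thr = cfg.sigma * cfg.norm_length(gpose)
            d = np.linalg.norm(ppose.points() - gpose.points(), axis=1)
            motp_sum += float(np.sum(1.0 - d[correct] / thr))
            motp_n += int(correct.sum())
            key = (cid, gpose.track_id)
            prev = last_pred_id.get(key)
            if prev is not None and prev != ppose.track_id:
                counts.idsw += ann
            last_pred_id[key] = ppose.track_id
        for gi in un_g:
            counts.fn += gposes[gi].annotated_mask()
        for pi in un_p:
            counts.fp += np.ones(N_JOINTS, dtype=int)

    report = MetricsReport()
    with np.errstate(divide="ignore", invalid="ignore"):
        per = 100.0 * (
            1.0 - (counts.fn + counts.fp + counts.idsw) / counts.g.astype(float)
        )
    per[counts.g == 0] = np.nan
    report.mota_joint = per
    g_tot = counts.g.sum()
    err_tot = counts.fn.sum() + counts.fp.sum() + counts.idsw.sum()
    report.mota_total = 100.0 * (1.0 - err_tot / g_tot) if g_tot else float("nan")
    report.motp = 100.0 * motp_sum / motp_n if motp_n else float("nan")
    tp_tot, fp_tot, fn_tot = int(tp.sum()), int(counts.fp.sum()), int(counts.fn.sum())
    report.precision = 100.0 * tp_tot / (tp_tot + fp_tot) if tp_tot + fp_tot else 0.0
    report.recall = 100.0 * tp_tot / (tp_tot + fn_tot) if tp_tot + fn_tot else 0.0
    report.f1 = (
        2 * report.precision * report.recall / (report.precision + report.recall)
        if report.precision + report.recall
        else 0.0
    )
    return report, counts


def evaluate_all(
    gts: list[ClipAnnotation],
    preds: list[ClipAnnotation],
    cfg: EvalConfig | None = None,
) -> tuple[MetricsReport, MotaCounts]:
    """Detection + tracking metrics in one report."""
    cfg = cfg or EvalConfig()
    report, counts = evaluate_mota(gts, preds, cfg)
    report.ap, report.map = evaluate_map(preds, gts, cfg)
    return report, counts
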