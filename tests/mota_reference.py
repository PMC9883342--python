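"""Independent event-level reference implementation of joint-level MOTA.

Written as a literal, loop-based transcription of the accounting rules —
per frame, match predicted poses to ground truth by highest PCK
(one-to-one, greedy, zero-PCK pairs never matched), then count per
annotated joint: a miss (FN) when the pose is unmatched or the joint
falls outside the gate, a false positive (FP) for every joint of an
unmatched predicted pose and every gated-out matched joint, and an
identity switch (IDSW) per annotated joint when a ground-truth track's
matched predicted id changes. Kept deliberately separate from the
package's vectorized implementation so the two can be compared exactly.
"""
from __future__ import annotations

import math


def _pck(pred_pose, gt_pose, sigma):
    """(per-joint correct dict, pck score) using the max-box-side gate."""
    norm = max(gt_pose.box.x1 - gt_pose.box.x0, gt_pose.box.y1 - gt_pose.box.y0)
    gate = sigma * norm
    correct = {}
    n_ann = 0
    n_ok = 0
    for j in range(21):
        g = gt_pose.keypoints[j]
        if g.state == "unannotated":
            continue
        n_ann += 1
        p = pred_pose.keypoints[j]
        ok = math.hypot(p.x - g.x, p.y - g.y) <= gate
        correct[j] = ok
        n_ok += int(ok)
    return correct, (n_ok / n_ann if n_ann else 0.0)


def _match_frame(pred_poses, gt_poses, sigma):
    scored = []
    for pi, p in enumerate(pred_poses):
        for gi, g in enumerate(gt_poses):
            _, s = _pck(p, g, sigma)
            if s > 0:
                scored.append((s, pi, gi))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p, used_g, pairs = set(), set(), []
    for _s, pi, gi in scored:
        if pi in used_p or gi in used_g:
            continue
        pairs.append((pi, gi))
        used_p.add(pi)
        used_g.add(gi)
    return pairs


def reference_counts(gt_clips, pred_clips, sigma=0.2):
    """Total FN / FP / IDSW / G over a list of clip annotation pairs."""
    fn = fp = idsw = g_total = 0
    preds_by_id = {c.clip_id: c for c in pred_clips}
    for gclip in gt_clips:
        pclip = preds_by_id[gclip.clip_id]
        pred_frames = {fr.frame_index: fr.poses for fr in pclip.frames}
        last_id = {}
        for fr in gclip.frames:
            gt_poses = fr.poses
            pred_poses = pred_frames.get(fr.frame_index, [])
            for g in gt_poses:
                for kp in g.keypoints:
                    if kp.state != "unannotated":
                        g_total += 1
            pairs = _match_frame(pred_poses, gt_poses, sigma)
            matched_p = {pi for pi, _ in pairs}
            matched_g = {gi for _, gi in pairs}
            for pi, gi in pairs:
                correct, _ = _pck(pred_poses[pi], gt_poses[gi], sigma)
                for _j, ok in correct.items():
                    if not ok:
                        fn += 1
                        fp += 1
                gtid = gt_poses[gi].track_id
                ptid = pred_poses[pi].track_id
                if gtid in last_id and last_id[gtid] != ptid:
                    idsw += len(correct)
                last_id[gtid] = ptid
            for gi, g in enumerate(gt_poses):
                if gi not in matched_g:
                    fn += sum(
                        1 for kp in g.keypoints if kp.state != "unannotated"
                    )
            for pi in range(len(pred_poses)):
                if pi not in matched_p:
                    fp += 21
    return {"FN": fn, "FP": fp, "IDSW": idsw, "G": g_total}
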