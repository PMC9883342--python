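"""Detect-then-track data association for multi-hand pose tracking.

Given the hands of frame t-1 and the detections of frame t, a similarity
function scores every pair and a greedy matcher (Hungarian optional)
links them: box IoU, negative mean keypoint L2 distance, or negative
distance between contrastive pose embeddings from a graph convolutional
network over the hand skeleton. Unmatched detections open new track ids;
tracks unseen for longer than ``max_age`` frames expire and their ids are
never reused.

The pose embedding normalizes keypoints to [0, 1] within the hand's box
(optionally with an annotation-state third channel), passes them through
two graph-convolution layers over the skeleton adjacency, pools over
joints, and projects to 128 dimensions. Training minimizes a contrastive
loss over pose pairs sampled as: positive (same track, adjacent frames)
with probability 0.5, negative from the same video 0.4, negative from a
different video 0.1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datamodel import BoundingBox, ClipAnnotation, HandPose, N_JOINTS, SKELETON_EDGES
from .heatmap import HeatmapStack
from .nn import Adam, Linear, Param

__all__ = [
    "iou",
    "mean_keypoint_distance",
    "NO_MATCH",
    "normalize_pose",
    "PoseGCN",
    "embed_pose",
    "contrastive_loss",
    "sample_training_pair",
    "PairSampler",
    "train_gcn",
    "TrackerState",
    "step_tracker",
    "greedy_assign",
]

#: Sentinel similarity for undefined comparisons (treated as non-match).
NO_MATCH = -math.inf

PAIR_PROBS = (0.5, 0.4, 0.1)  # positive, same-video negative, cross-video negative


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def mean_keypoint_distance(a: HandPose, b: HandPose) -> float:
    """Mean L2 distance over joints annotated in both poses.

    Returns ``inf`` when no joint is annotated in both (treated as a
    non-match by the tracker).
    """
    ma = a.annotated_mask() & b.annotated_mask()
    if not ma.any():
        return math.inf
    d = np.linalg.norm(a.points()[ma] - b.points()[ma], axis=1)
    return float(d.mean())


def normalize_pose(pose: HandPose, channels: int = 3) -> np.ndarray:
    """Box-normalized keypoint matrix X of shape (21, C), C in {2, 3}.

    Coordinates are mapped to [0, 1] relative to the pose's box and
    clamped. The optional third channel carries the annotation state:
    0 for unannotated, 1 for annotated ground truth, or the keypoint
    confidence in [0, 1] for predictions.
    """
    if channels not in (2, 3):
        raise ValueError("channels must be 2 or 3")
    box = pose.box
    if box.width <= 0 or box.height <= 0:
        raise ValueError("zero-area box")
    pts = pose.points()
    x = np.empty((N_JOINTS, channels), dtype=np.float32)
    x[:, 0] = np.clip((pts[:, 0] - box.x0) / box.width, 0.0, 1.0)
    x[:, 1] = np.clip((pts[:, 1] - box.y0) / box.height, 0.0, 1.0)
    if channels == 3:
        for j, kp in enumerate(pose.keypoints):
            if not kp.annotated:
                x[j, 2] = 0.0
            elif kp.confidence is not None:
                x[j, 2] = kp.confidence
            else:
                x[j, 2] = 1.0
    return x


def _skeleton_adjacency() -> np.ndarray:
    """Symmetric-normalized adjacency with self-loops over the 21 joints."""
    a = np.eye(N_JOINTS)
    for i, j in SKELETON_EDGES:
        a[i, j] = a[j, i] = 1.0
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return (a * dinv[None, :] * dinv[:, None]).astype(np.float32)


class PoseGCN:
    """Two graph-conv layers + mean pool + linear map to a 128-d embedding."""

    def __init__(
        self,
        channels: int = 3,
        hidden: tuple[int, int] = (32, 64),
        embed_dim: int = 128,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.channels = channels
        self.A = _skeleton_adjacency()
        self.g1 = Linear(channels, hidden[0], rng=rng)
        self.g2 = Linear(hidden[0], hidden[1], rng=rng)
        self.out = Linear(hidden[1], embed_dim, rng=rng)
        self._cache = None

    def params(self):
        return self.g1.params() + self.g2.params() + self.out.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, J, C) -> embeddings (N, D)."""
        x = np.asarray(x, dtype=np.float32)
        n, j, c = x.shape
        ax = np.einsum("jk,nkc->njc", self.A, x)
        h1 = self.g1.forward(ax.reshape(n * j, c)).reshape(n, j, -1)
        r1 = np.maximum(h1, 0.0)
        ar1 = np.einsum("jk,nkc->njc", self.A, r1)
        h2 = self.g2.forward(ar1.reshape(n * j, -1)).reshape(n, j, -1)
        r2 = np.maximum(h2, 0.0)
        pooled = r2.mean(axis=1)
        emb = self.out.forward(pooled)
        self._cache = (n, j, h1 > 0, h2 > 0)
        return emb

    def backward(self, demb: np.ndarray) -> None:
        n, j, m1, m2 = self._cache
        dpooled = self.out.backward(demb)
        dr2 = np.repeat(dpooled[:, None, :], j, axis=1) / j
        dh2 = np.where(m2, dr2, 0.0)
        dar1 = self.g2.backward(dh2.reshape(n * j, -1)).reshape(n, j, -1)
        dr1 = np.einsum("kj,nkc->njc", self.A, dar1)
        dh1 = np.where(m1, dr1, 0.0)
        self.g1.backward(dh1.reshape(n * j, -1))

    def state_dict(self) -> dict:
        return {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.asarray(state[f"p{i}"], dtype=np.float32).copy()
            p.grad = np.zeros_like(p.value)


def embed_pose(model: PoseGCN, x: np.ndarray) -> np.ndarray:
    """Embed one normalized pose matrix (J, C) to a 128-d vector."""
    x = np.asarray(x, dtype=np.float32)
    if x.shape != (N_JOINTS, model.channels):
        raise ValueError(f"expected ({N_JOINTS}, {model.channels}), got {x.shape}")
    return model.forward(x[None])[0]


def contrastive_loss(
    e1: np.ndarray,
    e2: np.ndarray,
    y: int,
    m: float = 1.0,
    mode: str = "as_printed",
) -> float:
    """Contrastive embedding loss for a pose pair (y=1 same hand, 0 different).

    ``as_printed`` (default) uses the squared L2 distance d and the form
    0.5 * (y*d + (1-y)*max(0, (m-d)^2)), whose negative branch drives d
    toward the margin m. ``standard`` is the textbook hinge form
    0.5 * (y*d^2 + (1-y)*max(0, m-d)^2) with d the L2 distance.
    """
    if m <= 0:
        raise ValueError("margin must be positive")
    diff = np.asarray(e1, dtype=float) - np.asarray(e2, dtype=float)
    if mode == "as_printed":
        d = float(diff @ diff)
        return 0.5 * (y * d + (1 - y) * max(0.0, (m - d) ** 2))
    if mode == "standard":
        d = float(np.linalg.norm(diff))
        return 0.5 * (y * d * d + (1 - y) * max(0.0, m - d) ** 2)
    raise ValueError(f"unknown mode {mode!r}")


def _contrastive_grad(e1, e2, y, m, mode):
    """d(loss)/d(e1); the gradient wrt e2 is its negation."""
    diff = e1 - e2
    if mode == "as_printed":
        d = float(diff @ diff)
        dl_dd = 0.5 * y - (1 - y) * (m - d)
        return (2.0 * dl_dd) * diff
    d = float(np.linalg.norm(diff))
    if y == 1:
        return diff
    if d >= m or d == 0.0:
        return np.zeros_like(diff)
    return -(m - d) / d * diff


# ---------------------------------------------------------------------------
# Pair sampling for embedding training
# ---------------------------------------------------------------------------


class PairSampler:
    """Samples (pose, pose, label) pairs from tracked clips.

    Categories: positive (same track id, adjacent annotated frames) with
    probability 0.5; negative from the same video 0.4; negative from a
    different video 0.1. Impossible draws (e.g. a single-clip dataset for
    the cross-video category) are redrawn and counted in ``redraws``.
    """

    def __init__(self, clips: list[ClipAnnotation]):
        self.redraws = 0
        # positives: (clip idx, pose a, pose b)
        self.positives: list[tuple[int, HandPose, HandPose]] = []
        # all poses grouped by clip
        self.by_clip: list[list[HandPose]] = []
        for ci, clip in enumerate(clips):
            poses = []
            by_track: dict[int, list[tuple[int, HandPose]]] = {}
            order = {fr.frame_index: k for k, fr in enumerate(clip.frames)}
            for fr in clip.frames:
                for p in fr.poses:
                    poses.append(p)
                    if p.track_id is not None:
                        by_track.setdefault(p.track_id, []).append(
                            (order[fr.frame_index], p)
                        )
            self.by_clip.append(poses)
            for entries in by_track.values():
                entries.sort(key=lambda e: e[0])
                for (fa, pa), (fb, pb) in zip(entries, entries[1:]):
                    if fb - fa == 1:
                        self.positives.append((ci, pa, pb))
        self.multi_track_clips = [
            ci
            for ci, clip in enumerate(clips)
            if any(
                len({p.track_id for p in fr.poses if p.track_id is not None}) >= 2
                for fr in clip.frames
            )
        ]

    def sample(self, rng: np.random.Generator):
        """Returns (X-source pose 1, pose 2, y, category index)."""
        for _ in range(64):
            cat = int(rng.choice(3, p=PAIR_PROBS))
            if cat == 0:
                if not self.positives:
                    self.redraws += 1
                    continue
                ci, pa, pb = self.positives[int(rng.integers(len(self.positives)))]
                return pa, pb, 1, 0
            if cat == 1:
                if not self.multi_track_clips:
                    self.redraws += 1
                    continue
                ci = self.multi_track_clips[
                    int(rng.integers(len(self.multi_track_clips)))
                ]
                poses = self.by_clip[ci]
                for _ in range(32):
                    pa = poses[int(rng.integers(len(poses)))]
                    pb = poses[int(rng.integers(len(poses)))]
                    if pa.track_id != pb.track_id:
                        return pa, pb, 0, 1
                self.redraws += 1
                continue
            if len(self.by_clip) < 2:
                self.redraws += 1
                continue
            ca, cb = rng.choice(len(self.by_clip), size=2, replace=False)
            pa = self.by_clip[ca][int(rng.integers(len(self.by_clip[ca])))]
            pb = self.by_clip[cb][int(rng.integers(len(self.by_clip[cb])))]
            return pa, pb, 0, 2
        raise RuntimeError("pair sampling failed: dataset too degenerate")


def sample_training_pair(clips: list[ClipAnnotation], rng: np.random.Generator):
    """One-shot convenience wrapper around :class:`PairSampler`."""
    return PairSampler(clips).sample(rng)


@dataclass
class GCNTrainConfig:
    batch_size: int = 32
    epochs: int = 60
    lr: float = 1e-3
    margin: float = 1.0
    mode: str = "as_printed"
    channels: int = 3
    steps_per_epoch: int = 100
    n_val_pairs: int = 200
    val_fraction: float = 0.2
    seed: int = 0


def _pair_accuracy(model, pairs, margin, mode):
    # decision rule: same hand iff Euclidean embedding distance < margin/2
    # (the as_printed training objective uses the squared distance internally)
    correct = 0
    for xa, xb, y in pairs:
        ea, eb = model.forward(np.stack([xa, xb]))
        d = float(np.linalg.norm(ea - eb))
        pred = 1 if d < margin / 2 else 0
        correct += int(pred == y)
    return correct / len(pairs)


def train_gcn(
    clips: list[ClipAnnotation],
    config: GCNTrainConfig | None = None,
) -> tuple[PoseGCN, list[float]]:
    """Train the pose-embedding GCN with the contrastive objective.

    The last ``val_fraction`` of clips are held out; per epoch the pair
    classification accuracy (same hand iff embedding distance < m/2) on a
    fixed set of held-out pairs is recorded and returned as the history.
    """
    config = config or GCNTrainConfig()
    if not clips:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    n_val = max(0, int(round(len(clips) * config.val_fraction)))
    train_clips = clips[: len(clips) - n_val] if n_val else clips
    val_clips = clips[len(clips) - n_val :] if n_val else clips
    sampler = PairSampler(train_clips)
    val_sampler = PairSampler(val_clips)
    val_pairs = []
    for _ in range(config.n_val_pairs):
        pa, pb, y, _c = val_sampler.sample(rng)
        val_pairs.append(
            (
                normalize_pose(pa, config.channels),
                normalize_pose(pb, config.channels),
                y,
            )
        )
    model = PoseGCN(channels=config.channels, seed=config.seed)
    opt = Adam(model.params(), lr=config.lr)
    history = []
    for _epoch in range(config.epochs):
        for _step in range(config.steps_per_epoch):
            xs, ys = [], []
            for _ in range(config.batch_size):
                pa, pb, y, _c = sampler.sample(rng)
                xs.append(normalize_pose(pa, config.channels))
                xs.append(normalize_pose(pb, config.channels))
                ys.append(y)
            emb = model.forward(np.stack(xs))
            demb = np.zeros_like(emb)
            for k, y in enumerate(ys):
                e1, e2 = emb[2 * k], emb[2 * k + 1]
                g = _contrastive_grad(
                    e1.astype(float), e2.astype(float), y, config.margin, config.mode
                ) / len(ys)
                demb[2 * k] += g
                demb[2 * k + 1] -= g
            opt.zero_grad()
            model.backward(demb)
            opt.step()
        history.append(_pair_accuracy(model, val_pairs, config.margin, config.mode))
    return model, history


# ---------------------------------------------------------------------------
# Tracker
# ---------------------------------------------------------------------------


@dataclass
class _TrackEntry:
    pose: HandPose
    heatmap: HeatmapStack | None
    missed: int = 0


@dataclass
class TrackerState:
    """Live tracks and association settings for one clip."""

    strategy: str = "iou"
    iou_threshold: float = 0.2
    l2_box_diag_factor: float = 0.5
    embed_threshold: float = 0.5  # margin / 2 under the default margin 1.0
    max_age: int = 1
    use_hungarian: bool = False
    next_id: int = 0
    tracks: dict[int, _TrackEntry] = field(default_factory=dict)

    def live_priors(self):
        """(track ids, their last heatmaps) for conditional inference."""
        ids = sorted(self.tracks)
        return ids, [self.tracks[i].heatmap for i in ids]


def greedy_assign(sim: np.ndarray, min_sim: np.ndarray) -> list[tuple[int, int]]:
    """Greedy descending-similarity one-to-one assignment.

    ``sim``: (n_tracks, n_dets); ``min_sim`` per-pair acceptance floor.
    """
    pairs = []
    n, m = sim.shape
    order = np.argsort(sim, axis=None)[::-1]
    used_r, used_c = set(), set()
    for flat in order:
        r, c = divmod(int(flat), m)
        if r in used_r or c in used_c:
            continue
        if not np.isfinite(sim[r, c]) or sim[r, c] < min_sim[r, c]:
            continue
        pairs.append((r, c))
        used_r.add(r)
        used_c.add(c)
    return pairs


def _hungarian_assign(sim: np.ndarray, min_sim: np.ndarray):
    from scipy.optimize import linear_sum_assignment

    cost = np.where(np.isfinite(sim), -sim, 1e9)
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(r), int(c))
        for r, c in zip(rows, cols)
        if np.isfinite(sim[r, c]) and sim[r, c] >= min_sim[r, c]
    ]


def step_tracker(
    state: TrackerState,
    detections: list[HandPose],
    heatmaps: list[HeatmapStack] | None = None,
    gcn: PoseGCN | None = None,
) -> list[int]:
    """Associate one frame's detections with the live tracks.

    Returns the assigned track id per detection (new ids for unmatched
    detections). Updates ``state`` in place: matched tracks are
    refreshed, unmatched tracks age and expire after ``max_age`` missed
    frames.
    """
    if state.strategy == "gcn" and gcn is None:
        raise ValueError("strategy 'gcn' requires an embedding model")
    ids = sorted(state.tracks)
    n, m = len(ids), len(detections)
    sim = np.full((n, m), NO_MATCH)
    floor = np.full((n, m), NO_MATCH)
    if n and m:
        if state.strategy == "gcn":
            det_emb = [embed_pose(gcn, normalize_pose(d, gcn.channels)) for d in detections]
            trk_emb = [
                embed_pose(gcn, normalize_pose(state.tracks[i].pose, gcn.channels))
                for i in ids
            ]
        for r, tid in enumerate(ids):
            tr = state.tracks[tid]
            for c, det in enumerate(detections):
                if state.strategy == "iou":
                    sim[r, c] = iou(tr.pose.box, det.box)
                    floor[r, c] = state.iou_threshold
                elif state.strategy == "l2":
                    d = mean_keypoint_distance(tr.pose, det)
                    sim[r, c] = -d if math.isfinite(d) else NO_MATCH
                    floor[r, c] = -state.l2_box_diag_factor * tr.pose.box.diagonal
                elif state.strategy == "gcn":
                    sim[r, c] = -float(np.linalg.norm(trk_emb[r] - det_emb[c]))
                    floor[r, c] = -state.embed_threshold
                else:
                    raise ValueError(f"unknown strategy {state.strategy!r}")
    assign = _hungarian_assign(sim, floor) if state.use_hungarian else greedy_assign(sim, floor)

    det_ids = [-1] * m
    matched_tracks = set()
    for r, c in assign:
        tid = ids[r]
        det_ids[c] = tid
        matched_tracks.add(tid)
        state.tracks[tid].pose = detections[c]
        state.tracks[tid].heatmap = heatmaps[c] if heatmaps else None
        state.tracks[tid].missed = 0
    for c in range(m):
        if det_ids[c] == -1:
            tid = state.next_id
            state.next_id += 1
            det_ids[c] = tid
            state.tracks[tid] = _TrackEntry(
                detections[c], heatmaps[c] if heatmaps else None
            )
    for tid in ids:
        if tid not in matched_tracks:
            state.tracks[tid].missed += 1
            if state.tracks[tid].missed >= state.max_age:
                del state.tracks[tid]
    return det_ids
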