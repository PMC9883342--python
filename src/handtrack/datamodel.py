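"""Domain types and annotation I/O for multi-instance hand pose clips.

A clip is a sequence of frames, each carrying zero or more hand instances.
Every hand is described by a bounding box, a handedness label, an optional
track id that is persistent within the clip, and 21 keypoints laid out as
one wrist joint followed by five four-joint finger chains. Each joint has
an annotation state: ``visible`` (on screen), ``occluded`` (obstructed but
its position can still be estimated) or ``unannotated`` (the position
cannot be inferred or lies off-screen). Unannotated joints are ignored by
every loss and metric.

Annotations and predictions share one JSON dialect (see ``save_clip``);
predicted keypoints additionally carry a confidence in [0, 1].
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

__all__ = [
    "N_JOINTS",
    "JOINT_NAMES",
    "SKELETON_EDGES",
    "STATES",
    "SchemaError",
    "Keypoint",
    "BoundingBox",
    "HandPose",
    "FrameAnnotation",
    "ClipAnnotation",
    "load_clip",
    "save_clip",
    "clip_to_dict",
    "clip_from_dict",
    "load_detections",
]

N_JOINTS = 21

#: Joint order: wrist first, then thumb/index/middle/ring/pinky, each
#: base-to-tip. This matches the conventional 21-joint hand skeleton.
_FINGERS = ("thumb", "index", "middle", "ring", "pinky")
JOINT_NAMES = ["wrist"] + [f"{f}{i}" for f in _FINGERS for i in range(1, 5)]

#: Bone list (parent, child) over the 21-joint skeleton.
SKELETON_EDGES = tuple(
    (0, 1 + 4 * f) for f in range(5)
) + tuple(
    (1 + 4 * f + i, 2 + 4 * f + i) for f in range(5) for i in range(3)
)

STATES = ("visible", "occluded", "unannotated")
_HANDEDNESS = ("left", "right")


class SchemaError(ValueError):
    """Raised when a file or value violates the annotation schema."""


@dataclass
class Keypoint:
    """One joint: frame-pixel coordinates, annotation state, confidence.

    Coordinates are 0-based pixel centers, x to the right, y downward.
    ``confidence`` is present only on predicted keypoints.
    """

    x: float
    y: float
    state: str = "visible"
    confidence: float | None = None

    def validate(self) -> None:
        if self.state not in STATES:
            raise SchemaError(f"keypoint state {self.state!r} not in {STATES}")
        if self.confidence is not None and not (
            0.0 <= self.confidence <= 1.0 or math.isnan(self.confidence)
        ):
            raise SchemaError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def annotated(self) -> bool:
        return self.state != "unannotated"


@dataclass
class BoundingBox:
    """Axis-aligned half-open pixel box [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def validate(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise SchemaError(
                f"degenerate box ({self.x0}, {self.y0}, {self.x1}, {self.y1}):"
                " requires x1 > x0 and y1 > y0"
            )

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def as_list(self) -> list[float]:
        return [self.x0, self.y0, self.x1, self.y1]


@dataclass
class HandPose:
    """One hand instance in one frame."""

    keypoints: list[Keypoint]
    box: BoundingBox
    handedness: str = "right"
    track_id: int | None = None
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.keypoints) != N_JOINTS:
            raise SchemaError(
                f"pose has {len(self.keypoints)} keypoints, expected {N_JOINTS}"
            )
        if self.handedness not in _HANDEDNESS:
            raise SchemaError(f"handedness {self.handedness!r} not in {_HANDEDNESS}")
        if self.track_id is not None and (
            not isinstance(self.track_id, int) or self.track_id < 0
        ):
            raise SchemaError(f"track_id {self.track_id!r} must be an integer >= 0")
        self.box.validate()
        for kp in self.keypoints:
            kp.validate()

    def points(self):
        """(21, 2) float array of joint coordinates."""
        import numpy as np

        return np.array([[k.x, k.y] for k in self.keypoints], dtype=float)

    def annotated_mask(self):
        import numpy as np

        return np.array([k.annotated for k in self.keypoints], dtype=bool)


@dataclass
class FrameAnnotation:
    frame_index: int
    image_path: str
    poses: list[HandPose]
    extra: dict = field(default_factory=dict)


@dataclass
class ClipAnnotation:
    """Ordered multi-instance ground truth or predictions for one clip."""

    clip_id: str
    fps: float
    frames: list[FrameAnnotation]
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        prev = None
        for fr in self.frames:
            if prev is not None and fr.frame_index <= prev:
                raise SchemaError(
                    f"frame indices not strictly increasing at {fr.frame_index}"
                )
            prev = fr.frame_index
            seen: set[int] = set()
            for pose in fr.poses:
                pose.validate()
                if pose.track_id is not None:
                    if pose.track_id in seen:
                        raise SchemaError(
                            f"duplicate track_id {pose.track_id} in frame"
                            f" {fr.frame_index}"
                        )
                    seen.add(pose.track_id)

    def n_poses(self) -> int:
        return sum(len(fr.poses) for fr in self.frames)


# ---------------------------------------------------------------------------
# JSON serialization. Unknown keys at clip / frame / pose level survive a
# round-trip via the `extra` dicts; output bytes are stable (sorted keys).
# ---------------------------------------------------------------------------

_KP_KEYS = {"x", "y", "state", "confidence"}
_POSE_KEYS = {"keypoints", "box", "handedness", "track_id"}
_FRAME_KEYS = {"frame_index", "image_path", "poses"}
_CLIP_KEYS = {"clip_id", "fps", "frames"}


def _kp_to_dict(kp: Keypoint) -> dict:
    d = {"x": kp.x, "y": kp.y, "state": kp.state}
    if kp.confidence is not None:
        d["confidence"] = kp.confidence
    return d


def _kp_from_dict(d: dict, where: str) -> Keypoint:
    try:
        kp = Keypoint(
            x=float(d["x"]),
            y=float(d["y"]),
            state=d.get("state", "visible"),
            confidence=(None if d.get("confidence") is None else float(d["confidence"])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"bad keypoint at {where}: {exc}") from exc
    kp.validate()
    return kp


def _pose_to_dict(pose: HandPose) -> dict:
    d = {
        "keypoints": [_kp_to_dict(k) for k in pose.keypoints],
        "box": pose.box.as_list(),
        "handedness": pose.handedness,
        "track_id": pose.track_id,
    }
    d.update(pose.extra)
    return d


def _pose_from_dict(d: dict, where: str) -> HandPose:
    try:
        box = BoundingBox(*[float(v) for v in d["box"]])
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"bad box at {where}: {exc}") from exc
    tid = d.get("track_id")
    pose = HandPose(
        keypoints=[
            _kp_from_dict(k, f"{where}.keypoints[{i}]")
            for i, k in enumerate(d.get("keypoints", []))
        ],
        box=box,
        handedness=d.get("handedness", "right"),
        track_id=None if tid is None else int(tid),
        extra={k: v for k, v in d.items() if k not in _POSE_KEYS},
    )
    return pose


def clip_to_dict(clip: ClipAnnotation) -> dict:
    d = {
        "clip_id": clip.clip_id,
        "fps": clip.fps,
        "frames": [
            {
                "frame_index": fr.frame_index,
                "image_path": fr.image_path,
                "poses": [_pose_to_dict(p) for p in fr.poses],
                **fr.extra,
            }
            for fr in clip.frames
        ],
    }
    d.update(clip.extra)
    return d


def clip_from_dict(d: dict) -> ClipAnnotation:
    if "clip_id" not in d or "frames" not in d:
        missing = {"clip_id", "frames"} - set(d)
        raise SchemaError(f"missing required field(s): {sorted(missing)}")
    frames = []
    for i, fd in enumerate(d["frames"]):
        where = f"frames[{i}]"
        if "frame_index" not in fd:
            raise SchemaError(f"missing frame_index at {where}")
        frames.append(
            FrameAnnotation(
                frame_index=int(fd["frame_index"]),
                image_path=str(fd.get("image_path", "")),
                poses=[
                    _pose_from_dict(p, f"{where}.poses[{j}]")
                    for j, p in enumerate(fd.get("poses", []))
                ],
                extra={k: v for k, v in fd.items() if k not in _FRAME_KEYS},
            )
        )
    clip = ClipAnnotation(
        clip_id=str(d["clip_id"]),
        fps=float(d.get("fps", 8.0)),
        frames=frames,
        extra={k: v for k, v in d.items() if k not in _CLIP_KEYS},
    )
    clip.validate()
    return clip


def load_clip(path: str | os.PathLike) -> ClipAnnotation:
    """Load and fully validate a clip annotation/prediction JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    return clip_from_dict(d)


def save_clip(clip: ClipAnnotation, path: str | os.PathLike) -> None:
    """Write a clip as byte-stable JSON (sorted keys, fixed separators)."""
    clip.validate()
    payload = json.dumps(clip_to_dict(clip), sort_keys=True, indent=1)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(payload)
        fh.write("\n")


# ---------------------------------------------------------------------------
# External detections: one box per row, grouped by frame index. Text rows
# are `frame_index x0 y0 x1 y1 [score]` (whitespace or comma separated);
# a .json file holds a list of such rows or of objects with the same keys.
# ---------------------------------------------------------------------------


def _detection_row(vals, where: str) -> tuple[int, BoundingBox, float | None]:
    if len(vals) not in (5, 6):
        raise SchemaError(f"{where}: expected 5 or 6 fields, got {len(vals)}")
    try:
        fi = int(vals[0])
        box = BoundingBox(*[float(v) for v in vals[1:5]])
        score = float(vals[5]) if len(vals) == 6 else None
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{where}: {exc}") from exc
    box.validate()
    return fi, box, score


def load_detections(path: str | os.PathLike) -> dict[int, list[tuple[BoundingBox, float | None]]]:
    """Load per-frame bounding boxes from a detection file.

    Returns a mapping ``frame_index -> [(box, score), ...]``; frames with
    no row are simply absent (callers treat them as empty).
    """
    out: dict[int, list[tuple[BoundingBox, float | None]]] = {}
    spath = os.fspath(path)
    if spath.endswith(".json"):
        with open(spath, "r", encoding="utf-8") as fh:
            rows = json.load(fh)
        for i, row in enumerate(rows):
            if isinstance(row, dict):
                vals = [row.get("frame_index"), *row.get("box", [])]
                if "score" in row and row["score"] is not None:
                    vals.append(row["score"])
            else:
                vals = list(row)
            fi, box, score = _detection_row(vals, f"{spath}:row {i}")
            out.setdefault(fi, []).append((box, score))
        return out
    with open(spath, "r", encoding="utf-8") as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vals = line.replace(",", " ").split()
            fi, box, score = _detection_row(vals, f"{spath}:line {ln}")
            out.setdefault(fi, []).append((box, score))
    return out
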