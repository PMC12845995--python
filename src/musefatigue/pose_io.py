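"""Reading, validating and normalizing per-frame 2-D keypoint streams.

The toolkit consumes the output of a bottom-up human-pose estimator in the
COCO-17 joint convention (nose, eyes, ears, shoulders, elbows, wrists, hips,
knees, ankles), one skeleton per person per frame, each joint carrying a
confidence score in [0, 1].  Image coordinates are used throughout: origin at
the top-left corner, y increasing downward.  Absent joints are represented
explicitly with confidence 0 and are never silently dropped.

COCO-17 has no neck landmark; where a neck is needed (torso-length
normalization for the hands-on-hips rule) the midpoint of the two shoulders
is used as a proxy.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "COCO_JOINTS",
    "Keypoint2D",
    "PoseFrame",
    "Track",
    "ValidityRule",
    "FormatError",
    "read_keypoint_stream",
    "write_tracks",
    "tracks_to_csv",
    "is_valid",
    "normalize_frame",
    "NormalizedFrame",
]

#: Canonical COCO-17 joint order as emitted by COCO-trained estimators.
COCO_JOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

_JOINT_SET = frozenset(COCO_JOINTS)

POSTURES = ("squat", "akimbo", "leg_lift")

#: Per-posture joint sets that must be confidently detected before the frame
#: is evaluated for that posture.  Lower-limb rules need hip-knee-ankle; the
#: hands-on-hips rule needs the full upper-limb chain plus hips (shoulders
#: double as the neck proxy).
REQUIRED_JOINTS: dict[str, tuple[str, ...]] = {
    "squat": (
        "left_hip", "right_hip",
        "left_knee", "right_knee",
        "left_ankle", "right_ankle",
    ),
    "leg_lift": (
        "left_hip", "right_hip",
        "left_knee", "right_knee",
        "left_ankle", "right_ankle",
    ),
    "akimbo": (
        "left_shoulder", "right_shoulder",
        "left_elbow", "right_elbow",
        "left_wrist", "right_wrist",
        "left_hip", "right_hip",
    ),
}


class FormatError(ValueError):
    """Raised when an input keypoint file violates the documented layout."""


@dataclass(frozen=True)
class Keypoint2D:
    """One joint observation: pixel position plus detector confidence."""

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence!r} outside [0, 1]")
        if self.confidence > 0 and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("detected keypoint has non-finite coordinates")

    @property
    def present(self) -> bool:
        return self.confidence > 0.0


ABSENT = Keypoint2D(0.0, 0.0, 0.0)


@dataclass
class PoseFrame:
    """One person's COCO-17 skeleton in one frame.

    ``joints`` always contains all 17 joint names; joints the estimator did
    not report carry confidence 0.  ``width``/``height`` are the frame
    dimensions used for spatial normalization.
    """

    frame_index: int
    person_id: str
    joints: dict[str, Keypoint2D]
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        unknown = set(self.joints) - _JOINT_SET
        if unknown:
            raise FormatError(f"unknown joint name(s): {sorted(unknown)}")
        for name in COCO_JOINTS:
            self.joints.setdefault(name, ABSENT)

    def joint(self, name: str) -> Keypoint2D:
        return self.joints[name]

    def neck(self) -> Keypoint2D:
        """Shoulder-midpoint neck proxy (confidence = min of the shoulders)."""
        ls, rs = self.joints["left_shoulder"], self.joints["right_shoulder"]
        conf = min(ls.confidence, rs.confidence)
        if conf == 0.0:
            return ABSENT
        return Keypoint2D((ls.x + rs.x) / 2.0, (ls.y + rs.y) / 2.0, conf)


@dataclass
class Track:
    """Ordered per-visitor frame sequence at a fixed frame interval ``dt``.

    ``zone_ids`` optionally assigns each frame to a spatial unit (``None``
    entries mean "outside all zones").
    """

    visitor_id: str
    frames: list[PoseFrame]
    dt: float = 1.0 / 30.0
    zone_ids: list[int | None] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("track must contain at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if self.zone_ids is not None and len(self.zone_ids) != len(self.frames):
            raise ValueError("zone_ids must have one entry per frame")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ValidityRule:
    """Confidence threshold plus per-posture required-joint completeness."""

    conf_min: float = 0.3
    required_joints: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(REQUIRED_JOINTS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.conf_min <= 1.0:
            raise ValueError("conf_min must lie in [0, 1]")
        for posture, joints in self.required_joints.items():
            if not joints:
                raise ValueError(f"empty required-joint set for {posture!r}")


def is_valid(frame: PoseFrame, rule: ValidityRule, posture: str) -> bool:
    """True iff every joint the posture rule needs clears the confidence bar.

    Frames failing this gate are never evaluated geometrically, which is what
    prevents occlusion-induced misclassification.
    """
    if posture not in rule.required_joints:
        raise ValueError(f"unknown posture {posture!r}; expected one of {POSTURES}")
    return all(
        frame.joints[name].confidence >= rule.conf_min
        for name in rule.required_joints[posture]
    )


@dataclass(frozen=True)
class NormalizedFrame:
    """Dimensionless keypoint map: x/W and y/H per present joint.

    ``shoulder_width_px`` and its width-normalized counterpart are returned
    as auxiliary scalars when both shoulders are present (they scale the
    wrist-hip offset in the hands-on-hips rule); otherwise ``None``.
    """

    coords: dict[str, tuple[float, float]]
    shoulder_width_px: float | None
    shoulder_width: float | None


def normalize_frame(frame: PoseFrame) -> NormalizedFrame:
    """Scale keypoints by frame width/height; absent joints stay absent."""
    coords = {
        name: (kp.x / frame.width, kp.y / frame.height)
        for name, kp in frame.joints.items()
        if kp.present
    }
    ls, rs = frame.joints["left_shoulder"], frame.joints["right_shoulder"]
    if ls.present and rs.present:
        w_px = abs(ls.x - rs.x)
        return NormalizedFrame(coords, w_px, w_px / frame.width)
    return NormalizedFrame(coords, None, None)


# ---------------------------------------------------------------------------
# File I/O
#
# Two dialects are read:
#   * "run":      a single JSON file for the whole recording, either a list of
#                 records or {"frames": [...]}.  Each record:
#                 {"frame": int, "person": str, "width": W, "height": H,
#                  "keypoints": [x0, y0, c0, x1, y1, c1, ...]}   (COCO order)
#                 "keypoints" may alternatively be a {joint_name: [x, y, c]}
#                 mapping.  A flat list shorter than 17 triples pads the
#                 remaining joints with confidence 0.
#   * "openpose": a directory of one-file-per-frame JSONs
#                 ({"people": [{"pose_keypoints_2d": [...]}, ...]}).  The
#                 OpenPose dialect does not store image dimensions, so they
#                 must be supplied; person identity is positional within each
#                 file (index i -> "p{i}").
# ---------------------------------------------------------------------------


def _triples_to_joints(kps: Sequence[float], where: str) -> dict[str, Keypoint2D]:
    if len(kps) % 3 != 0:
        raise FormatError(f"{where}: keypoint list length {len(kps)} is not a multiple of 3")
    n = len(kps) // 3
    if n > len(COCO_JOINTS):
        raise FormatError(f"{where}: {n} joints exceed the COCO-17 set (unknown joint index)")
    joints: dict[str, Keypoint2D] = {}
    for i in range(n):
        x, y, c = kps[3 * i], kps[3 * i + 1], kps[3 * i + 2]
        try:
            joints[COCO_JOINTS[i]] = Keypoint2D(float(x), float(y), float(c))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{where}: joint {COCO_JOINTS[i]!r}: {exc}") from exc
    return joints


def _mapping_to_joints(kps: Mapping[str, Sequence[float]], where: str) -> dict[str, Keypoint2D]:
    joints: dict[str, Keypoint2D] = {}
    for name, triple in kps.items():
        if name not in _JOINT_SET:
            raise FormatError(f"{where}: unknown joint name {name!r}")
        if len(triple) != 3:
            raise FormatError(f"{where}: joint {name!r} needs [x, y, confidence]")
        joints[name] = Keypoint2D(float(triple[0]), float(triple[1]), float(triple[2]))
    return joints


def _frames_to_tracks(
    frames: Iterable[PoseFrame], dt: float
) -> list[Track]:
    by_person: dict[str, list[PoseFrame]] = {}
    for f in frames:
        by_person.setdefault(f.person_id, []).append(f)
    tracks = []
    for pid in sorted(by_person):
        fs = sorted(by_person[pid], key=lambda f: f.frame_index)
        tracks.append(Track(visitor_id=pid, frames=fs, dt=dt))
    return tracks


def read_keypoint_stream(
    path: str | Path,
    layout: str = "run",
    dt: float = 1.0 / 30.0,
    width: float | None = None,
    height: float | None = None,
) -> list[Track]:
    """Read a keypoint stream into per-visitor tracks.

    Parameters
    ----------
    path:
        JSON file (``layout="run"``) or directory of per-frame JSON files
        (``layout="openpose"``).
    layout:
        Input dialect, see module docstring.
    dt:
        Seconds per frame attached to every track (default 1/30 s, matching
        30 fps acquisition).
    width, height:
        Frame dimensions; required for the OpenPose dialect, optional
        fallback for run records that omit them.
    """
    path = Path(path)
    if layout == "run":
        return _read_run_file(path, dt, width, height)
    if layout == "openpose":
        if width is None or height is None:
            raise ValueError("the openpose dialect requires explicit width/height")
        return _read_openpose_dir(path, dt, width, height)
    raise ValueError(f"unsupported layout {layout!r}")


def _read_run_file(
    path: Path, dt: float, width: float | None, height: float | None
) -> list[Track]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    records = payload.get("frames") if isinstance(payload, dict) else payload
    if not isinstance(records, list):
        raise FormatError(f"{path}: expected a list of records or a 'frames' key")
    frames: list[PoseFrame] = []
    for i, rec in enumerate(records):
        where = f"{path} record {i}"
        if not isinstance(rec, dict):
            raise FormatError(f"{where}: not an object")
        try:
            fidx = int(rec["frame"])
            pid = str(rec["person"])
        except KeyError as exc:
            raise FormatError(f"{where}: missing field {exc}") from exc
        w = float(rec.get("width", width) or 0)
        h = float(rec.get("height", height) or 0)
        if w <= 0 or h <= 0:
            raise FormatError(f"{where}: missing or non-positive frame dimensions")
        kps = rec.get("keypoints")
        if isinstance(kps, Mapping):
            joints = _mapping_to_joints(kps, where)
        elif isinstance(kps, list):
            joints = _triples_to_joints(kps, where)
        else:
            raise FormatError(f"{where}: 'keypoints' must be a list or mapping")
        frames.append(PoseFrame(fidx, pid, joints, w, h))
    return _frames_to_tracks(frames, dt)


def _read_openpose_dir(path: Path, dt: float, width: float, height: float) -> list[Track]:
    files = sorted(path.glob("*.json"))
    if not files:
        raise FormatError(f"{path}: no JSON files found")
    frames: list[PoseFrame] = []
    for fi, fp in enumerate(files):
        m = re.search(r"(\d+)", fp.stem)
        fidx = int(m.group(1)) if m else fi
        try:
            payload = json.loads(fp.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{fp}: not valid JSON ({exc})") from exc
        people = payload.get("people")
        if not isinstance(people, list):
            raise FormatError(f"{fp}: missing 'people' list")
        for pi, person in enumerate(people):
            kps = person.get("pose_keypoints_2d")
            if not isinstance(kps, list):
                raise FormatError(f"{fp} person {pi}: missing 'pose_keypoints_2d'")
            joints = _triples_to_joints(kps, f"{fp} person {pi}")
            frames.append(PoseFrame(fidx, f"p{pi}", joints, width, height))
    return _frames_to_tracks(frames, dt)


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks in the canonical single-file "run" dialect."""
    records = []
    for t in tracks:
        for f in t.frames:
            kps: list[float] = []
            for name in COCO_JOINTS:
                kp = f.joints[name]
                kps.extend((kp.x, kp.y, kp.confidence))
            records.append(
                {
                    "frame": f.frame_index,
                    "person": t.visitor_id,
                    "width": f.width,
                    "height": f.height,
                    "keypoints": kps,
                }
            )
    Path(path).write_text(json.dumps({"frames": records}))


def tracks_to_csv(tracks: Sequence[Track], path: str | Path) -> None:
    """Flat inspection CSV: frame, person, joint, x, y, conf."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "person", "joint", "x", "y", "conf"])
        for t in tracks:
            for f in t.frames:
                for name in COCO_JOINTS:
                    kp = f.joints[name]
                    writer.writerow([f.frame_index, t.visitor_id, name, kp.x, kp.y, kp.confidence])
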