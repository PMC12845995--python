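"""Per-frame geometric classification of compensatory fatigue postures.

Three load-relieving postures are recognized from COCO-17 keypoints by
explicit geometric rules:

* **squat** — the hip midpoint drops below the knee midpoint by more than a
  frame-height-normalized ratio (delta > 0.10) while both knee interior
  angles (hip-knee-ankle) are below 120 degrees;
* **akimbo** (hands-on-hips) — the shoulder-width-normalized horizontal
  wrist-hip offset eta lies in (0.30, 0.45) on both sides, both elbow
  interior angles lie in (80, 120) degrees, the frame-height-normalized
  torso length tau lies in (0.3, 0.7), and (optionally) each hip sits above
  the same-side wrist in the image;
* **leg lift** — one knee interior angle lies in (70, 130) degrees while the
  other (support) leg is nearly straight (flexion = 180 - interior angle
  <= 15 degrees) and the frame-width-normalized ankle separation gamma
  exceeds 0.05.

All comparisons against open-interval thresholds are strict: boundary values
fail.  Image coordinates are y-down, so "hip below knee" means
``y_hip > y_knee``.  A combined classifier applies the three detectors in
the fixed priority order SQUAT > AKIMBO > LEG_LIFT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path

from .pose_io import Keypoint2D, PoseFrame, ValidityRule, is_valid

__all__ = [
    "PostureLabel",
    "PostureParams",
    "DegenerateGeometryError",
    "MissingJointError",
    "interior_angle",
    "squat_ratio",
    "detect_squat",
    "akimbo_eta",
    "torso_ratio",
    "detect_akimbo",
    "ankle_separation",
    "detect_leg_lift",
    "detect_pose",
]


class PostureLabel(str, Enum):
    SQUAT = "SQUAT"
    AKIMBO = "AKIMBO"
    LEG_LIFT = "LEG_LIFT"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class DegenerateGeometryError(ValueError):
    """Coincident keypoints make an angle or ratio undefined."""


class MissingJointError(ValueError):
    """A geometry op was called on a frame lacking a required joint."""


@dataclass(frozen=True)
class PostureParams:
    """Thresholds of the three posture rules.

    Defaults are the operating points used in the field deployment: ratio
    thresholds are dimensionless, angle thresholds in degrees.  All interval
    bounds are open (strict comparisons).  ``squat_knee_mode`` selects the
    both-knees reading (``"both"``, default) or the min-over-knees reading
    (``"min"``) of the squat angle condition.
    """

    tau_squat: float = 0.10
    theta_knee_squat: float = 120.0
    eta_range: tuple[float, float] = (0.30, 0.45)
    elbow_range: tuple[float, float] = (80.0, 120.0)
    torso_range: tuple[float, float] = (0.3, 0.7)
    theta_raise_range: tuple[float, float] = (70.0, 130.0)
    gamma_ankle: float = 0.05
    theta_support_flexion_max: float = 15.0
    enforce_hip_wrist_order: bool = True
    squat_knee_mode: str = "both"

    def __post_init__(self) -> None:
        for name in ("eta_range", "elbow_range", "torso_range", "theta_raise_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a nonempty open interval")
        if self.tau_squat <= 0 or self.theta_knee_squat <= 0 or self.gamma_ankle <= 0:
            raise ValueError("thresholds must be positive")
        if self.squat_knee_mode not in ("both", "min"):
            raise ValueError("squat_knee_mode must be 'both' or 'min'")

    # -- plain-text config (key = value), spec'd external interface --------

    def to_config(self, path: str | Path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = f"{v[0]},{v[1]}"
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "PostureParams":
        known = {f.name: f for f in fields(cls)}
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"unknown posture parameter {key!r}")
            if key == "squat_knee_mode":
                kwargs[key] = raw
            elif key == "enforce_hip_wrist_order":
                kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
            elif "," in raw:
                lo, hi = raw.split(",")
                kwargs[key] = (float(lo), float(hi))
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)

    def with_(self, **overrides) -> "PostureParams":
        return replace(self, **overrides)


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def _need(frame: PoseFrame, name: str) -> Keypoint2D:
    kp = frame.joints[name]
    if not kp.present:
        raise MissingJointError(f"joint {name!r} absent (confidence 0)")
    return kp


def interior_angle(a: Keypoint2D, vertex: Keypoint2D, b: Keypoint2D) -> float:
    """Angle at ``vertex`` between rays vertex->a and vertex->b, in degrees.

    A straight limb gives 180; a right angle gives 90.  Raises
    :class:`DegenerateGeometryError` if either ray has zero length.
    """
    ux, uy = a.x - vertex.x, a.y - vertex.y
    vx, vy = b.x - vertex.x, b.y - vertex.y
    nu = math.hypot(ux, uy)
    nv = math.hypot(vx, vy)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("coincident keypoints: angle undefined")
    cosang = (ux * vx + uy * vy) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def _knee_angles(frame: PoseFrame) -> tuple[float, float]:
    left = interior_angle(
        _need(frame, "left_hip"), _need(frame, "left_knee"), _need(frame, "left_ankle")
    )
    right = interior_angle(
        _need(frame, "right_hip"), _need(frame, "right_knee"), _need(frame, "right_ankle")
    )
    return left, right


def squat_ratio(frame: PoseFrame) -> float:
    """Vertical drop delta = (mean hip y - mean knee y) / frame height.

    Positive when the hip midpoint sits below the knee midpoint in the image
    (deep squat); negative for a standing figure.
    """
    lh, rh = _need(frame, "left_hip"), _need(frame, "right_hip")
    lk, rk = _need(frame, "left_knee"), _need(frame, "right_knee")
    y_hip = (lh.y + rh.y) / 2.0
    y_knee = (lk.y + rk.y) / 2.0
    return (y_hip - y_knee) / frame.height


def detect_squat(frame: PoseFrame, params: PostureParams) -> bool:
    if squat_ratio(frame) <= params.tau_squat:
        return False
    left, right = _knee_angles(frame)
    if params.squat_knee_mode == "min":
        return min(left, right) < params.theta_knee_squat
    return left < params.theta_knee_squat and right < params.theta_knee_squat


def akimbo_eta(frame: PoseFrame, side: str) -> float:
    """Shoulder-width-normalized horizontal wrist-hip offset (absolute)."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    wrist = _need(frame, f"{side}_wrist")
    hip = _need(frame, f"{side}_hip")
    ls, rs = _need(frame, "left_shoulder"), _need(frame, "right_shoulder")
    w_shoulder = abs(ls.x - rs.x)
    if w_shoulder == 0.0:
        raise DegenerateGeometryError("zero shoulder width")
    return abs(wrist.x - hip.x) / w_shoulder


def torso_ratio(frame: PoseFrame) -> float:
    """Normalized torso length tau = |neck proxy - hip midpoint| / height."""
    ls, rs = _need(frame, "left_shoulder"), _need(frame, "right_shoulder")
    lh, rh = _need(frame, "left_hip"), _need(frame, "right_hip")
    nx, ny = (ls.x + rs.x) / 2.0, (ls.y + rs.y) / 2.0
    hx, hy = (lh.x + rh.x) / 2.0, (lh.y + rh.y) / 2.0
    return math.hypot(nx - hx, ny - hy) / frame.height


def _in_open(value: float, interval: tuple[float, float]) -> bool:
    return interval[0] < value < interval[1]


def detect_akimbo(frame: PoseFrame, params: PostureParams) -> bool:
    for side in ("left", "right"):
        if not _in_open(akimbo_eta(frame, side), params.eta_range):
            return False
        elbow = interior_angle(
            _need(frame, f"{side}_shoulder"),
            _need(frame, f"{side}_elbow"),
            _need(frame, f"{side}_wrist"),
        )
        if not _in_open(elbow, params.elbow_range):
            return False
    if not _in_open(torso_ratio(frame), params.torso_range):
        return False
    if params.enforce_hip_wrist_order:
        for side in ("left", "right"):
            if not _need(frame, f"{side}_hip").y < _need(frame, f"{side}_wrist").y:
                return False
    return True


def ankle_separation(frame: PoseFrame) -> float:
    """Frame-width-normalized horizontal ankle distance gamma."""
    la, ra = _need(frame, "left_ankle"), _need(frame, "right_ankle")
    return abs(la.x - ra.x) / frame.width


def detect_leg_lift(frame: PoseFrame, params: PostureParams) -> bool:
    if not ankle_separation(frame) > params.gamma_ankle:
        return False
    left, right = _knee_angles(frame)
    for raised, support in ((left, right), (right, left)):
        if _in_open(raised, params.theta_raise_range):
            if 180.0 - support <= params.theta_support_flexion_max:
                return True
    return False


_DETECTORS = (
    (PostureLabel.SQUAT, "squat", detect_squat),
    (PostureLabel.AKIMBO, "akimbo", detect_akimbo),
    (PostureLabel.LEG_LIFT, "leg_lift", detect_leg_lift),
)


def detect_pose(
    frame: PoseFrame,
    params: PostureParams | None = None,
    rule: ValidityRule | None = None,
) -> PostureLabel:
    """Priority-ordered combined classifier (SQUAT > AKIMBO > LEG_LIFT).

    Invalid frames (confidence gate or missing joints) and degenerate
    geometry yield ``NONE`` rather than an exception.
    """
    params = params or PostureParams()
    rule = rule or ValidityRule()
    for label, posture_name, detector in _DETECTORS:
        if not is_valid(frame, rule, posture_name):
            continue
        try:
            if detector(frame, params):
                return label
        except (DegenerateGeometryError, MissingJointError):
            continue
    return PostureLabel.NONE
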