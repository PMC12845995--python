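"""Synthetic fixture factory: keypoint tracks, populations, plans, images.

Every generator is a pure function of its seed and spec, so all downstream
modules are testable without any recorded footage.  Posed figures are built
from a canonical 2-D stick figure with anthropometric segment ratios in a
1920x1080 frame; the figure is sized so its normalized torso length lands
inside the (0.3, 0.7) band required by the hands-on-hips rule.  Each
scripted posture satisfies its detector's criteria with explicit margins
(squat: delta = 0.2, knee angles 100 deg; akimbo: eta = 0.375, elbows
100 deg; leg lift: raised knee 100 deg, support flexion ~12 deg,
gamma ~ 0.084), and the neutral standing figure satisfies none.

Because fatigue credit starts only at the m-th consecutive frame, events can
be scripted by *confirmed* duration: :func:`event_for_confirmed` prepends
the m-1 lead-in frames so the confirmed frame count is exact.  Population
generation uses this to give fatigued visitors a scripted budget of exactly
3.5 weighted-seconds (above the 0.15 * 20 = 3.0 decision boundary) and
non-fatigued visitors 1.0, keeping the per-zone binomial truth unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box

from .pose_io import COCO_JOINTS, Keypoint2D, PoseFrame, Track
from .posture import PostureLabel
from .coverage import CameraCandidate, CoverageGrid
from .zoning import Zone

__all__ = [
    "FRAME_W",
    "FRAME_H",
    "PostureScript",
    "PopulationSpec",
    "standing_figure",
    "squat_figure",
    "akimbo_figure",
    "leg_lift_figure",
    "figure_for",
    "event_for_confirmed",
    "gen_track",
    "gen_population",
    "gen_zone_grid",
    "gen_floorplan",
    "gen_test_images",
]

FRAME_W = 1920.0
FRAME_H = 1080.0
_X0 = 960.0


def _rot(vec: tuple[float, float], degrees: float) -> tuple[float, float]:
    c, s = math.cos(math.radians(degrees)), math.sin(math.radians(degrees))
    return (c * vec[0] - s * vec[1], s * vec[0] + c * vec[1])


def _limb_end(
    joint: tuple[float, float],
    toward: tuple[float, float],
    angle_deg: float,
    length: float,
) -> tuple[float, float]:
    """End point of a segment from ``joint`` making ``angle_deg`` with
    joint->toward, choosing the solution that points downward in the image."""
    ux, uy = toward[0] - joint[0], toward[1] - joint[1]
    n = math.hypot(ux, uy)
    ux, uy = ux / n, uy / n
    best = None
    for sign in (+1.0, -1.0):
        dx, dy = _rot((ux, uy), sign * angle_deg)
        cand = (joint[0] + length * dx, joint[1] + length * dy)
        if best is None or cand[1] > best[1]:
            best = cand
    return best


_HEAD = {
    "nose": (_X0, 60.0),
    "left_eye": (_X0 - 15.0, 50.0),
    "right_eye": (_X0 + 15.0, 50.0),
    "left_ear": (_X0 - 30.0, 55.0),
    "right_ear": (_X0 + 30.0, 55.0),
}


def standing_figure() -> dict[str, tuple[float, float]]:
    """Neutral upright figure: arms hanging, legs near-straight."""
    fig = dict(_HEAD)
    fig.update(
        {
            "left_shoulder": (_X0 - 110.0, 180.0),
            "right_shoulder": (_X0 + 110.0, 180.0),
            "left_elbow": (_X0 - 130.0, 370.0),
            "right_elbow": (_X0 + 130.0, 370.0),
            "left_wrist": (_X0 - 80.0, 545.0),
            "right_wrist": (_X0 + 80.0, 545.0),
            "left_hip": (_X0 - 60.0, 540.0),
            "right_hip": (_X0 + 60.0, 540.0),
            "left_knee": (_X0 - 70.0, 790.0),
            "right_knee": (_X0 + 70.0, 790.0),
            "left_ankle": (_X0 - 30.0, 1030.0),
            "right_ankle": (_X0 + 30.0, 1030.0),
        }
    )
    return fig


def squat_figure(delta: float = 0.2, knee_angle: float = 100.0) -> dict[str, tuple[float, float]]:
    """Deep squat: hip midpoint ``delta``*H below the knee midpoint, both
    knee interior angles at ``knee_angle`` degrees."""
    knee_y = 700.0
    hip_y = knee_y + delta * FRAME_H
    fig = {
        "nose": (_X0, 500.0),
        "left_eye": (_X0 - 15.0, 492.0),
        "right_eye": (_X0 + 15.0, 492.0),
        "left_ear": (_X0 - 30.0, 496.0),
        "right_ear": (_X0 + 30.0, 496.0),
        "left_shoulder": (_X0 - 110.0, 600.0),
        "right_shoulder": (_X0 + 110.0, 600.0),
        "left_elbow": (_X0 - 135.0, 680.0),
        "right_elbow": (_X0 + 135.0, 680.0),
        "left_wrist": (_X0 - 120.0, 760.0),
        "right_wrist": (_X0 + 120.0, 760.0),
        "left_hip": (_X0 - 60.0, hip_y),
        "right_hip": (_X0 + 60.0, hip_y),
        "left_knee": (_X0 - 100.0, knee_y),
        "right_knee": (_X0 + 100.0, knee_y),
    }
    for side in ("left", "right"):
        fig[f"{side}_ankle"] = _limb_end(
            fig[f"{side}_knee"], fig[f"{side}_hip"], knee_angle, 330.0
        )
    return fig


def akimbo_figure(eta: float = 0.375, elbow_angle: float = 100.0) -> dict[str, tuple[float, float]]:
    """Hands on hips: wrist-hip offset ``eta`` shoulder widths, elbows bent
    to ``elbow_angle`` degrees, wrists just below the hips in the image."""
    fig = standing_figure()
    shoulder_w = fig["right_shoulder"][0] - fig["left_shoulder"][0]
    offset = eta * shoulder_w
    for side, sign in (("left", -1.0), ("right", +1.0)):
        hip = fig[f"{side}_hip"]
        wrist = (hip[0] + sign * offset, hip[1] + 20.0)
        fig[f"{side}_wrist"] = wrist
        shoulder = fig[f"{side}_shoulder"]
        # elbow on the perpendicular bisector of shoulder-wrist, far enough
        # out that the interior angle at the elbow equals elbow_angle
        sx, sy = shoulder
        wx, wy = wrist
        half_l = math.hypot(wx - sx, wy - sy) / 2.0
        d = half_l / math.tan(math.radians(elbow_angle / 2.0))
        mx, my = (sx + wx) / 2.0, (sy + wy) / 2.0
        ux, uy = (wx - sx) / (2.0 * half_l), (wy - sy) / (2.0 * half_l)
        nx, ny = -uy, ux
        if (nx > 0) != (sign > 0):  # point the elbow outward from the body
            nx, ny = -nx, -ny
        fig[f"{side}_elbow"] = (mx + d * nx, my + d * ny)
    return fig


def leg_lift_figure(raised_knee_angle: float = 100.0) -> dict[str, tuple[float, float]]:
    """Single-leg stance: right knee raised and bent to ``raised_knee_angle``
    degrees, left (support) leg near-straight, ankles clearly separated."""
    fig = standing_figure()
    hip = fig["right_hip"]
    knee = (hip[0] + 180.0, hip[1] + 140.0)
    fig["right_knee"] = knee
    fig["right_ankle"] = _limb_end(knee, hip, raised_knee_angle, 230.0)
    return fig


_FIGURES = {
    PostureLabel.NONE: standing_figure,
    PostureLabel.SQUAT: squat_figure,
    PostureLabel.AKIMBO: akimbo_figure,
    PostureLabel.LEG_LIFT: leg_lift_figure,
}


def figure_for(label: PostureLabel) -> dict[str, tuple[float, float]]:
    return _FIGURES[label]()


@dataclass(frozen=True)
class PostureScript:
    """Scripted posture timeline for one visitor.

    ``events`` are (start_frame, end_frame, label) with an exclusive end;
    outside events the figure stands neutrally.  Gaussian pixel jitter
    (``noise_sd``) and per-joint Bernoulli dropout are applied after posing.
    """

    duration_frames: int
    events: tuple[tuple[int, int, PostureLabel], ...] = ()
    fps: float = 30.0
    noise_sd: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0
    width: float = FRAME_W
    height: float = FRAME_H
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.duration_frames < 1 or self.fps <= 0:
            raise ValueError("need duration_frames >= 1 and fps > 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        spans = sorted((s, e) for s, e, _ in self.events)
        for (s, e) in spans:
            if not 0 <= s < e <= self.duration_frames:
                raise ValueError(f"event ({s}, {e}) outside the script duration")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("overlapping posture events")


def event_for_confirmed(
    start: int, n_confirmed: int, label: PostureLabel, m_confirm: int = 5
) -> tuple[int, int, PostureLabel]:
    """Event whose run yields exactly ``n_confirmed`` confirmed frames under
    m-frame confirmation (the m-1 lead-in frames are prepended)."""
    if n_confirmed < 1:
        raise ValueError("n_confirmed must be >= 1")
    return (start, start + n_confirmed + m_confirm - 1, label)


def _label_at(script: PostureScript, t: int) -> PostureLabel:
    for s, e, label in script.events:
        if s <= t < e:
            return label
    return PostureLabel.NONE


def gen_track(
    script: PostureScript, visitor_id: str = "v1"
) -> tuple[Track, list[PostureLabel]]:
    """Generate a track plus its ground-truth per-frame labels."""
    rng = np.random.default_rng(script.seed)
    frames: list[PoseFrame] = []
    truth: list[PostureLabel] = []
    for t in range(script.duration_frames):
        label = _label_at(script, t)
        truth.append(label)
        fig = figure_for(label)
        joints: dict[str, Keypoint2D] = {}
        for name in COCO_JOINTS:
            x, y = fig[name]
            if script.noise_sd > 0:
                x += rng.normal(0.0, script.noise_sd)
                y += rng.normal(0.0, script.noise_sd)
            conf = script.confidence
            if script.dropout_rate > 0 and rng.random() < script.dropout_rate:
                conf = 0.0
            joints[name] = Keypoint2D(x, y, conf)
        frames.append(PoseFrame(t, visitor_id, joints, script.width, script.height))
    return Track(visitor_id, frames, dt=1.0 / script.fps), truth


@dataclass(frozen=True)
class PopulationSpec:
    """Per-zone visitor populations with known fatigue probabilities.

    Each visitor is independently "fatigued" with the zone's probability p;
    fatigued visitors receive a scripted squat worth ``fatigued_budget``
    weighted-seconds of confirmed posture time, others ``nonfatigued_budget``
    (below the decision boundary).  ``fps`` = 5 keeps population-scale runs
    short without changing the weighted-seconds truth (confirmation counts
    frames, budgets count seconds).
    """

    zone_ids: tuple[int, ...]
    visitors_per_zone: int
    fatigue_probability: float | Mapping[int, float]
    seed: int = 0
    fps: float = 5.0
    m_confirm: int = 5
    fatigued_budget: float = 3.5
    nonfatigued_budget: float = 1.0
    squat_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.visitors_per_zone < 1:
            raise ValueError("visitors_per_zone must be >= 1")
        for z in self.zone_ids:
            p = self.p_for(z)
            if not 0.0 <= p <= 1.0:
                raise ValueError("fatigue_probability must lie in [0, 1]")

    def p_for(self, zone_id: int) -> float:
        if isinstance(self.fatigue_probability, Mapping):
            return self.fatigue_probability[zone_id]
        return float(self.fatigue_probability)


def gen_population(spec: PopulationSpec) -> tuple[list[Track], dict[int, float]]:
    """Generate tracks for every zone; returns (tracks, true per-zone p)."""
    rng = np.random.default_rng(spec.seed)
    tracks: list[Track] = []
    lead = 3
    for zone_id in spec.zone_ids:
        p = spec.p_for(zone_id)
        for k in range(spec.visitors_per_zone):
            fatigued = rng.random() < p
            budget = spec.fatigued_budget if fatigued else spec.nonfatigued_budget
            confirmed_s = budget / spec.squat_weight
            n_confirmed = max(1, round(confirmed_s * spec.fps))
            event = event_for_confirmed(lead, n_confirmed, PostureLabel.SQUAT, spec.m_confirm)
            duration = event[1] + lead
            script = PostureScript(
                duration_frames=duration,
                events=(event,),
                fps=spec.fps,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            track, _ = gen_track(script, visitor_id=f"z{zone_id}v{k}")
            track.zone_ids = [zone_id] * len(track.frames)
            tracks.append(track)
    truth = {z: spec.p_for(z) for z in spec.zone_ids}
    return tracks, truth


def gen_zone_grid(nx: int, ny: int, cell: float = 1.0) -> list[Zone]:
    """Axis-aligned grid of square zones, ids 1..nx*ny row-major."""
    zones = []
    zid = 1
    for j in range(ny):
        for i in range(nx):
            poly = box(i * cell, j * cell, (i + 1) * cell, (j + 1) * cell)
            zones.append(Zone(zid, poly, ((i + 0.5) * cell, (j + 0.5) * cell)))
            zid += 1
    return zones


def gen_floorplan(
    kind: str, seed: int = 0
) -> tuple[CoverageGrid, list[CameraCandidate]]:
    """Toy floor plans with boundary camera candidates heading inward.

    ``"open-hall"``: 20x12 m rectangle, no obstacles; candidate 1 is a
    corner camera whose 90-degree wedge covers the whole hall.
    ``"partition-wall"``: same hall with an internal wall (x = 10,
    y in [2, 10]) occluding cells behind it from front cameras.
    """
    rng = np.random.default_rng(seed)
    w, h = 20.0, 12.0
    domain = box(0.0, 0.0, w, h)
    if kind == "open-hall":
        obstacles: list[Polygon] = []
    elif kind == "partition-wall":
        obstacles = [Polygon([(9.9, 2.0), (10.1, 2.0), (10.1, 10.0), (9.9, 10.0)])]
    else:
        raise ValueError(f"unknown layout {kind!r}")
    grid = CoverageGrid.from_plan(domain, 1.0, obstacles)
    radius = math.hypot(w, h) + 1.0
    # corner cameras head along the diagonal: a 90-degree wedge then spans
    # the full quadrant of bearings into the hall
    spots = [
        ((0.0, 0.0), 45.0),
        ((w, 0.0), 135.0),
        ((w, h), -135.0),
        ((0.0, h), -45.0),
        ((0.0, h / 2), 0.0),
        ((w, h / 2), 180.0),
        ((w / 2, 0.0), 90.0),
        ((w / 2, h), -90.0),
    ]
    candidates = []
    for i, (pos, heading) in enumerate(spots, start=1):
        fov = 90.0 if i == 1 else float(rng.uniform(90.0, 120.0))
        candidates.append(CameraCandidate(i, pos, heading, fov, radius))
    return grid, candidates


def gen_test_images(kind: str, **params) -> np.ndarray:
    """Deterministic raster test images with analytically known metrics.

    Kinds: ``constant`` (value, shape), ``two_pixel`` ({0, 1} strip),
    ``step`` (vertical edge of given height), ``checkerboard`` (period),
    ``gradient`` (horizontal ramp), ``blurred`` (3x3 box blur of ``base``,
    replicate borders).
    """
    shape = params.get("shape", (16, 16))
    if kind == "constant":
        return np.full(shape, float(params.get("value", 0.5)))
    if kind == "two_pixel":
        return np.array([[0.0, 1.0]])
    if kind == "step":
        height = float(params.get("height", 1.0))
        img = np.zeros(shape)
        img[:, shape[1] // 2 :] = height
        return img
    if kind == "checkerboard":
        period = int(params.get("period", 2))
        yy, xx = np.indices(shape)
        return (((yy // period) + (xx // period)) % 2).astype(float)
    if kind == "gradient":
        return np.tile(np.linspace(0.0, 1.0, shape[1]), (shape[0], 1))
    if kind == "blurred":
        base = np.asarray(params["base"], dtype=float)
        return ndimage.uniform_filter(base, size=3, mode="nearest")
    raise ValueError(f"unknown image kind {kind!r}")
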