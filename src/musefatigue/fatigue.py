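"""Temporal confirmation and per-visitor fatigue scoring.

A per-frame posture label only accrues fatigue credit once it has persisted
for ``m`` consecutive frames (default 5), which suppresses transient
misdetections and short occlusions.  Accrual starts at the m-th frame of a
run: a raw run of length L >= m contributes L - m + 1 confirmed frames, and
runs shorter than m contribute nothing.

Confirmed per-posture durations f_i (seconds) are combined into a raw score

    F = sum_i w_i * f_i          (weights: squat 0.5, leg lift 0.3, akimbo 0.2)

and min-max normalized to S_v in [0, 1].  The default normalization is the
fixed pilot scale (F_min = 0, F_max = 20 weighted-seconds); an alternative
"window" mode normalizes by w_max * T_win for a fixed observation window.
A visitor is flagged fatigued when S_v >= gamma (default 0.15; the equality
case flags).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .pose_io import Track, ValidityRule
from .posture import PostureLabel, PostureParams, detect_pose

__all__ = [
    "FatigueParams",
    "FatigueResult",
    "confirm_states",
    "accumulate_score",
    "normalize_score",
    "detect_fatigue",
    "results_to_csv",
]

_SCORED = (PostureLabel.SQUAT, PostureLabel.AKIMBO, PostureLabel.LEG_LIFT)


def _default_weights() -> dict[PostureLabel, float]:
    return {
        PostureLabel.SQUAT: 0.5,
        PostureLabel.LEG_LIFT: 0.3,
        PostureLabel.AKIMBO: 0.2,
    }


@dataclass(frozen=True)
class FatigueParams:
    """Weights, confirmation depth, normalization scale and decision bar."""

    weights: Mapping[PostureLabel, float] = field(default_factory=_default_weights)
    m_confirm: int = 5
    gamma_fatigue: float = 0.15
    f_min: float = 0.0
    f_max: float = 20.0
    norm_mode: str = "fixed"
    t_win: float | None = None

    def __post_init__(self) -> None:
        if self.m_confirm < 1:
            raise ValueError("m_confirm must be >= 1")
        if not 0.0 <= self.gamma_fatigue <= 1.0:
            raise ValueError("gamma_fatigue must lie in [0, 1]")
        if self.f_max <= self.f_min:
            raise ValueError("f_max must exceed f_min")
        if self.norm_mode not in ("fixed", "window"):
            raise ValueError("norm_mode must be 'fixed' or 'window'")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("posture weights must be positive")

    def with_(self, **overrides) -> "FatigueParams":
        return replace(self, **overrides)


def confirm_states(
    labels: Sequence[PostureLabel], m: int
) -> list[PostureLabel]:
    """Multi-frame confirmation of a raw per-frame label sequence.

    Frame t carries a confirmed label iff it sits at position >= m inside an
    unbroken run of that label; a NONE or a different label resets the
    counter.  With m = 1 the output equals the input.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    out: list[PostureLabel] = []
    count = 0
    prev = PostureLabel.NONE
    for label in labels:
        if label == PostureLabel.NONE:
            count = 0
            prev = PostureLabel.NONE
        elif label == prev:
            count += 1
        else:
            count = 1
            prev = label
        out.append(label if count >= m else PostureLabel.NONE)
    return out


def accumulate_score(
    confirmed: Sequence[PostureLabel],
    params: FatigueParams | None = None,
    dt: float = 1.0 / 30.0,
) -> tuple[float, dict[PostureLabel, float]]:
    """Weighted raw score F and per-posture confirmed durations (seconds)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params or FatigueParams()
    counts = {p: 0 for p in _SCORED}
    for label in confirmed:
        if label in counts:
            counts[label] += 1
    # durations from frame counts in one multiply, so a whole-second run
    # (e.g. 180 frames at 1/30 s) lands exactly on the second boundary
    durations = {p: counts[p] * dt for p in _SCORED}
    f_raw = sum(params.weights[p] * durations[p] for p in _SCORED)
    return f_raw, durations


def normalize_score(f_raw: float, params: FatigueParams | None = None) -> float:
    """Min-max normalized score S_v, clamped to [0, 1]."""
    params = params or FatigueParams()
    if params.norm_mode == "window":
        if params.t_win is None or params.t_win <= 0:
            raise ValueError("window normalization requires a positive t_win")
        smax = max(params.weights.values()) * params.t_win
        smin = 0.0
    else:
        smin, smax = params.f_min, params.f_max
    sv = (f_raw - smin) / (smax - smin)
    return min(1.0, max(0.0, sv))


@dataclass(frozen=True)
class FatigueResult:
    """Per-visitor outcome of the fatigue determination pipeline."""

    visitor_id: str
    score_raw: float
    score_norm: float
    flag: bool
    confirmed_durations: Mapping[PostureLabel, float]
    labels: tuple[PostureLabel, ...] = ()
    confirmed: tuple[PostureLabel, ...] = ()


def detect_fatigue(
    track: Track,
    posture_params: PostureParams | None = None,
    validity_rule: ValidityRule | None = None,
    fatigue_params: FatigueParams | None = None,
) -> FatigueResult:
    """Full per-visitor pipeline: classify, confirm, accumulate, normalize."""
    posture_params = posture_params or PostureParams()
    validity_rule = validity_rule or ValidityRule()
    fatigue_params = fatigue_params or FatigueParams()
    labels = [detect_pose(f, posture_params, validity_rule) for f in track.frames]
    confirmed = confirm_states(labels, fatigue_params.m_confirm)
    f_raw, durations = accumulate_score(confirmed, fatigue_params, track.dt)
    sv = normalize_score(f_raw, fatigue_params)
    return FatigueResult(
        visitor_id=track.visitor_id,
        score_raw=f_raw,
        score_norm=sv,
        flag=sv >= fatigue_params.gamma_fatigue,
        confirmed_durations=durations,
        labels=tuple(labels),
        confirmed=tuple(confirmed),
    )


def results_to_csv(results: Sequence[FatigueResult], path: str | Path) -> None:
    """Export: visitor_id, F, Sv, fv, per-posture confirmed seconds."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["visitor_id", "F", "Sv", "fv", "squat_s", "akimbo_s", "leg_lift_s"]
        )
        for r in results:
            writer.writerow(
                [
                    r.visitor_id,
                    r.score_raw,
                    r.score_norm,
                    int(r.flag),
                    r.confirmed_durations[PostureLabel.SQUAT],
                    r.confirmed_durations[PostureLabel.AKIMBO],
                    r.confirmed_durations[PostureLabel.LEG_LIFT],
                ]
            )
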