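"""Zone-level Fatigue Index aggregation, banding, mapping and comparison.

The exhibition floor is partitioned into spatial analysis units (polygons
with a representative point).  For each unit the Fatigue Index is the
proportion of visitors flagged fatigued while inside it:

    FI_i = N_f,i / N_t,i

where N_t is the number of unique visitors with at least one frame in the
unit and N_f the number of those whose *zone-restricted* frame subsequence
yields a fatigue flag (the multi-frame confirmation is re-run on the
restricted subsequence, so fatigue does not carry over between units).

FI is banded low / medium / high by the continuous partition
[0, 1/3], (1/3, 2/3], (2/3, 1], which agrees with the published two-decimal
band table.  Descriptive comparison arithmetic for pre/post-intervention
runs (percentage-point FI decreases, museum-wide means, relative changes,
proportions) lives here as well.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .pose_io import Track, ValidityRule
from .posture import PostureParams
from .fatigue import FatigueParams, detect_fatigue

__all__ = [
    "Zone",
    "ZoneStats",
    "RunComparison",
    "Homography",
    "load_zones",
    "save_zones",
    "assign_zone",
    "assign_track_zones",
    "zone_fatigue_index",
    "classify_fi",
    "compare_runs",
    "relative_change",
    "proportion",
    "export_heatmap",
]

BAND_COLORS = {"low": "#4daf4a", "medium": "#ff7f00", "high": "#e41a1c"}


@dataclass
class Zone:
    """One spatial analysis unit: polygon boundary plus representative point."""

    zone_id: int
    boundary: Polygon
    rep_point: tuple[float, float]

    def __post_init__(self) -> None:
        if not isinstance(self.boundary, Polygon):
            self.boundary = Polygon(self.boundary)
        if not self.boundary.is_valid:
            raise ValueError(f"zone {self.zone_id}: self-intersecting boundary")


@dataclass(frozen=True)
class ZoneStats:
    zone_id: int
    n_total: int
    n_fatigued: int
    fi: float
    band: str
    empty: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_fatigued <= max(self.n_total, 0):
            raise ValueError("need 0 <= Nf <= Nt")


def load_zones(path: str | Path) -> list[Zone]:
    """Zone config: JSON list of {zone_id, polygon, rep_point}."""
    payload = json.loads(Path(path).read_text())
    zones = [
        Zone(int(z["zone_id"]), Polygon(z["polygon"]), tuple(z["rep_point"]))
        for z in payload
    ]
    ids = [z.zone_id for z in zones]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate zone ids in config")
    return zones


def save_zones(zones: Sequence[Zone], path: str | Path) -> None:
    payload = [
        {
            "zone_id": z.zone_id,
            "polygon": [list(xy) for xy in z.boundary.exterior.coords[:-1]],
            "rep_point": list(z.rep_point),
        }
        for z in zones
    ]
    Path(path).write_text(json.dumps(payload))


class Homography:
    """Planar projective map from camera-image to floor-plan coordinates.

    The camera-to-plan projection is site-specific calibration data supplied
    by the user as >= 4 point correspondences (direct linear transform).
    """

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.asarray(matrix, dtype=float).reshape(3, 3)

    @classmethod
    def from_points(cls, src: Sequence[tuple[float, float]], dst: Sequence[tuple[float, float]]) -> "Homography":
        src = np.asarray(src, float)
        dst = np.asarray(dst, float)
        if len(src) < 4 or len(src) != len(dst):
            raise ValueError("need >= 4 paired correspondences")
        rows = []
        for (x, y), (u, v) in zip(src, dst):
            rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
            rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
        _, _, vt = np.linalg.svd(np.asarray(rows))
        return cls(vt[-1])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        homo = np.hstack([pts, np.ones((len(pts), 1))]) @ self.matrix.T
        return homo[:, :2] / homo[:, 2:3]


def assign_zone(point: tuple[float, float], zones: Sequence[Zone]) -> int | None:
    """Id of the zone containing the point (boundary inclusive); None outside.

    Overlapping zones resolve to the lowest zone_id with a warning.
    """
    if not zones:
        raise ValueError("zones must be nonempty")
    p = Point(point)
    hits = sorted(z.zone_id for z in zones if z.boundary.covers(p))
    if len(hits) > 1:
        warnings.warn(
            f"point {point} lies in overlapping zones {hits}; using {hits[0]}",
            stacklevel=2,
        )
    return hits[0] if hits else None


def assign_track_zones(
    track: Track,
    zones: Sequence[Zone],
    points: Sequence[tuple[float, float]],
    homography: Homography | None = None,
) -> Track:
    """Attach per-frame zone ids from per-frame floor (or image) positions."""
    if len(points) != len(track.frames):
        raise ValueError("need one position per frame")
    pts = np.asarray(points, float)
    if homography is not None:
        pts = homography.apply(pts)
    track.zone_ids = [assign_zone(tuple(p), zones) for p in pts]
    return track


def _zone_subtrack(track: Track, zone_id: int) -> Track | None:
    if track.zone_ids is None:
        return None
    frames = [f for f, z in zip(track.frames, track.zone_ids) if z == zone_id]
    if not frames:
        return None
    return Track(track.visitor_id, frames, dt=track.dt)


def zone_fatigue_index(
    tracks: Sequence[Track],
    zone: Zone,
    posture_params: PostureParams | None = None,
    validity_rule: ValidityRule | None = None,
    fatigue_params: FatigueParams | None = None,
) -> ZoneStats:
    """Nt, Nf and FI for one zone, re-running detection per zone subsequence."""
    n_total = 0
    n_fatigued = 0
    for track in tracks:
        sub = _zone_subtrack(track, zone.zone_id)
        if sub is None:
            continue
        n_total += 1
        result = detect_fatigue(sub, posture_params, validity_rule, fatigue_params)
        if result.flag:
            n_fatigued += 1
    if n_total == 0:
        return ZoneStats(zone.zone_id, 0, 0, 0.0, classify_fi(0.0), empty=True)
    fi = n_fatigued / n_total
    return ZoneStats(zone.zone_id, n_total, n_fatigued, fi, classify_fi(fi))


def classify_fi(fi: float) -> str:
    """Band an FI value: low [0, 1/3], medium (1/3, 2/3], high (2/3, 1]."""
    if not 0.0 <= fi <= 1.0:
        raise ValueError("FI must lie in [0, 1]")
    if fi <= 1.0 / 3.0:
        return "low"
    if fi <= 2.0 / 3.0:
        return "medium"
    return "high"


@dataclass(frozen=True)
class RunComparison:
    """Pre/post-intervention descriptive comparison.

    ``drop_pp`` holds per-zone decreases in percentage points,
    100 * (FI_pre - FI_post); museum-wide means exclude empty zones.
    """

    fi_pre: Mapping[int, float]
    fi_post: Mapping[int, float]
    drop_pp: Mapping[int, float]
    mean_fi_pre: float
    mean_fi_post: float
    mean_decrease: float


def compare_runs(
    pre: Sequence[ZoneStats], post: Sequence[ZoneStats]
) -> RunComparison:
    pre_by = {s.zone_id: s for s in pre}
    post_by = {s.zone_id: s for s in post}
    if set(pre_by) != set(post_by):
        raise ValueError("pre/post runs cover different zone ids")
    fi_pre = {zid: pre_by[zid].fi for zid in sorted(pre_by)}
    fi_post = {zid: post_by[zid].fi for zid in sorted(post_by)}
    drop = {zid: 100.0 * (fi_pre[zid] - fi_post[zid]) for zid in fi_pre}
    pre_vals = [s.fi for s in pre if not s.empty]
    post_vals = [s.fi for s in post if not s.empty]
    mean_pre = float(np.mean(pre_vals)) if pre_vals else 0.0
    mean_post = float(np.mean(post_vals)) if post_vals else 0.0
    return RunComparison(fi_pre, fi_post, drop, mean_pre, mean_post, mean_pre - mean_post)


def relative_change(before: float, after: float) -> float:
    """Percent change 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("relative change undefined for before = 0")
    return 100.0 * (after - before) / before


def proportion(k: int, n: int) -> float:
    """Percent proportion 100 * k / n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return 100.0 * k / n


def stats_to_frame(stats: Sequence[ZoneStats], zones: Sequence[Zone]) -> pd.DataFrame:
    rep = {z.zone_id: z.rep_point for z in zones}
    return pd.DataFrame(
        {
            "zone_id": [s.zone_id for s in stats],
            "rep_x": [rep[s.zone_id][0] for s in stats],
            "rep_y": [rep[s.zone_id][1] for s in stats],
            "Nt": [s.n_total for s in stats],
            "Nf": [s.n_fatigued for s in stats],
            "FI": [s.fi for s in stats],
            "band": [s.band for s in stats],
            "empty": [s.empty for s in stats],
        }
    )


def export_heatmap(
    stats: Sequence[ZoneStats],
    zones: Sequence[Zone],
    out_csv: str | Path,
    out_plot: str | Path | None = None,
) -> None:
    """Write the per-zone CSV and (optionally) a banded FI map.

    Zones are drawn with the band palette and annotated with FI; a constant
    FI field (min == max) renders without error as a single-color map.
    """
    by_id = {z.zone_id: z for z in zones}
    missing = [s.zone_id for s in stats if s.zone_id not in by_id]
    if missing:
        raise ValueError(f"stats reference unknown zones {missing}")
    stats_to_frame(stats, zones).to_csv(out_csv, index=False, float_format="%.10g")
    if out_plot is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    for s in stats:
        zone = by_id[s.zone_id]
        xs, ys = zone.boundary.exterior.xy
        ax.fill(xs, ys, color=BAND_COLORS[s.band], alpha=0.7, edgecolor="black")
        ax.annotate(
            f"{s.zone_id}\n{s.fi:.2f}",
            zone.rep_point,
            ha="center",
            va="center",
            fontsize=7,
        )
    ax.set_aspect("equal")
    ax.set_title("Zone Fatigue Index")
    fig.savefig(out_plot, dpi=120, bbox_inches="tight")
    plt.close(fig)
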