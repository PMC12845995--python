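"""Occlusion-aware camera-coverage evaluation and layout planning.

The exhibition floor (plan view, meters) is discretized into regular
coverage cells.  A candidate camera sees a cell iff the cell center lies
within its observation radius and its field-of-view wedge (both boundaries
closed) and the sight line to the cell crosses no occluder polygon.
Installation height is folded into the effective radius; the horizontal FOV
is constrained to [90, 120] degrees, the range that balances wide coverage
against geometric distortion.

Layout quality is measured by the Covered Area Percentage

    CAP = 100 * |{cells seen by >= r selected cameras}| / N,    UAP = 100 - CAP

with r the required coverage redundancy.  Two planners are provided: a
greedy marginal-gain selector (deterministic tie-breaks by lowest camera
id) and an exhaustive search over candidate subsets for small instances,
which serves as the optimality oracle.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CoverageGrid",
    "CameraCandidate",
    "CoverageReport",
    "visible_cells",
    "cap",
    "uap",
    "greedy_plan",
    "exhaustive_plan",
    "load_plan",
]

_EXHAUSTIVE_GUARD = 2**20


@dataclass
class CoverageGrid:
    """Coverage cells (id -> center) inside a floor domain, minus obstacles."""

    cell_size: float
    cells: dict[int, tuple[float, float]]
    obstacles: list[Polygon] = field(default_factory=list)
    domain: Polygon | None = None

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("grid must contain at least one cell")

    @classmethod
    def from_plan(
        cls,
        domain: Polygon | Sequence[tuple[float, float]],
        cell_size: float,
        obstacles: Sequence[Polygon] = (),
    ) -> "CoverageGrid":
        """Lay a regular grid of cell centers over the domain interior."""
        if not isinstance(domain, Polygon):
            domain = Polygon(domain)
        obstacles = [o if isinstance(o, Polygon) else Polygon(o) for o in obstacles]
        minx, miny, maxx, maxy = domain.bounds
        cells: dict[int, tuple[float, float]] = {}
        cid = 1
        y = miny + cell_size / 2.0
        while y < maxy:
            x = minx + cell_size / 2.0
            while x < maxx:
                p = Point(x, y)
                if domain.covers(p) and not any(o.contains(p) for o in obstacles):
                    cells[cid] = (x, y)
                    cid += 1
                x += cell_size
            y += cell_size
        return cls(cell_size, cells, obstacles, domain)


@dataclass(frozen=True)
class CameraCandidate:
    """A candidate camera pose: position (m), heading and FOV (degrees)."""

    cam_id: int
    position: tuple[float, float]
    heading: float
    fov: float
    radius: float

    def __post_init__(self) -> None:
        if not 90.0 <= self.fov <= 120.0:
            raise ValueError("fov must lie in [90, 120] degrees")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class CoverageReport:
    counts: dict[int, int]
    cap: float
    uap: float
    r: int
    selection: tuple[int, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selection": list(self.selection),
                    "r": self.r,
                    "cap": self.cap,
                    "uap": self.uap,
                    "counts": {str(k): v for k, v in self.counts.items()},
                }
            )
        )


def _angle_diff(a: float, b: float) -> float:
    """Absolute angular difference in degrees, wrapped to [0, 180]."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


def visible_cells(cam: CameraCandidate, grid: CoverageGrid) -> set[int]:
    """Cells visible to a camera: radius, FOV wedge, and occlusion tests.

    Boundary cells (exactly on the radius or wedge edge) count as visible;
    a tiny epsilon absorbs floating-point noise on those closed boundaries.
    """
    eps = 1e-9
    cx, cy = cam.position
    out: set[int] = set()
    for cid, (x, y) in grid.cells.items():
        dx, dy = x - cx, y - cy
        dist = math.hypot(dx, dy)
        if dist > cam.radius * (1.0 + eps) + eps:
            continue
        if dist > 0:
            bearing = math.degrees(math.atan2(dy, dx))
            if _angle_diff(bearing, cam.heading) > cam.fov / 2.0 + eps:
                continue
        if grid.obstacles:
            ray = LineString([cam.position, (x, y)])
            if any(ray.intersects(o) for o in grid.obstacles):
                continue
        out.add(cid)
    return out


def _coverage_counts(
    selection: Sequence[CameraCandidate], grid: CoverageGrid
) -> dict[int, int]:
    counts = {cid: 0 for cid in grid.cells}
    for cam in selection:
        for cid in visible_cells(cam, grid):
            counts[cid] += 1
    return counts


def cap(
    selection: Sequence[CameraCandidate], grid: CoverageGrid, r: int = 1
) -> float:
    """Covered Area Percentage: percent of cells seen by >= r cameras."""
    if r < 1:
        raise ValueError("redundancy r must be >= 1")
    counts = _coverage_counts(selection, grid)
    covered = sum(1 for c in counts.values() if c >= r)
    return 100.0 * covered / len(grid.cells)


def uap(cap_value: float) -> float:
    """Uncovered Area Percentage = 100 - CAP."""
    if not 0.0 <= cap_value <= 100.0:
        raise ValueError("CAP must lie in [0, 100]")
    return 100.0 - cap_value


def _make_report(
    selection: Sequence[CameraCandidate], grid: CoverageGrid, r: int
) -> CoverageReport:
    counts = _coverage_counts(selection, grid)
    covered = sum(1 for c in counts.values() if c >= r)
    cap_value = 100.0 * covered / len(grid.cells)
    return CoverageReport(
        counts=counts,
        cap=cap_value,
        uap=100.0 - cap_value,
        r=r,
        selection=tuple(c.cam_id for c in selection),
    )


def greedy_plan(
    candidates: Sequence[CameraCandidate],
    grid: CoverageGrid,
    r: int = 1,
    budget: int = 1,
) -> CoverageReport:
    """Greedy marginal-gain selection of up to ``budget`` cameras.

    At each step the candidate adding the most newly r-covered cells is
    selected (ties: lowest cam_id); selection stops at the budget or at zero
    marginal gain.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if r < 1:
        raise ValueError("redundancy r must be >= 1")
    vis = {c.cam_id: visible_cells(c, grid) for c in candidates}
    by_id = {c.cam_id: c for c in candidates}
    counts = {cid: 0 for cid in grid.cells}
    chosen: list[CameraCandidate] = []
    remaining = sorted(by_id)
    while len(chosen) < budget and remaining:
        best_id, best_gain = None, 0
        for cam_id in remaining:
            gain = sum(1 for cid in vis[cam_id] if counts[cid] == r - 1)
            if gain > best_gain:
                best_id, best_gain = cam_id, gain
        if best_id is None:
            break
        chosen.append(by_id[best_id])
        remaining.remove(best_id)
        for cid in vis[best_id]:
            counts[cid] += 1
    return _make_report(chosen, grid, r)


def exhaustive_plan(
    candidates: Sequence[CameraCandidate],
    grid: CoverageGrid,
    r: int = 1,
    budget: int = 1,
) -> CoverageReport:
    """Globally CAP-optimal selection over all subsets of size <= budget.

    Ties resolve to fewer cameras, then lexicographically smallest id tuple.
    Guarded against combinatorial blow-up (> 2^20 subsets): use the greedy
    planner for larger instances.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    n = len(candidates)
    budget = min(budget, n)
    n_subsets = sum(math.comb(n, k) for k in range(1, budget + 1))
    if n_subsets > _EXHAUSTIVE_GUARD:
        raise ValueError(
            f"{n_subsets} candidate subsets exceed the exhaustive-search guard "
            f"({_EXHAUSTIVE_GUARD}); use greedy_plan"
        )
    cand_sorted = sorted(candidates, key=lambda c: c.cam_id)
    cell_ids = sorted(grid.cells)
    cell_pos = {cid: i for i, cid in enumerate(cell_ids)}
    masks = {}
    for c in cand_sorted:
        m = np.zeros(len(cell_ids), dtype=np.int32)
        for cid in visible_cells(c, grid):
            m[cell_pos[cid]] = 1
        masks[c.cam_id] = m
    best: tuple[float, int, tuple[int, ...]] | None = None
    best_sel: tuple[CameraCandidate, ...] = ()
    for k in range(1, budget + 1):
        for combo in itertools.combinations(cand_sorted, k):
            total = sum(masks[c.cam_id] for c in combo)
            covered = int(np.count_nonzero(total >= r))
            key = (-covered, k, tuple(c.cam_id for c in combo))
            if best is None or key < best:
                best = key
                best_sel = combo
    return _make_report(best_sel, grid, r)


def load_plan(path: str | Path) -> tuple[CoverageGrid, list[CameraCandidate]]:
    """Plan file: JSON with domain, obstacles, cell_size and candidates."""
    payload = json.loads(Path(path).read_text())
    grid = CoverageGrid.from_plan(
        Polygon(payload["domain"]),
        float(payload["cell_size"]),
        [Polygon(o) for o in payload.get("obstacles", [])],
    )
    candidates = [
        CameraCandidate(
            int(c["cam_id"]),
            tuple(c["position"]),
            float(c["heading"]),
            float(c["fov"]),
            float(c["radius"]),
        )
        for c in payload["candidates"]
    ]
    return grid, candidates
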