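"""Growth trajectories, growth vectors, local growth rates, merge exclusion.

A growth trajectory is the streamline of the arrival-time gradient integrated
from a visit-1 margin point until it reaches the visit-2 margin.  Streamlines
are the natural path family orthogonal to the interpolated front positions.
Where fronts collide (intrafocus or interfoci merging) the arrival field has
a ridge with a vanishing gradient: trajectories stall there, and such margin
points -- together with points whose paths wander into territory claimed by a
different visit-1 focus -- are excluded from all statistics, since the
margin correspondence is ill-posed after merging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arrival import ArrivalTimeField
from .params import GrowthParams

__all__ = [
    "GrowthTrajectory",
    "GrowthVector",
    "trace_trajectory",
    "trace_trajectories",
    "flag_merging_points",
    "growth_vector",
    "local_growth_rate",
]


@dataclass
class GrowthTrajectory:
    """Polyline from a visit-1 margin point to (ideally) the visit-2 margin."""

    vertices: np.ndarray  # (n, 2) physical mm; first vertex is the margin point
    reached_margin: bool
    merge_excluded: bool = False

    @property
    def arclength_mm(self) -> float:
        if len(self.vertices) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.vertices, axis=0).T)))

    @property
    def start(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def end(self) -> np.ndarray:
        return self.vertices[-1]


@dataclass
class GrowthVector:
    """Straight segment from trajectory start to end (or the epsilon stand-in)."""

    vector_mm: np.ndarray  # (2,)
    is_epsilon: bool = False

    @property
    def length_mm(self) -> float:
        return float(np.hypot(*self.vector_mm))


def trace_trajectories(
    field: ArrivalTimeField,
    points_mm: np.ndarray,
    params: GrowthParams | None = None,
) -> list[GrowthTrajectory]:
    """Integrate arrival-time gradient streamlines from margin points (batch).

    Fixed-step RK2 (midpoint) with step = half the working grid pitch,
    advanced in lock-step over all still-active points.  A trace succeeds
    when it comes within delta of the visit-2 margin (the end point is then
    snapped exactly onto the margin, removing the delta truncation bias); it
    stalls -- ``reached_margin = False`` -- when the interpolated gradient
    magnitude falls below the floor, when it stops making net progress
    (oscillation at an arrival-time ridge), or when the step budget runs out.
    Margin points already within delta of the visit-2 margin have no growth
    and yield a single-vertex trajectory of arclength zero.
    """
    params = params or GrowthParams()
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    n = len(pts)
    h = field.h_mm
    delta = params.delta_mm
    nr, nc = field.T.shape
    rc = field.to_grid(pts)
    if np.any((rc < -1.0) | (rc > np.array([nr, nc], dtype=float))):
        raise ValueError("margin point lies outside the arrival-time grid")

    step = 0.5 * h
    g_min = params.g_min / h  # gradient floor per mm of position
    budget = int(6.0 * max(nr, nc))
    verts: list[list[np.ndarray]] = [[pts[i].copy()] for i in range(n)]
    reached = np.abs(field.interp_phi2(pts)) <= delta  # zero-growth points
    zero_growth = reached.copy()
    active = ~reached
    x = pts.copy()
    window = np.empty((17, n, 2))
    for it in range(budget):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        g1 = field.grad_at_many(x[ai])
        n1 = np.hypot(g1[:, 0], g1[:, 1])
        ok = n1 >= g_min
        # stalled: vanishing gradient (shock / unreached pocket)
        active[ai[~ok]] = False
        ai = ai[ok]
        if len(ai) == 0:
            continue
        d1 = g1[ok] / n1[ok, None]
        g2 = field.grad_at_many(x[ai] + 0.5 * step * d1)
        n2 = np.hypot(g2[:, 0], g2[:, 1])
        d2 = np.where(n2[:, None] >= g_min, g2 / np.maximum(n2[:, None], g_min), d1)
        x[ai] = x[ai] + step * d2
        for i in ai:
            verts[i].append(x[i].copy())
        hit = field.interp_phi2(x[ai]) >= -delta
        reached[ai[hit]] = True
        active[ai[hit]] = False
        # oscillation detection: no net motion over the last 16 steps
        window[it % 17] = x
        if it >= 16:
            prev = window[(it + 1) % 17]
            osc = np.hypot(*(x - prev).T) < h
            stalled = active & osc
            active[stalled] = False
    trajs: list[GrowthTrajectory] = []
    for i in range(n):
        v = np.vstack(verts[i])
        if reached[i] and not zero_growth[i]:
            # snap the end point onto the visit-2 margin
            _, idx = field.tree2.query(v[-1])
            snap = field.margin2_samples[idx]
            if np.hypot(*(snap - v[-1])) > 1e-12:
                v = np.vstack([v, snap])
        if zero_growth[i]:
            v = v[:1]
        trajs.append(GrowthTrajectory(vertices=v, reached_margin=bool(reached[i])))
    return trajs


def trace_trajectory(
    field: ArrivalTimeField,
    point_mm: np.ndarray,
    params: GrowthParams | None = None,
) -> GrowthTrajectory:
    """Trace a single margin point (see :func:`trace_trajectories`)."""
    return trace_trajectories(field, np.asarray(point_mm, dtype=float)[None, :], params)[0]


def flag_merging_points(
    field: ArrivalTimeField,
    trajectories: list[GrowthTrajectory],
    point_components: np.ndarray | None = None,
) -> np.ndarray:
    """Merge-exclusion flags for a set of traced margin points.

    A point is flagged iff (a) its trajectory failed to reach the visit-2
    margin (it stalled at an arrival-time ridge, the front-collision locus),
    or (b) its trajectory enters a cell whose propagated visit-1 component
    label differs from the point's own component (interfoci collision).
    Flags are also written back onto the trajectories.
    """
    flags = np.zeros(len(trajectories), dtype=bool)
    labels1, propagated = field.component_labels()
    n_comp = int(labels1.max())
    nr, nc = propagated.shape
    for i, traj in enumerate(trajectories):
        if not traj.reached_margin:
            flags[i] = True
            continue
        if n_comp <= 1 or len(traj.vertices) < 2:
            continue
        rc = np.rint(field.to_grid(traj.vertices)).astype(int)
        rc[:, 0] = np.clip(rc[:, 0], 0, nr - 1)
        rc[:, 1] = np.clip(rc[:, 1], 0, nc - 1)
        labels_along = propagated[rc[:, 0], rc[:, 1]]
        own = labels_along[labels_along > 0]
        if point_components is not None and len(own):
            # own label = propagated label at the start vertex
            own_label = own[0]
        elif len(own) == 0:
            continue
        else:
            own_label = own[0]
        if np.any((labels_along > 0) & (labels_along != own_label)):
            flags[i] = True
    for traj, f in zip(trajectories, flags):
        traj.merge_excluded = bool(f)
    return flags


def growth_vector(
    traj: GrowthTrajectory,
    outward_normal: np.ndarray,
    epsilon_um: float = 1.0,
) -> GrowthVector:
    """End-minus-start growth vector; epsilon-length outward normal if no growth.

    At margin points having no growth the trajectory is a single point and
    the growth direction is undefined; the surrogate is an epsilon-length
    vector along the outward margin normal.  Only the direction is used by
    downstream statistics, so the value of epsilon is inconsequential.
    """
    if traj.arclength_mm == 0.0 or len(traj.vertices) < 2:
        n = np.asarray(outward_normal, dtype=float)
        n = n / np.hypot(*n)
        return GrowthVector(vector_mm=n * (epsilon_um / 1000.0), is_epsilon=True)
    return GrowthVector(vector_mm=traj.end - traj.start, is_epsilon=False)


def local_growth_rate(traj: GrowthTrajectory, dt_years: float) -> float:
    """Local growth rate v = trajectory arclength / intervisit time (mm/yr)."""
    if dt_years <= 0:
        raise ValueError("intervisit time must be positive")
    return traj.arclength_mm / dt_years
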