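"""Iterative stochastic growth model with timed stochastic retraction.

The simulator reproduces embryonic dendrite development inside the 2D
contour of a reference spanning field.  Starting from an existing main
branch, every 15-minute iteration adds on average B_r branches: the arena
is probed with uniform random target points, each probe's shortest
distance to the tree is capped at the active growth-range radius, one
target is drawn with preference for larger distances (noise parameter k),
and it is connected to the tree node minimising wire plus bf-weighted
path-to-root cost.  At fixed hourly time points a stochastic retraction
shortens the tips of a randomly selected fraction of terminal branches by
the mean retracted-branch cable length of that time bin (removing branches
shorter than that), and adds a compensating fraction of new branches.

All rates, fractions and radii are measured from single-branch tracking
data via :func:`extract_growth_parameters`; no free parameters are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .tree import (
    TimeSeries,
    Tree,
    add_branch,
    dissect_terminal_branches,
    trim_terminal_branch,
)

__all__ = [
    "GrowthParams",
    "GrowthArena",
    "grow_step",
    "retraction_step",
    "simulate_development",
    "extract_growth_parameters",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (16.0, 17.5, 18.5, 19.5, 20.5, 21.5)
_MB_NTYPE = 2  # structure-type tag marking main-branch nodes in simulations


@dataclass(frozen=True)
class GrowthParams:
    """All constants of the growth/retraction simulator.

    Defaults emulate the embryonic study conditions: 15-min iterations from
    16 to 22.5 hrs AEL, growth-range radius 2.5 µm before 19.5 hrs AEL and
    1.81 µm after, target-selection noise k = 0.5, balancing factor
    bf = 0.2 and 100,000 probe points per branch addition.  Retraction
    occurs at six hourly time points with per-time shorten/new fractions
    and shorten lengths (µm) measured from branch-tracking data.
    """

    b_r: float = 4.0
    r_grow_pre: float = 2.5
    r_grow_post: float = 1.81
    k: float = 0.5
    bf: float = 0.2
    n_probe: int = 100_000
    t_start: float = 16.0
    t_retraction_end: float = 19.5
    t_stop: float = 22.5
    dt: float = 0.25
    retraction_times: tuple = (16.5, 17.5, 18.5, 19.5, 20.5, 21.5)
    shorten_fraction: tuple = (0.50, 0.50, 0.45, 0.35, 0.15, 0.05)
    new_fraction: tuple = (0.35, 0.35, 0.25, 0.15, 0.05, 0.02)
    shorten_length: tuple = (1.8, 1.8, 1.8, 1.8, 1.8, 1.8)
    attach_spacing: float = 0.1
    poisson_branching: bool = True

    def __post_init__(self):
        if not (0 <= self.k <= 1 and 0 <= self.bf <= 1):
            raise ValueError("k and bf must lie in [0, 1]")
        if self.r_grow_pre <= 0 or self.r_grow_post <= 0:
            raise ValueError("growth radii must be positive")
        n = len(self.retraction_times)
        for name in ("shorten_fraction", "new_fraction", "shorten_length"):
            vals = getattr(self, name)
            if len(vals) != n:
                raise ValueError(f"{name} must have one entry per retraction time")
        if any(not 0 <= f <= 1 for f in self.shorten_fraction + self.new_fraction):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class GrowthArena:
    """Initial main branch and the 2D contour bounding the simulation."""

    mb: Tree
    contour: Polygon

    def __post_init__(self):
        xy = self.mb.xyz[:, :2]
        inside = shapely.contains_xy(self.contour, xy[:, 0], xy[:, 1])
        on_edge = shapely.dwithin(
            self.contour.exterior, shapely.points(xy[:, 0], xy[:, 1]), 1e-9
        )
        if not np.all(inside | on_edge):
            raise ValueError("main branch must lie inside the contour")


def _mark_mb(tree: Tree) -> Tree:
    ntype = np.full(tree.n_nodes, _MB_NTYPE, dtype=int)
    return replace(tree, ntype=ntype)


def _sample_in_contour(contour: Polygon, n: int, rng) -> np.ndarray:
    """Uniform points inside the contour (rejection sampling in its bbox)."""
    xmin, ymin, xmax, ymax = contour.bounds
    out = []
    have = 0
    for _ in range(50):
        m = max(n - have, 1000)
        cand = rng.uniform((xmin, ymin), (xmax, ymax), size=(m, 2))
        keep = shapely.contains_xy(contour, cand[:, 0], cand[:, 1])
        if keep.any():
            out.append(cand[keep])
            have += int(keep.sum())
        if have >= n:
            break
    if have == 0:
        raise ValueError("degenerate arena: no probe point falls inside contour")
    return np.concatenate(out)[:n]


def _add_one_branch(
    state: Tree, contour: Polygon, p: GrowthParams, radius: float, rng
) -> Tree:
    """One branch addition; returns the (possibly unchanged) tree."""
    probes = _sample_in_contour(contour, p.n_probe, rng)
    kd = cKDTree(state.xyz[:, :2])
    d, _ = kd.query(probes)
    d = np.minimum(d, radius)
    candidates = d > 1e-6
    if not candidates.any():
        return state
    if p.k >= 1.0:
        weights = np.zeros(len(d))
        weights[np.argmax(np.where(candidates, d, -np.inf))] = 1.0
    elif p.k <= 0.0:
        weights = candidates.astype(float)
    else:
        gamma = p.k / (1.0 - p.k)
        weights = np.where(candidates, d**gamma, 0.0)
    weights = weights / weights.sum()
    plen = state.path_length_to_root()
    for _ in range(5):
        target = probes[rng.choice(len(probes), p=weights)]
        dist = np.linalg.norm(state.xyz[:, :2] - target, axis=1)
        cost = dist + p.bf * (plen + dist)
        attach = int(np.lexsort((np.arange(len(cost)), cost))[0])
        seg = target - state.xyz[attach, :2]
        seg_len = float(np.linalg.norm(seg))
        if seg_len <= 1e-9:
            continue
        step = min(seg_len, radius)
        direction = seg / seg_len
        tip = state.xyz[attach, :2] + direction * step
        if not shapely.contains_xy(contour, tip[0], tip[1]):
            continue
        n_int = max(int(np.ceil(step / p.attach_spacing)), 1)
        offsets = np.linspace(step / n_int, step, n_int)
        points = state.xyz[attach, :2][None, :] + direction[None, :] * offsets[:, None]
        return add_branch(state, attach, points)
    return state


def grow_step(
    state: Tree,
    arena: GrowthArena,
    p: GrowthParams,
    rng: np.random.Generator,
    radius: float | None = None,
    n_branches: int | None = None,
) -> Tree:
    """One 15-minute growth iteration: add ~B_r branches.

    ``n_branches`` defaults to a Poisson draw with mean ``p.b_r`` (or the
    rounded rate with ``poisson_branching=False``).
    """
    if radius is None:
        radius = p.r_grow_pre
    if n_branches is None:
        n_branches = (
            int(rng.poisson(p.b_r)) if p.poisson_branching else int(round(p.b_r))
        )
    for _ in range(n_branches):
        state = _add_one_branch(state, arena.contour, p, radius, rng)
    return state


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _lateral_terminal_branches(state: Tree):
    """Terminal branches excluding the main branch's own tip piece."""
    return [
        tb
        for tb in dissect_terminal_branches(state)
        if state.ntype[tb.tip] != _MB_NTYPE
    ]


def retraction_step(
    state: Tree,
    arena: GrowthArena,
    p: GrowthParams,
    shorten_fraction: float,
    shorten_length: float,
    new_fraction: float,
    radius: float,
    rng: np.random.Generator,
) -> Tree:
    """One timed stochastic retraction: shorten the tips of a random
    fraction of terminal branches by ``shorten_length`` µm (branches no
    longer than that are removed entirely), then add a ``new_fraction``
    of new branches through the growth machinery."""
    terminals = _lateral_terminal_branches(state)
    n_term = len(terminals)
    if n_term and shorten_fraction > 0:
        n_sel = max(_round_half_up(shorten_fraction * n_term), 1)
        n_sel = min(n_sel, n_term)
        chosen = rng.choice(n_term, size=n_sel, replace=False)
        tip_ids = [int(state.node_ids[terminals[i].tip]) for i in chosen]
        for tip_id in tip_ids:
            idx = np.flatnonzero(state.node_ids == tip_id)
            if len(idx) == 0:
                continue  # branch vanished in an earlier merge
            tb = next(
                (b for b in dissect_terminal_branches(state) if b.tip == idx[0]), None
            )
            if tb is None:
                continue
            state, _ = trim_terminal_branch(state, tb, shorten_length)
    if n_term and new_fraction > 0:
        n_new = _round_half_up(new_fraction * n_term)
        for _ in range(n_new):
            state = _add_one_branch(state, arena.contour, p, radius, rng)
    return state


def simulate_development(
    arena: GrowthArena,
    p: GrowthParams,
    seed: int | None = None,
    with_retraction: bool = True,
) -> TimeSeries:
    """Simulate development from ``t_start`` to ``t_stop`` at ``dt`` (hr)
    resolution.

    With retraction enabled, growth iterations run until
    ``t_retraction_end`` (the growth radius switching from ``r_grow_pre``
    to ``r_grow_post`` there) and retraction steps fire at
    ``retraction_times``; without retraction the model reduces to pure
    growth until ``t_stop``.  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    state = _mark_mb(arena.mb)
    times = [p.t_start]
    frames = [state]
    n_steps = int(round((p.t_stop - p.t_start) / p.dt))
    retraction_set = {round(t, 6): i for i, t in enumerate(p.retraction_times)}
    for step in range(1, n_steps + 1):
        t = p.t_start + step * p.dt
        radius = p.r_grow_pre if t <= p.t_retraction_end else p.r_grow_post
        growing = (t <= p.t_retraction_end) if with_retraction else True
        if growing:
            state = grow_step(state, arena, p, rng, radius=radius)
        key = round(t, 6)
        if with_retraction and key in retraction_set:
            i = retraction_set[key]
            state = retraction_step(
                state,
                arena,
                p,
                shorten_fraction=p.shorten_fraction[i],
                shorten_length=p.shorten_length[i],
                new_fraction=p.new_fraction[i],
                radius=radius,
                rng=rng,
            )
        times.append(t)
        frames.append(state)
    return TimeSeries(times=np.array(times), trees=frames)


def extract_growth_parameters(
    series: TimeSeries,
    events,
    bin_edges=DEFAULT_BIN_EDGES,
    base: GrowthParams | None = None,
) -> GrowthParams:
    """Measure simulator constants from a registered time series and its
    branch events.

    B_r is the mean branch-point increment per 15-minute interval between
    ``t_start`` and ``t_retraction_end``; per-bin shorten fractions combine
    the retracting and shortening class fractions; new fractions are the
    newly-formed class fractions; shorten lengths are the mean initial
    lengths of retracted branches; the growth radii are the mean lengths of
    newly formed branches before/after ``t_retraction_end``.
    """
    from .tracking import dynamics_summary

    if base is None:
        base = GrowthParams()
    counts = series.branch_point_counts().astype(float)
    t = series.times
    mask = (t >= base.t_start - 1e-9) & (t <= base.t_retraction_end + 1e-9)
    tt, cc = t[mask], counts[mask]
    if len(tt) < 2:
        raise ValueError("series does not cover the growth phase")
    increments = np.diff(cc) / (np.diff(tt) / base.dt)
    # a net-loss window yields no growth iterations rather than a negative rate
    b_r = float(max(np.mean(increments), 0.0))

    summary = dynamics_summary(events, bin_edges)
    empty = summary[summary["n_events"] == 0]
    if len(empty):
        missing = [f"({row.bin_start}, {row.bin_end}]" for row in empty.itertuples()]
        raise ValueError(f"no events in bins: {', '.join(missing)}")

    edges = np.asarray(bin_edges, dtype=float)

    def bin_of(time: float) -> int:
        i = int(np.searchsorted(edges, time, side="left")) - 1
        return int(np.clip(i, 0, len(edges) - 2))

    shorten_fraction, new_fraction, shorten_length = [], [], []
    overall_retr = events.loc[
        events["dynamics_class"] == "retracted", "length_t0"
    ].mean()
    for rt in base.retraction_times:
        row = summary.iloc[bin_of(rt)]
        shorten_fraction.append(float(row["frac_retracted"] + row["frac_shortened"]))
        new_fraction.append(float(row["frac_new"]))
        sl = row["mean_retracted_length"]
        shorten_length.append(float(sl if np.isfinite(sl) else (overall_retr if np.isfinite(overall_retr) else 0.0)))

    new_events = events[events["dynamics_class"] == "new"]
    pre = new_events[new_events["t1"] <= base.t_retraction_end]["length_t1"]
    post = new_events[new_events["t1"] > base.t_retraction_end]["length_t1"]
    r_pre = float(pre.mean()) if len(pre) else base.r_grow_pre
    r_post = float(post.mean()) if len(post) else base.r_grow_post

    return replace(
        base,
        b_r=b_r,
        r_grow_pre=r_pre,
        r_grow_post=r_post,
        shorten_fraction=tuple(shorten_fraction),
        new_fraction=tuple(new_fraction),
        shorten_length=tuple(shorten_length),
    )
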