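"""Synthetic-data generators with ground truth for every pipeline stage.

The generators emulate the statistics of embryonic comb-like c1vpda
dendrites — a long vertical main branch carrying long, near-perpendicular
second-order lateral branches (median length ~6 µm, angles peaked near
60-65 deg) and short higher-order branches (median ~1.6-2 µm, broad flat
angle distribution) — along with 1-hour time-lapse series with planted
per-branch events, and soma-triplet peristalsis trajectories with coupled
fluorescence transients.  Every generator is deterministic under a seed
and returns its planted parameters as ground truth so each estimator in
the package has a parameter-recovery test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .calcium import TripletTrajectory
from .growth import GrowthArena
from .tree import TimeSeries, Tree, add_branch, remove_terminal_branch, trim_terminal_branch, dissect_terminal_branches

__all__ = [
    "CombParams",
    "TimelapseParams",
    "PeristalsisParams",
    "make_comb_tree",
    "make_timelapse",
    "make_peristalsis",
    "make_arena",
]


@dataclass(frozen=True)
class CombParams:
    """Shape statistics of the synthetic comb.

    Lateral lengths are log-normal with the given medians; orientation
    angles (degrees, 0 = along the MB, 90 = anteroposterior) are normal
    for second-order branches and near-flat for higher-order ones, both
    clipped to [0, 90].
    """

    mb_length: float = 30.0
    n_laterals: int = 12
    second_order_median_length: float = 6.0
    second_order_length_sigma: float = 0.35
    higher_order_median_length: float = 1.8
    higher_order_length_sigma: float = 0.35
    second_order_angle_mean: float = 63.0
    second_order_angle_sd: float = 8.0
    higher_order_angle_low: float = 5.0
    higher_order_angle_high: float = 85.0
    mean_children_per_lateral: float = 1.0
    jitter: float = 0.0
    node_spacing: float = 0.5

    def __post_init__(self):
        if self.mb_length <= 0 or self.node_spacing <= 0:
            raise ValueError("lengths must be positive")
        for a in (self.second_order_angle_mean, self.higher_order_angle_low,
                  self.higher_order_angle_high):
            if not 0 <= a <= 90:
                raise ValueError("angle parameters must lie in [0, 90]")


def _polyline(start: np.ndarray, direction: np.ndarray, length: float, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(length / spacing)), 1)
    offs = np.linspace(length / n, length, n)
    return start[None, :] + direction[None, :] * offs[:, None]


def make_comb_tree(
    p: CombParams = CombParams(), seed: int | None = None
) -> tuple[Tree, pd.DataFrame]:
    """Generate a comb tree plus its ground-truth branch table.

    The MB runs from the root at the origin straight up the y-axis.
    Second-order laterals attach at evenly spaced MB heights, alternating
    sides; higher-order branches sprout from the middle portion of their
    parent lateral and are kept shorter than the remaining parent cable so
    the planted branch-length ordering is unambiguous.  Returns
    ``(tree, truth)`` where ``truth`` has one row per planted branch with
    its true blo, order class, length and angle.
    """
    rng = np.random.default_rng(seed)
    sp = p.node_spacing
    mb_pts = _polyline(np.zeros(2), np.array([0.0, 1.0]), p.mb_length, sp)
    xyz = np.column_stack([np.vstack([np.zeros(2), mb_pts]), np.zeros(len(mb_pts) + 1)])
    parent = np.arange(-1, len(mb_pts))
    tree = Tree(xyz=xyz, radii=np.full(len(xyz), 0.25), parent=parent)
    truth_rows = []

    if p.n_laterals > 0:
        heights = np.linspace(0.15, 0.92, p.n_laterals) * p.mb_length
        for j, h in enumerate(heights):
            side = 1.0 if j % 2 == 0 else -1.0
            length = float(
                np.exp(np.log(p.second_order_median_length)
                       + p.second_order_length_sigma * rng.standard_normal())
            )
            ang = float(np.clip(
                rng.normal(p.second_order_angle_mean, p.second_order_angle_sd), 0, 90
            ))
            theta = np.radians(ang)
            direction = np.array([side * np.sin(theta), np.cos(theta)])
            attach = int(np.argmin(np.abs(tree.xyz[: len(mb_pts) + 1, 1] - h)
                                   + 1e6 * (np.abs(tree.xyz[: len(mb_pts) + 1, 0]) > 1e-9)))
            start = tree.xyz[attach, :2]
            pts = _polyline(start, direction, length, sp)
            first_new = tree.n_nodes
            tree = add_branch(tree, attach, pts)
            truth_rows.append(dict(
                branch="lateral", parent_branch=-1, blo=1, order_class="second",
                length=length, angle=ang, attach_node=attach,
                tip_node=tree.n_nodes - 1,
            ))
            # higher-order children sprout from the middle of the lateral
            n_children = rng.poisson(p.mean_children_per_lateral)
            lat_nodes = np.arange(first_new, tree.n_nodes)
            for _ in range(n_children):
                if len(lat_nodes) < 4:
                    break
                pos = int(rng.integers(1, max(len(lat_nodes) // 2, 2)))
                attach2 = int(lat_nodes[pos])
                remaining = length * (1 - (pos + 1) / len(lat_nodes))
                child_len = float(np.exp(
                    np.log(p.higher_order_median_length)
                    + p.higher_order_length_sigma * rng.standard_normal()
                ))
                child_len = min(child_len, max(remaining * 0.8, sp))
                ang2 = float(rng.uniform(p.higher_order_angle_low, p.higher_order_angle_high))
                th2 = np.radians(ang2)
                d2 = np.array([side * np.sin(th2), -np.cos(th2)])
                pts2 = _polyline(tree.xyz[attach2, :2], d2, child_len, sp)
                tree = add_branch(tree, attach2, pts2)
                truth_rows.append(dict(
                    branch="higher", parent_branch=j, blo=2, order_class="higher",
                    length=child_len, angle=ang2, attach_node=attach2,
                    tip_node=tree.n_nodes - 1,
                ))

    if p.jitter > 0:
        xyz = tree.xyz.copy()
        noise = rng.normal(0, p.jitter, size=(tree.n_nodes, 2))
        noise[tree.root] = 0
        xyz[:, :2] += noise
        tree = Tree(xyz=xyz, radii=tree.radii, parent=tree.parent, ntype=tree.ntype)

    truth = pd.DataFrame(
        truth_rows,
        columns=["branch", "parent_branch", "blo", "order_class", "length",
                 "angle", "attach_node", "tip_node"],
    )
    return tree, truth


# ---------------------------------------------------------------------------
# Time-lapse generator


@dataclass(frozen=True)
class TimelapseParams:
    """Planted per-interval branch dynamics.

    ``class_fractions`` maps each dynamics class to its per-interval
    probability (one tuple entry per frame interval); rates are µm/hr,
    centred between 2 and 3 as in embryonic single-branch tracking.
    """

    times: tuple = (16.5, 17.5, 18.5, 19.5, 20.5, 21.5)
    frac_retracted: tuple = (0.30, 0.30, 0.25, 0.10, 0.05)
    frac_shortened: tuple = (0.20, 0.20, 0.20, 0.15, 0.10)
    frac_elongated: tuple = (0.20, 0.20, 0.20, 0.25, 0.25)
    frac_new_per_existing: tuple = (0.30, 0.25, 0.15, 0.05, 0.02)
    rate_mean: float = 2.5
    rate_sd: float = 0.5
    resolution: float = 0.3

    def __post_init__(self):
        n = len(self.times) - 1
        for name in ("frac_retracted", "frac_shortened", "frac_elongated",
                     "frac_new_per_existing"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} needs {n} entries (one per interval)")


def _draw_rate(p: TimelapseParams, rng) -> float:
    return float(abs(rng.normal(p.rate_mean, p.rate_sd)))


def _removal_is_clean(tree: Tree, tb, registered_tips: set[int]) -> bool:
    """A terminal-branch removal is clean when it cannot change the
    dissected length of any other registered terminal branch: the origin
    either keeps >= 2 children, or the surviving sibling chain reaches a
    branch point or an unregistered tip before terminating."""
    ch = tree.children()
    o = tb.origin
    first_on_branch = tb.node_path[1]
    siblings = [c for c in ch[o] if c != first_on_branch]
    if len(siblings) >= 2:
        return True
    if not siblings:
        return True  # removing the only child (path-graph tail)
    node = siblings[0]
    while len(ch[node]) == 1:
        node = ch[node][0]
    if len(ch[node]) >= 2:
        return True
    return node not in registered_tips


def _clean_attach_nodes(tree: Tree, registered_tips: set[int]) -> np.ndarray:
    """Cable nodes where a new branch can sprout without splitting a
    registered terminal branch (interior cable and branch points)."""
    nchild = tree.n_children()
    blocked = np.zeros(tree.n_nodes, dtype=bool)
    for tb in dissect_terminal_branches(tree):
        if tb.tip in registered_tips:
            blocked[list(tb.node_path[1:])] = True
    ok = (nchild >= 1) & ~blocked
    ok[tree.root] = False
    return np.flatnonzero(ok)


def make_timelapse(
    p: TimelapseParams, base: Tree, seed: int | None = None
) -> tuple[TimeSeries, pd.DataFrame]:
    """Apply planted events frame by frame to ``base``.

    Each interval assigns the planted numbers of retracted, shortened and
    elongated events to randomly chosen registered terminal branches (the
    rest stay stable) and sprouts new branches from random cable
    locations.  Removals and sprout sites are restricted to positions
    where the edit cannot silently change the dissected length of another
    registered branch, so the returned event table is exact ground truth
    for the tracking stage.  The main branch's own terminal piece is left
    out of the registration.  Returns ``(series, truth)`` with the truth
    schema matching :func:`combmorph.tracking.classify_dynamics`.
    """
    rng = np.random.default_rng(seed)
    tree = base
    plen = tree.path_length_to_root()
    mb_tip_id = int(tree.node_ids[int(np.argmax(plen))])
    next_track = 0
    tip_track: dict[int, int] = {}
    for tb in dissect_terminal_branches(tree):
        nid = int(tree.node_ids[tb.tip])
        if nid == mb_tip_id:
            continue
        tip_track[nid] = next_track
        next_track += 1
    reg_rows = [
        dict(frame=0, node_id=nid, track_id=tr) for nid, tr in tip_track.items()
    ]
    frames = [tree]
    truth_rows = []
    for k, (t0, t1) in enumerate(zip(p.times[:-1], p.times[1:])):
        dt = t1 - t0
        new_tip_track: dict[int, int] = {}
        tbs = [
            tb for tb in dissect_terminal_branches(tree)
            if int(tree.node_ids[tb.tip]) in tip_track
        ]
        n = len(tbs)
        n_r = int(round(p.frac_retracted[k] * n))
        n_s = int(round(p.frac_shortened[k] * n))
        n_e = int(round(p.frac_elongated[k] * n))
        perm = list(rng.permutation(n))
        lengths0 = {int(tree.node_ids[tb.tip]): tb.length for tb in tbs}

        def emit(track, cls, delta, length0):
            truth_rows.append(dict(
                branch_id=track, t0=t0, t1=t1, dynamics_class=cls,
                length_t0=length0,
                length_t1=max(length0 + delta, 0.0) if cls != "retracted" else 0.0,
                delta_length=delta, rate=delta / dt,
            ))

        # removals first, only where they cannot corrupt other branches
        tip_nids = [int(tree.node_ids[tb.tip]) for tb in tbs]
        removed = 0
        survivors = []
        for j in perm:
            nid = tip_nids[j]
            idx = np.flatnonzero(tree.node_ids == nid)
            tb = next((b for b in dissect_terminal_branches(tree) if b.tip == idx[0]), None)
            reg_tips = {
                int(np.flatnonzero(tree.node_ids == m)[0])
                for m in lengths0 if (tree.node_ids == m).any()
            }
            if removed < n_r and tb is not None and _removal_is_clean(tree, tb, reg_tips):
                tree, _ = remove_terminal_branch(tree, tb)
                emit(tip_track[nid], "retracted", -lengths0[nid], lengths0[nid])
                removed += 1
            else:
                survivors.append(nid)

        # shorten / elongate / stabilise the survivors
        for pos, nid in enumerate(survivors):
            track = tip_track[nid]
            length0 = lengths0[nid]
            idx = np.flatnonzero(tree.node_ids == nid)
            tb = next((b for b in dissect_terminal_branches(tree) if b.tip == idx[0]), None)
            if tb is None:
                continue
            if pos < n_s:
                amount = min(_draw_rate(p, rng) * dt, tb.length * 0.6)
                amount = max(amount, min(2.5 * p.resolution, tb.length * 0.6))
                tree, index_map = trim_terminal_branch(tree, tb, amount)
                surviving = index_map[list(tb.node_path)]
                new_nid = int(tree.node_ids[surviving[surviving >= 0][-1]])
                new_tip_track[new_nid] = track
                emit(track, "shortened", -amount, length0)
            elif pos < n_s + n_e:
                amount = max(_draw_rate(p, rng) * dt, 2.5 * p.resolution)
                tip_idx = int(idx[0])
                par = int(tree.parent[tip_idx])
                direction = tree.xyz[tip_idx, :2] - tree.xyz[par, :2]
                nrm = np.linalg.norm(direction)
                direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0])
                pts = _polyline(tree.xyz[tip_idx, :2], direction, amount, 0.5)
                tree = add_branch(tree, tip_idx, pts)
                new_nid = int(tree.node_ids[tree.n_nodes - 1])
                new_tip_track[new_nid] = track
                emit(track, "elongated", amount, length0)
            else:
                new_tip_track[nid] = track
                emit(track, "stable", 0.0, length0)

        # planted new branches from clean cable locations
        n_new = int(round(p.frac_new_per_existing[k] * n))
        for _ in range(n_new):
            reg_tips = {
                int(np.flatnonzero(tree.node_ids == m)[0])
                for m in new_tip_track if (tree.node_ids == m).any()
            }
            sites = _clean_attach_nodes(tree, reg_tips)
            if len(sites) == 0:
                break
            attach = int(rng.choice(sites))
            length = max(_draw_rate(p, rng) * dt, 0.6)
            theta = np.radians(rng.uniform(10, 80))
            side = rng.choice([-1.0, 1.0])
            direction = np.array(
                [side * np.sin(theta), np.cos(theta) * rng.choice([-1.0, 1.0])]
            )
            pts = _polyline(tree.xyz[attach, :2], direction, length, 0.5)
            tree = add_branch(tree, attach, pts)
            nid = int(tree.node_ids[tree.n_nodes - 1])
            new_tip_track[nid] = next_track
            emit(next_track, "new", length, 0.0)
            next_track += 1

        tip_track = new_tip_track
        frames.append(tree)
        reg_rows.extend(
            dict(frame=k + 1, node_id=nid, track_id=tr)
            for nid, tr in tip_track.items()
        )

    series = TimeSeries(
        times=np.asarray(p.times, dtype=float),
        trees=frames,
        registration=pd.DataFrame(reg_rows, columns=["frame", "node_id", "track_id"]),
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["branch_id", "t0", "t1", "dynamics_class", "length_t0",
                 "length_t1", "delta_length", "rate"],
    )
    return series, truth


# ---------------------------------------------------------------------------
# Peristalsis / calcium generator


@dataclass(frozen=True)
class PeristalsisParams:
    """Sinusoid-plus-noise soma kinematics with a coupled fluorescence
    transient of configurable lag (s) and Pearson correlation."""

    n_frames: int = 200
    frame_interval: float = 0.2
    rest_distance: float = 60.0
    contraction_amplitude: float = 20.0
    period: float = 8.0
    onset: float = 10.0
    lag: float = 0.2
    pearson_r: float = 0.85
    position_noise: float = 0.0
    signal_amplitude: float = 1.5
    baseline_ratio: float = 0.8

    def __post_init__(self):
        if not 0 < self.pearson_r <= 1:
            raise ValueError("pearson_r must lie in (0, 1]")
        if self.lag % self.frame_interval > 1e-9:
            raise ValueError("lag must be a multiple of the frame interval")


def make_peristalsis(
    p: PeristalsisParams = PeristalsisParams(), seed: int | None = None
) -> tuple[TripletTrajectory, pd.DataFrame, dict]:
    """Soma-triplet trajectory plus a lagged, noise-coupled ratio trace.

    Contraction follows smooth bumps after ``onset``; the fluorescence
    transient is the contraction waveform shifted by ``lag`` with Gaussian
    noise scaled so the planted Pearson correlation with the contraction
    is ``pearson_r`` in expectation.  Returns the trajectory, a trace
    DataFrame (times, F_g, F_t) and the ground-truth dict.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(p.n_frames) * p.frame_interval
    phase = np.clip((t - p.onset) / p.period, 0, None)
    bump = np.where(
        (t >= p.onset) & (t <= p.onset + p.period),
        np.sin(np.pi * np.clip((t - p.onset) / p.period, 0, 1)) ** 2,
        0.0,
    )
    d = p.rest_distance - p.contraction_amplitude * bump
    half = d / 2
    central = np.zeros((p.n_frames, 2))
    anterior = np.column_stack([-half, np.zeros(p.n_frames)])
    posterior = np.column_stack([half, np.zeros(p.n_frames)])
    if p.position_noise > 0:
        anterior += rng.normal(0, p.position_noise, anterior.shape)
        posterior += rng.normal(0, p.position_noise, posterior.shape)
    traj = TripletTrajectory(times=t, central=central, anterior=anterior, posterior=posterior)

    lag_frames = int(round(p.lag / p.frame_interval))
    waveform = np.roll(bump, lag_frames)
    waveform[:lag_frames] = 0.0
    sd_wave = waveform.std()
    noise_sd = sd_wave * np.sqrt(1 / p.pearson_r**2 - 1)
    signal = p.signal_amplitude * (waveform + rng.normal(0, noise_sd, p.n_frames))
    ratio = p.baseline_ratio * (1.0 + signal)
    f_t = np.full(p.n_frames, 100.0)
    trace = pd.DataFrame({"times": t, "F_g": ratio * f_t, "F_t": f_t})
    truth = dict(
        lag=p.lag,
        pearson_r=p.pearson_r,
        contraction_peak_frame=int(np.argmax(bump)),
        signal_amplitude=p.signal_amplitude,
    )
    return traj, trace, truth


# ---------------------------------------------------------------------------
# Growth arena


def make_arena(
    width: float = 14.0,
    height: float = 26.0,
    mb_length: float = 22.0,
    node_spacing: float = 0.5,
) -> GrowthArena:
    """Rectangular growth arena with a vertical main branch up its centre."""
    contour = box(-width / 2, -2.0, width / 2, height - 2.0)
    pts = _polyline(np.zeros(2), np.array([0.0, 1.0]), mb_length, node_spacing)
    xyz = np.column_stack([np.vstack([np.zeros(2), pts]), np.zeros(len(pts) + 1)])
    mb = Tree(xyz=xyz, radii=np.full(len(xyz), 0.25), parent=np.arange(-1, len(pts)))
    return GrowthArena(mb=mb, contour=contour)
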