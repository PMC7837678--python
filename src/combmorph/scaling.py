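"""Wire-optimality scaling law and minimum-spanning-tree synthetic trees.

For planar dendrites that minimise wiring cost, total cable length L,
spanning-field area S and the number of branch points N obey

    L ~ sqrt(S * N / pi).

Synthetic trees are grown with a greedy minimum-spanning-tree (MST) rule:
uniformly scattered target points are connected one at a time to the
existing tree at the node minimising

    wire cost + bf * path cost  =  d + bf * (plen + d),

where d is the Euclidean connection distance, plen the path length of the
attachment node to the root, and bf the balancing factor trading total
cable against path length to the soma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .tree import Tree

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingTriple",
    "scaling_law_L",
    "generate_mst_tree",
    "mst_scaling_ensemble",
    "scale_to_area",
    "fit_scaling",
]


@dataclass(frozen=True)
class ScalingTriple:
    """(N branch points, L total length µm, S spanning area µm²)."""

    N: int
    L: float
    S: float

    def __post_init__(self):
        if self.N < 0 or self.L <= 0 or self.S < 0:
            raise ValueError("require N >= 0, L > 0, S >= 0")


def scaling_law_L(S: float, N: float) -> float:
    """Total length predicted by the optimal-wire scaling law, sqrt(S·N/π)."""
    if S < 0 or N < 0:
        raise ValueError("S and N must be non-negative")
    return float(np.sqrt(S * N / np.pi))


def _greedy_mst(
    targets: np.ndarray, root: np.ndarray, bf: float
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Vectorised greedy MST construction.

    Returns all points (root first), parent indices and the order in which
    targets were connected.  Coincident duplicate targets are skipped with
    a log entry.  Ties in the combined cost break to the lowest target
    index (stable lexsort on cost then index).
    """
    pts = np.vstack([root[None, :], targets])
    n = len(pts)
    parent = np.full(n, -1, dtype=int)
    plen = np.zeros(n)
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    d0 = np.linalg.norm(pts - root, axis=1)
    best_cost = d0 + bf * d0
    best_node = np.zeros(n, dtype=int)
    best_cost[0] = np.inf
    order: list[int] = []
    for _ in range(n - 1):
        masked = np.where(in_tree, np.inf, best_cost)
        i = int(np.lexsort((np.arange(n), masked))[0])
        p = int(best_node[i])
        d = float(np.linalg.norm(pts[i] - pts[p]))
        if d == 0.0:
            logger.info("skipping duplicate target coincident with node %d", p)
            in_tree[i] = True
            continue
        parent[i] = p
        plen[i] = plen[p] + d
        in_tree[i] = True
        order.append(i)
        dd = np.linalg.norm(pts - pts[i], axis=1)
        cand = dd + bf * (plen[i] + dd)
        upd = (~in_tree) & (cand < best_cost)
        best_cost[upd] = cand[upd]
        best_node[upd] = i
    return pts, parent, order


def generate_mst_tree(
    targets: np.ndarray, root: np.ndarray | None = None, bf: float = 0.2
) -> Tree:
    """Grow a greedy MST over 2D ``targets`` from ``root``.

    ``bf`` in [0, 1]: 0 minimises wire only; larger values also penalise
    the path length from each new node to the root.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if targets.shape[1] != 2:
        raise ValueError("targets must be (n, 2)")
    if len(targets) < 1:
        raise ValueError("need at least one target")
    if not 0 <= bf <= 1:
        raise ValueError("bf must be in [0, 1]")
    if root is None:
        root = targets.mean(axis=0)
    root = np.asarray(root, dtype=float)
    pts, parent, _ = _greedy_mst(targets, root, bf)
    keep = (parent >= 0) | (np.arange(len(pts)) == 0)
    index_map = np.full(len(pts), -1)
    index_map[keep] = np.arange(keep.sum())
    xyz = np.column_stack([pts[keep], np.zeros(keep.sum())])
    new_parent = np.where(parent[keep] >= 0, index_map[np.maximum(parent[keep], 0)], -1)
    return Tree(xyz=xyz, radii=np.full(keep.sum(), 0.25), parent=new_parent)


def mst_scaling_ensemble(
    n_sims: int = 100,
    max_targets: int = 500,
    bf: float = 0.2,
    area: float = 100.0,
    seed: int | None = None,
    checkpoint_step: int = 25,
    region: str = "square",
) -> pd.DataFrame:
    """Scaling triples from an ensemble of greedy MST simulations.

    Each simulation scatters ``max_targets`` points uniformly over a region
    of the given area (square by default, ``region="circle"`` optional)
    with the root at its centre, grows the MST, and records (N, L, S) at
    every ``checkpoint_step`` connected targets — a scaled-down version of
    recording a tree at every target count.
    """
    rng = np.random.default_rng(seed)
    side = np.sqrt(area)
    rows = []
    for sim in range(n_sims):
        if region == "square":
            targets = rng.uniform(0, side, size=(max_targets, 2))
            root = np.array([side / 2, side / 2])
        elif region == "circle":
            r = np.sqrt(rng.uniform(0, 1, max_targets)) * np.sqrt(area / np.pi)
            phi = rng.uniform(0, 2 * np.pi, max_targets)
            targets = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
            root = np.zeros(2)
        else:
            raise ValueError(f"unknown region {region!r}")
        pts, parent, order = _greedy_mst(targets, root, bf)
        n_children = np.zeros(len(pts), dtype=int)
        L = 0.0
        in_tree = np.zeros(len(pts), dtype=bool)
        in_tree[0] = True
        for cnt, i in enumerate(order, start=1):
            p = parent[i]
            L += float(np.linalg.norm(pts[i] - pts[p]))
            n_children[p] += 1
            in_tree[i] = True
            if cnt % checkpoint_step == 0 or cnt == len(order):
                N = int(np.sum(n_children >= 2))
                S = geometry.spanning_area(pts[in_tree], method="convex")
                if N >= 1 and L > 0 and S > 0:
                    rows.append(dict(sim=sim, n_targets=cnt, N=N, L=L, S=S))
    return pd.DataFrame(rows)


def scale_to_area(
    tree: Tree,
    target_area: float = 100.0,
    method: str = "convex",
    rel_tol: float = 1e-3,
    max_iter: int = 30,
) -> Tree:
    """Isotropically rescale x, y so the spanning area equals ``target_area``.

    The convex spanning field scales exactly with the square of the factor,
    so one step suffices; concave areas are iterated to within ``rel_tol``.
    """
    t = tree
    for _ in range(max_iter):
        S = geometry.spanning_area(t, method=method)
        if S <= 0:
            raise ValueError("degenerate tree: zero spanning area")
        if abs(S - target_area) <= rel_tol * target_area:
            return t
        t = t.scaled_xy(np.sqrt(target_area / S))
    return t


def fit_scaling(
    triples, target_area: float = 100.0
) -> tuple[float, float, float]:
    """OLS fit of L against sqrt(N) after normalising every tree's length
    to a common spanning area.

    Accepts ScalingTriples or a DataFrame with columns N, L, S.  Returns
    ``(slope, intercept, r_squared)``.
    """
    if isinstance(triples, pd.DataFrame):
        N = triples["N"].to_numpy(dtype=float)
        L = triples["L"].to_numpy(dtype=float)
        S = triples["S"].to_numpy(dtype=float)
    else:
        N = np.array([t.N for t in triples], dtype=float)
        L = np.array([t.L for t in triples], dtype=float)
        S = np.array([t.S for t in triples], dtype=float)
    if len(N) < 3:
        raise ValueError("need at least 3 trees to fit the scaling law")
    Ln = L * np.sqrt(target_area / S)
    x = np.sqrt(N)
    if np.ptp(x) == 0:
        raise ValueError("constant sqrt(N): slope undefined")
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, Ln, rcond=None)
    resid = Ln - A @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((Ln - Ln.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return float(coef[0]), float(coef[1]), float(r2)
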