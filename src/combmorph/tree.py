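"""Rooted geometric tree model and SWC I/O.

A dendrite reconstruction is a rooted tree of 3D points with radii and
parent links.  All geometric analyses in this package treat trees as planar
(x, y); z is carried through unchanged.  Lengths are in micrometres.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tree",
    "TerminalBranch",
    "TimeSeries",
    "SWCFormatError",
    "read_swc",
    "write_swc",
    "resample_tree",
    "dissect_terminal_branches",
    "counts_and_lengths",
    "remove_terminal_branch",
    "trim_terminal_branch",
    "add_branch",
]


class SWCFormatError(ValueError):
    """Raised for malformed SWC input (multiple roots, dangling parents...)."""


@dataclass(frozen=True)
class Tree:
    """Rooted tree of nodes with coordinates, radii and parent indices.

    Parameters
    ----------
    xyz
        ``(n, 3)`` node coordinates in µm.
    radii
        ``(n,)`` node radii in µm.
    parent
        ``(n,)`` integer index of each node's parent; the single root
        carries ``-1``.
    node_ids
        Original SWC sample ids (1-based); regenerated when absent.
    ntype
        SWC structure-type column, carried for round-tripping.
    """

    xyz: np.ndarray
    radii: np.ndarray
    parent: np.ndarray
    node_ids: np.ndarray | None = None
    ntype: np.ndarray | None = None

    def __post_init__(self):
        xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        radii = np.asarray(self.radii, dtype=float)
        parent = np.asarray(self.parent, dtype=int)
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "parent", parent)
        n = len(xyz)
        if xyz.shape != (n, 3) or radii.shape != (n,) or parent.shape != (n,):
            raise ValueError("inconsistent array shapes for Tree")
        roots = np.flatnonzero(parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(parent >= n):
            raise ValueError("parent index out of range")
        if self.node_ids is None:
            object.__setattr__(self, "node_ids", np.arange(1, n + 1))
        else:
            object.__setattr__(self, "node_ids", np.asarray(self.node_ids, dtype=int))
        if self.ntype is None:
            object.__setattr__(self, "ntype", np.full(n, 3, dtype=int))
        else:
            object.__setattr__(self, "ntype", np.asarray(self.ntype, dtype=int))
        # connectivity / acyclicity: BFS from the root must reach every node
        if len(self._traversal_order()) != n:
            raise ValueError("parent links do not form a single connected tree")

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.xyz)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def n_children(self) -> np.ndarray:
        counts = np.zeros(self.n_nodes, dtype=int)
        np.add.at(counts, self.parent[self.parent >= 0], 1)
        return counts

    def _traversal_order(self) -> list[int]:
        """Topological (root-first) order via BFS."""
        ch = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if 0 <= p < self.n_nodes:
                ch[p].append(i)
        root = int(np.flatnonzero(self.parent < 0)[0])
        order = [root]
        head = 0
        while head < len(order):
            order.extend(ch[order[head]])
            head += 1
        return order

    def is_branch_point(self) -> np.ndarray:
        return self.n_children() >= 2

    def is_terminal(self) -> np.ndarray:
        term = self.n_children() == 0
        if self.n_nodes > 1:
            term[self.root] = False
        return term

    def branch_points(self) -> np.ndarray:
        return np.flatnonzero(self.is_branch_point())

    def terminals(self) -> np.ndarray:
        return np.flatnonzero(self.is_terminal())

    # -- metrics ---------------------------------------------------------

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of the segment from each node to its parent (0 at root)."""
        seg = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        seg[mask] = np.linalg.norm(
            self.xyz[mask] - self.xyz[self.parent[mask]], axis=1
        )
        return seg

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def path_length_to_root(self) -> np.ndarray:
        seg = self.segment_lengths()
        plen = np.zeros(self.n_nodes)
        for i in self._traversal_order():
            p = self.parent[i]
            if p >= 0:
                plen[i] = plen[p] + seg[i]
        return plen

    def euclidean_to_root(self) -> np.ndarray:
        return np.linalg.norm(self.xyz - self.xyz[self.root], axis=1)

    def branch_order(self) -> np.ndarray:
        """Topological branch order: 0 at the root, +1 after every branch point."""
        bp = self.is_branch_point()
        bo = np.zeros(self.n_nodes, dtype=int)
        for i in self._traversal_order():
            p = self.parent[i]
            if p >= 0:
                bo[i] = bo[p] + (1 if bp[p] else 0)
        return bo

    def path_to_root(self, i: int) -> list[int]:
        """Node indices from ``i`` up to and including the root."""
        path = [int(i)]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    # -- transforms ------------------------------------------------------

    def translated(self, offset: Sequence[float]) -> "Tree":
        off = np.zeros(3)
        off[: len(offset)] = offset
        return replace(self, xyz=self.xyz + off)

    def rotated(self, angle: float, about: Sequence[float] | None = None) -> "Tree":
        """Rotate in the xy-plane by ``angle`` radians about ``about`` (default root)."""
        if about is None:
            about = self.xyz[self.root, :2]
        about = np.asarray(about, dtype=float)
        c, s = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -s], [s, c]])
        xy = (self.xyz[:, :2] - about) @ rot.T + about
        xyz = self.xyz.copy()
        xyz[:, :2] = xy
        return replace(self, xyz=xyz)

    def scaled_xy(self, factor: float, about: Sequence[float] | None = None) -> "Tree":
        if about is None:
            about = self.xyz[self.root, :2]
        about = np.asarray(about, dtype=float)
        xyz = self.xyz.copy()
        xyz[:, :2] = (xyz[:, :2] - about) * factor + about
        return replace(self, xyz=xyz)

    def keep_nodes(self, keep: np.ndarray) -> tuple["Tree", np.ndarray]:
        """Subset to the boolean mask ``keep`` (must be parent-closed and contain
        the root).  Returns the new tree and an old->new index map (-1 if dropped).
        """
        keep = np.asarray(keep, dtype=bool)
        if not keep[self.root]:
            raise ValueError("cannot drop the root")
        kept_parents = self.parent[keep]
        if np.any((kept_parents >= 0) & ~keep[np.maximum(kept_parents, 0)]):
            raise ValueError("mask is not parent-closed")
        index_map = np.full(self.n_nodes, -1, dtype=int)
        index_map[keep] = np.arange(int(keep.sum()))
        new_parent = np.where(kept_parents >= 0, index_map[np.maximum(kept_parents, 0)], -1)
        sub = Tree(
            xyz=self.xyz[keep],
            radii=self.radii[keep],
            parent=new_parent,
            node_ids=self.node_ids[keep],
            ntype=self.ntype[keep],
        )
        return sub, index_map


@dataclass(frozen=True)
class TerminalBranch:
    """Cable between a termination point and the preceding branch point.

    ``node_path`` runs from the branch point (or the root, for a path graph)
    to the termination point; ``length`` is its cable length in µm.
    """

    node_path: tuple[int, ...]
    length: float

    @property
    def tip(self) -> int:
        return self.node_path[-1]

    @property
    def origin(self) -> int:
        return self.node_path[0]


@dataclass
class TimeSeries:
    """Ordered reconstructions of one neuron with time stamps (hours AEL)."""

    times: np.ndarray
    trees: list[Tree]
    registration: pd.DataFrame | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.trees):
            raise ValueError("times and trees must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trees)

    def branch_point_counts(self) -> np.ndarray:
        return np.array([int(t.is_branch_point().sum()) for t in self.trees])


# ---------------------------------------------------------------------------
# SWC I/O


_SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


def read_swc(path: str | Path | io.TextIOBase) -> Tree:
    """Read a 7-column whitespace-separated SWC file into a :class:`Tree`.

    The dialect is the community standard: 1-based sample ids, ``-1`` parent
    for the single root, ``#`` comment lines.  Coordinates are preserved
    bit-exactly (parsed as IEEE doubles).
    """
    try:
        df = pd.read_csv(
            path, sep=r"\s+", comment="#", header=None, names=_SWC_COLUMNS,
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise SWCFormatError("empty SWC file") from None
    if df.shape[1] != 7 or df.isna().any().any():
        raise SWCFormatError("expected 7 numeric columns in SWC file")
    ids = df["id"].astype(int).to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise SWCFormatError("duplicate sample ids in SWC file")
    parent_ids = df["parent"].astype(int).to_numpy()
    id_to_index = {int(s): i for i, s in enumerate(ids)}
    parent = np.empty(len(ids), dtype=int)
    for i, p in enumerate(parent_ids):
        if p < 0:
            parent[i] = -1
        elif p in id_to_index:
            parent[i] = id_to_index[p]
        else:
            raise SWCFormatError(f"dangling parent reference {p}")
    n_roots = int((parent < 0).sum())
    if n_roots != 1:
        raise SWCFormatError(f"expected one root, found {n_roots}")
    try:
        return Tree(
            xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
            radii=df["radius"].to_numpy(dtype=float),
            parent=parent,
            node_ids=ids,
            ntype=df["type"].astype(int).to_numpy(),
        )
    except ValueError as exc:
        raise SWCFormatError(str(exc)) from None


def write_swc(tree: Tree, path: str | Path | io.TextIOBase, header: str | None = None) -> None:
    """Write ``tree`` as SWC.  ``%.17g`` formatting makes coordinate round
    trips through :func:`read_swc` bit-exact."""
    order = tree._traversal_order()
    new_id = np.empty(tree.n_nodes, dtype=int)
    new_id[order] = np.arange(1, tree.n_nodes + 1)
    lines = []
    if header:
        for ln in header.splitlines():
            lines.append(f"# {ln}")
    for i in order:
        p = tree.parent[i]
        pid = new_id[p] if p >= 0 else -1
        x, y, z = tree.xyz[i]
        lines.append(
            f"{new_id[i]} {tree.ntype[i]} {x:.17g} {y:.17g} {z:.17g} "
            f"{tree.radii[i]:.17g} {pid}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


# ---------------------------------------------------------------------------
# Resampling


def _sections(tree: Tree) -> list[list[int]]:
    """Maximal node paths between topological anchors (root / branch points)
    and on to terminals.  Every non-root node appears in exactly one section.
    """
    ch = tree.children()
    bp = tree.is_branch_point()
    root = tree.root
    anchors = [root] + [i for i in range(tree.n_nodes) if bp[i] and i != root]
    sections = []
    for a in anchors:
        for c in ch[a]:
            sec = [a, c]
            while len(ch[sec[-1]]) == 1:
                sec.append(ch[sec[-1]][0])
            sections.append(sec)
    return sections


def resample_tree(tree: Tree, spacing: float) -> Tree:
    """Resample every branch to ~equidistant nodes ``spacing`` µm apart.

    Section endpoints (root, branch points, terminals) are preserved, so the
    topology (branch- and termination-point counts) and the total cable
    length are unchanged; the final segment of each branch may be shorter
    than ``spacing``.  A branch shorter than ``spacing`` collapses to its
    two endpoints.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    secs = _sections(tree)
    # process each section only after its start anchor exists in the output
    pos = np.empty(tree.n_nodes, dtype=int)
    pos[tree._traversal_order()] = np.arange(tree.n_nodes)
    secs.sort(key=lambda s: pos[s[0]])
    root = tree.root
    new_xyz = [tree.xyz[root]]
    new_radii = [tree.radii[root]]
    new_type = [tree.ntype[root]]
    new_parent = [-1]
    anchor_new: dict[int, int] = {root: 0}

    for sec in secs:
        pts = tree.xyz[sec]
        rad = tree.radii[sec]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        if total <= 0:
            # degenerate zero-length section: keep the end node only
            targets = np.array([total])
        else:
            targets = np.arange(spacing, total, spacing)
            if len(targets) == 0 or total - targets[-1] > 1e-9:
                targets = np.append(targets, total)
            else:
                targets[-1] = total
        prev = anchor_new[sec[0]]
        for t in targets:
            j = int(np.searchsorted(cum, t, side="right") - 1)
            j = min(j, len(sec) - 2)
            frac = 0.0 if seg[j] == 0 else (t - cum[j]) / seg[j]
            if t >= total:
                p, r = pts[-1], rad[-1]
            else:
                p = pts[j] + frac * (pts[j + 1] - pts[j])
                r = rad[j] + frac * (rad[j + 1] - rad[j])
            new_xyz.append(p)
            new_radii.append(r)
            new_type.append(tree.ntype[sec[-1]])
            new_parent.append(prev)
            prev = len(new_xyz) - 1
        anchor_new[sec[-1]] = prev

    return Tree(
        xyz=np.array(new_xyz),
        radii=np.array(new_radii),
        parent=np.array(new_parent),
        ntype=np.array(new_type),
    )


# ---------------------------------------------------------------------------
# Terminal-branch dissection and basic counts


def dissect_terminal_branches(tree: Tree) -> list[TerminalBranch]:
    """One :class:`TerminalBranch` per termination point: the cable between
    the tip and the nearest branch point toward the root (the root itself
    for a path graph)."""
    bp = tree.is_branch_point()
    seg = tree.segment_lengths()
    out = []
    for tip in tree.terminals():
        path = [int(tip)]
        length = 0.0
        node = int(tip)
        while True:
            p = tree.parent[node]
            if p < 0:
                break
            length += seg[node]
            path.append(int(p))
            node = int(p)
            if bp[node]:
                break
        out.append(TerminalBranch(node_path=tuple(reversed(path)), length=length))
    return out


def counts_and_lengths(tree: Tree) -> tuple[int, float]:
    """``(N, L)``: number of branch points and total cable length in µm."""
    return int(tree.is_branch_point().sum()), tree.total_length


# ---------------------------------------------------------------------------
# Editing operations (used by the retraction schemes, the time-lapse
# generator and the growth model)


def remove_terminal_branch(tree: Tree, branch: TerminalBranch) -> tuple[Tree, np.ndarray]:
    """Remove all nodes of ``branch`` except its origin. Returns the edited
    tree and the old->new index map."""
    keep = np.ones(tree.n_nodes, dtype=bool)
    keep[list(branch.node_path[1:])] = False
    return tree.keep_nodes(keep)


def trim_terminal_branch(
    tree: Tree, branch: TerminalBranch, amount: float
) -> tuple[Tree, np.ndarray]:
    """Shorten ``branch`` from its tip by ``amount`` µm of cable.

    If ``amount`` is at least the branch length, the whole terminal branch
    is removed; otherwise nodes are stripped from the tip and a new tip is
    interpolated at the exact remaining arc length.
    """
    if amount >= branch.length - 1e-12:
        return remove_terminal_branch(tree, branch)
    path = list(branch.node_path)
    seg = tree.segment_lengths()
    # walk from the tip towards the origin, accumulating removed cable
    removed = 0.0
    cut = len(path) - 1
    while cut > 0 and removed + seg[path[cut]] <= amount + 1e-12:
        removed += seg[path[cut]]
        cut -= 1
    keep = np.ones(tree.n_nodes, dtype=bool)
    keep[path[cut + 1 :]] = False
    residual = amount - removed
    xyz = tree.xyz.copy()
    node = path[cut]
    if residual > 1e-12 and node != branch.origin:
        # move the surviving tip node back along its incoming segment
        par = tree.parent[node]
        direction = tree.xyz[node] - tree.xyz[par]
        seg_len = np.linalg.norm(direction)
        if seg_len > 0:
            xyz[node] = tree.xyz[node] - direction / seg_len * min(residual, seg_len * 0.999)
    edited = Tree(
        xyz=xyz, radii=tree.radii, parent=tree.parent,
        node_ids=tree.node_ids, ntype=tree.ntype,
    )
    return edited.keep_nodes(keep)


def add_branch(tree: Tree, attach: int, points: np.ndarray, radius: float = 0.25) -> Tree:
    """Append a chain of ``points`` (k, 2 or 3) starting at node ``attach``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    n = tree.n_nodes
    parent = np.concatenate([tree.parent, [attach] + list(range(n, n + len(pts) - 1))])
    next_id = int(tree.node_ids.max()) + 1
    return Tree(
        xyz=np.vstack([tree.xyz, pts]),
        radii=np.concatenate([tree.radii, np.full(len(pts), radius)]),
        parent=parent,
        node_ids=np.concatenate([tree.node_ids, np.arange(next_id, next_id + len(pts))]),
        ntype=np.concatenate([tree.ntype, np.full(len(pts), 3, dtype=int)]),
    )
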