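"""Main-branch alignment, branch-length ordering, orientation angles,
branching statistics and bootstrap testing.

The main branch (MB) of a comb-like proprioceptive dendrite runs
perpendicular to the anteroposterior contraction axis and serves as the
reference frame: after alignment the MB points up the y-axis and every
segment's orientation angle is measured against it, folded into [0°, 90°]
(90° = along the anteroposterior axis, 0° = along the MB).

Branch length order (blo) is the recursive ordering in which the metric
longest root-to-tip path of a lateral subtree is order 1 and the longest
paths branching off an order-k path are order k+1.  Lateral branches with
blo = 1 sprout directly from the MB ("second-order" branches); blo >= 2
branches are "higher-order".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .tree import Tree, resample_tree

__all__ = [
    "AlignedTree",
    "MainBranchError",
    "find_main_branch",
    "branch_length_order",
    "segment_orientation_angles",
    "lateral_branch_table",
    "compute_morphometrics",
    "MORPHOMETRIC_NAMES",
    "bootstrap_median_test",
]


class MainBranchError(RuntimeError):
    """Raised when the main-branch search does not converge."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class AlignedTree:
    """A tree rotated so its main branch runs up the y-axis from the root
    at the origin.

    ``mb_node_path`` ends at the converged MB tip (the last branch point
    shared by the two top-corner-nearest nodes); ``mb_full_path`` extends
    it through the straightest continuation to the anatomical top of the
    main branch, so the short cable above the last lateral is treated as
    main branch rather than as a lateral branch.
    """

    tree: Tree
    mb_node_path: tuple[int, ...]
    rotation_angle: float
    n_iterations: int
    mb_full_path: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.mb_full_path:
            self.mb_full_path = self.mb_node_path

    @property
    def mb_tip(self) -> int:
        return self.mb_node_path[-1]

    @property
    def mb_length(self) -> float:
        seg = self.tree.segment_lengths()
        return float(sum(seg[i] for i in self.mb_full_path[1:]))


def _deepest_terminal(tree: Tree, plen: np.ndarray) -> int:
    terms = tree.terminals()
    if len(terms) == 0:  # single-node tree
        return tree.root
    best = terms[np.lexsort((terms, -plen[terms]))][0]
    return int(best)


def _align_node_vertical(tree: Tree, node: int) -> tuple[Tree, float]:
    """Rotate about the root so ``node`` sits on the +y axis above the root."""
    v = tree.xyz[node, :2] - tree.xyz[tree.root, :2]
    if np.hypot(*v) == 0:
        return tree, 0.0
    ang = np.pi / 2 - np.arctan2(v[1], v[0])
    return tree.rotated(ang), float(ang)


def _lowest_common_ancestor(tree: Tree, a: int, b: int) -> int:
    pa = tree.path_to_root(a)
    pb = set(tree.path_to_root(b))
    for n in pa:
        if n in pb:
            return n
    return tree.root


def _mb_extension(
    tree: Tree, mb_tip: int, max_angle: float = 20.0
) -> tuple[int, ...]:
    """Continuation of the main branch above the converged MB tip: follow
    the child whose segment stays within ``max_angle`` degrees of vertical
    (in the aligned frame) until the continuation bends away or ends."""
    ch = tree.children()
    ext: list[int] = []
    node = mb_tip
    while ch[node]:
        best, best_angle = None, None
        for c in ch[node]:
            d = tree.xyz[c, :2] - tree.xyz[node, :2]
            if np.hypot(*d) == 0:
                continue
            ang = np.degrees(np.arctan2(abs(d[0]), abs(d[1])))
            if best_angle is None or ang < best_angle:
                best, best_angle = c, ang
        if best is None or best_angle >= max_angle:
            break
        ext.append(best)
        node = best
    return tuple(ext)


def find_main_branch(tree: Tree, tol: float = 1.0, max_iter: int = 50) -> AlignedTree:
    """Locate the main branch and align it vertically above the root.

    Iterative fixed-point search: (1) rotate so the tip of the metric
    longest path is vertical above the root at the origin, (2) take the
    bounding box and the tree nodes nearest its top-left and top-right
    corners, (3) define the MB tip as the first shared node of their two
    root paths, (4) re-rotate and repeat until the MB tip stops changing.
    Corner-node ties break to the lowest node index.
    """
    t = tree.translated(-tree.xyz[tree.root])
    plen = t.path_length_to_root()
    tip = _deepest_terminal(t, plen)
    t, total_angle = _align_node_vertical(t, tip)
    mb_tip = tip
    for iteration in range(1, max_iter + 1):
        xmin, xmax, ymin, ymax = geometry.bounding_box(t)
        corners = np.array([[xmin, ymax], [xmax, ymax]])
        xy = t.xyz[:, :2]
        nearest = []
        for c in corners:
            d = np.linalg.norm(xy - c, axis=1)
            nearest.append(int(np.lexsort((np.arange(len(d)), d))[0]))
        nl, nr = nearest
        lca = _lowest_common_ancestor(t, nl, nr)
        new_tip = mb_tip if lca == t.root else lca
        if new_tip == mb_tip:
            path = tuple(reversed(t.path_to_root(mb_tip)))
            if abs(t.xyz[mb_tip, 0]) > tol:
                t, ang = _align_node_vertical(t, mb_tip)
                total_angle += ang
            return AlignedTree(
                tree=t,
                mb_node_path=path,
                rotation_angle=float(np.arctan2(np.sin(total_angle), np.cos(total_angle))),
                n_iterations=iteration,
                mb_full_path=path + _mb_extension(t, mb_tip),
            )
        mb_tip = new_tip
        t, ang = _align_node_vertical(t, mb_tip)
        total_angle += ang
    raise MainBranchError(
        f"main-branch search did not converge in {max_iter} iterations",
        last_state=(t, mb_tip),
    )


# ---------------------------------------------------------------------------
# Branch length order


def _subtree_nodes(tree: Tree, start: int) -> list[int]:
    ch = tree.children()
    out = [start]
    head = 0
    while head < len(out):
        out.extend(ch[out[head]])
        head += 1
    return out


def branch_length_order(
    tree: Tree, root: int | None = None, allowed: set[int] | None = None
) -> np.ndarray:
    """Per-node blo labels for the subtree rooted at ``root`` (default: the
    tree root).  The subtree root itself is labelled 0; every other node
    gets the order of the branch it lies on.  Ties between equally long
    competing paths break to the lowest terminal node index.

    ``allowed`` optionally restricts the labelling to a node subset (used to
    order one lateral subtree while ignoring the rest of the tree)."""
    if root is None:
        root = tree.root
    base_ch = tree.children()
    if allowed is None:
        ch = base_ch
    else:
        ch = [[c for c in kids if c in allowed] for kids in base_ch]
    seg = tree.segment_lengths()
    labels = np.full(tree.n_nodes, -1, dtype=int)
    labels[root] = 0

    def subtree_nodes(start: int) -> list[int]:
        out = [start]
        head = 0
        while head < len(out):
            out.extend(ch[out[head]])
            head += 1
        return out

    def longest_path_down(start: int) -> list[int]:
        # depth of the deepest tip below each node, computed bottom-up
        nodes = subtree_nodes(start)
        depth: dict[int, float] = {}
        best_child: dict[int, int] = {}
        best_tip: dict[int, int] = {}
        for n in reversed(nodes):
            kids = ch[n]
            if not kids:
                depth[n] = 0.0
                best_tip[n] = n
                continue
            cands = [(depth[c] + seg[c], best_tip[c], c) for c in kids]
            # longest metric depth; ties to lowest terminal node index
            cands.sort(key=lambda x: (-x[0], x[1]))
            depth[n], best_tip[n], best_child[n] = cands[0]
        path = [start]
        while path[-1] in best_child:
            path.append(best_child[path[-1]])
        return path

    stack = [(root, 1)]
    while stack:
        start, order = stack.pop()
        path = longest_path_down(start)
        on_path = set(path)
        if labels[start] < 0:  # start of an off-path branch
            labels[start] = order
        for n in path[1:]:
            labels[n] = order
        # branches off the path start their own longest-path search at the
        # first off-path node; the branch includes the segment leading to it
        for n in path:
            for c in ch[n]:
                if c not in on_path and labels[c] < 0:
                    stack.append((c, order + 1))
    # a child start means: the branch includes the segment path-node -> child
    return labels


# ---------------------------------------------------------------------------
# Orientation angles


def segment_orientation_angles(aligned: AlignedTree) -> np.ndarray:
    """Orientation angle (degrees, folded to [0, 90]) of the incoming
    segment of every node of an aligned tree.

    90° = segment along the anteroposterior (horizontal) axis, 0° = along
    the MB (vertical).  The root and zero-length segments yield NaN.
    """
    t = aligned.tree
    ang = np.full(t.n_nodes, np.nan)
    mask = t.parent >= 0
    d = t.xyz[:, :2] - t.xyz[np.maximum(t.parent, 0), :2]
    lengths = np.linalg.norm(d, axis=1)
    valid = mask & (lengths > 0)
    ang[valid] = np.degrees(np.arctan2(np.abs(d[valid, 0]), np.abs(d[valid, 1])))
    return ang


def _lateral_subtree_roots(aligned: AlignedTree) -> list[tuple[int, int]]:
    """(attachment MB node, first lateral node) for every lateral subtree."""
    t = aligned.tree
    mb = set(aligned.mb_full_path)
    out = []
    ch = t.children()
    for n in aligned.mb_full_path:
        for c in ch[n]:
            if c not in mb:
                out.append((n, c))
    return out


def lateral_branch_table(aligned: AlignedTree) -> pd.DataFrame:
    """Per-branch records of all lateral branches of an aligned tree.

    One row per blo-defined branch with columns ``branch_id``, ``subtree``,
    ``blo``, ``order_class`` ('second' for blo = 1, 'higher' otherwise),
    ``length``, ``mean_angle``, ``segment_angles``, ``segment_lengths``,
    ``nodes`` and ``tip``.
    """
    t = aligned.tree
    angles = segment_orientation_angles(aligned)
    seg = t.segment_lengths()
    ch = t.children()
    rows = []
    branch_id = 0
    for subtree_idx, (attach, first) in enumerate(_lateral_subtree_roots(aligned)):
        # labels over the lateral subtree only, with the branch off the MB
        # treated as starting at the attachment node
        sub_nodes = set(_subtree_nodes(t, first))
        labels = branch_length_order(t, root=attach, allowed=sub_nodes | {attach})
        # group contiguous same-blo chains into branches
        visited = set()
        for n in sorted(sub_nodes):
            if n in visited or labels[n] < 1:
                continue
            # walk to the chain start: parent has a different blo
            start = n
            while (
                t.parent[start] in sub_nodes
                and labels[t.parent[start]] == labels[n]
            ):
                start = int(t.parent[start])
            if start in visited:
                continue
            chain = [start]
            visited.add(start)
            while True:
                nxt = [c for c in ch[chain[-1]] if c in sub_nodes and labels[c] == labels[start]]
                if not nxt:
                    break
                chain.append(nxt[0])
                visited.add(nxt[0])
            seg_angles = angles[chain]
            seg_lengths = seg[chain]
            ok = ~np.isnan(seg_angles)
            blo = int(labels[start])
            rows.append(
                dict(
                    branch_id=branch_id,
                    subtree=subtree_idx,
                    attach=attach,
                    blo=blo,
                    order_class="second" if blo == 1 else "higher",
                    length=float(seg_lengths.sum()),
                    mean_angle=float(seg_angles[ok].mean()) if ok.any() else np.nan,
                    segment_angles=seg_angles[ok].tolist(),
                    segment_lengths=seg_lengths[ok].tolist(),
                    nodes=tuple(chain),
                    tip=chain[-1],
                )
            )
            branch_id += 1
    return pd.DataFrame(
        rows,
        columns=[
            "branch_id", "subtree", "attach", "blo", "order_class", "length",
            "mean_angle", "segment_angles", "segment_lengths", "nodes", "tip",
        ],
    )


# ---------------------------------------------------------------------------
# The 49 branching statistics


MORPHOMETRIC_NAMES = [
    "n_branch_points", "max_branch_order", "mean_branch_order",
    "std_branch_order", "min_terminal_branch_order",
    "mean_terminal_branch_order", "std_terminal_branch_order",
    "mean_van_pelt_asymmetry", "std_van_pelt_asymmetry", "total_length",
    "mean_diameter", "std_diameter", "mean_taper_ratio", "std_taper_ratio",
    "total_surface", "total_volume", "mean_isoneuronal_distance",
    "min_isoneuronal_distance", "max_euclidean_distance",
    "mean_euclidean_distance", "std_euclidean_distance",
    "mean_euclidean_compactness", "std_euclidean_compactness",
    "max_path_distance", "mean_path_distance", "std_path_distance",
    "mean_path_compactness", "std_path_compactness", "mean_tortuosity",
    "std_tortuosity", "mean_branching_angle", "std_branching_angle",
    "spanning_area", "cable_density", "space_filling", "field_width",
    "field_height", "field_ratio", "mb_ratio", "n_terminals",
    "terminal_lateral_density", "perpendicularity", "min_branch_length",
    "mean_branch_length", "std_branch_length", "max_branch_length",
    "min_length_radius_ratio", "max_length_radius_ratio", "scaled_length",
]


def _van_pelt_asymmetry(tree: Tree) -> np.ndarray:
    """Van Pelt partition asymmetry |l - r| / (l + r - 2) at each branch
    point, from the terminal counts l, r of the two largest daughter
    subtrees (0 when both daughters are single terminals)."""
    ch = tree.children()
    n_term = np.zeros(tree.n_nodes, dtype=int)
    for i in reversed(tree._traversal_order()):
        kids = ch[i]
        n_term[i] = 1 if not kids else sum(n_term[c] for c in kids)
    vals = []
    for b in tree.branch_points():
        counts = sorted((n_term[c] for c in ch[b]), reverse=True)[:2]
        l, r = counts[0], counts[1]
        vals.append(0.0 if l + r <= 2 else abs(l - r) / (l + r - 2))
    return np.array(vals)


def _space_filling(tree: Tree, mesh: float = 1.0) -> float:
    """Coverage efficiency: fraction of ``mesh``-sized cells of the convex
    spanning field visited by the (resampled) cable."""
    pts = geometry.tree_points_2d(tree, resample_spacing=min(mesh / 2, 0.5))
    area = geometry.spanning_area(pts, method="convex")
    if area <= 0:
        return np.nan
    from scipy.spatial import ConvexHull
    from matplotlib.path import Path as MplPath

    hull = ConvexHull(pts)
    poly = MplPath(pts[hull.vertices])
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    gx = np.arange(xmin, xmax + mesh, mesh)
    gy = np.arange(ymin, ymax + mesh, mesh)
    gxx, gyy = np.meshgrid(gx + mesh / 2, gy + mesh / 2)
    centres = np.column_stack([gxx.ravel(), gyy.ravel()])
    inside = poly.contains_points(centres)
    if inside.sum() == 0:
        return np.nan
    occ_cells = set(
        zip(((pts[:, 0] - xmin) // mesh).astype(int), ((pts[:, 1] - ymin) // mesh).astype(int))
    )
    in_cells = set(
        zip(((centres[inside, 0] - xmin) // mesh).astype(int), ((centres[inside, 1] - ymin) // mesh).astype(int))
    )
    if not in_cells:
        return np.nan
    return len(occ_cells & in_cells) / len(in_cells)


def compute_morphometrics(
    tree: Tree,
    aligned: AlignedTree | None = None,
    target_area: float = 100.0,
    mesh: float = 1.0,
) -> pd.Series:
    """The 49 branching statistics of a single reconstruction.

    Statistics that require the main-branch frame (field box, MB ratio,
    perpendicularity, branch-length statistics...) are computed on the
    aligned tree; ``aligned`` can be supplied to skip re-alignment.
    Undefined entries on degenerate trees (e.g. asymmetry with < 2 branch
    points) are NaN, never errors.
    """
    from .scaling import scale_to_area

    t = tree
    seg = t.segment_lengths()
    bo = t.branch_order()
    terms = t.terminals()
    eucl = t.euclidean_to_root()
    plen = t.path_length_to_root()
    diam = 2.0 * t.radii
    out: dict[str, float] = {}

    out["n_branch_points"] = float(t.is_branch_point().sum())
    out["max_branch_order"] = float(bo.max())
    out["mean_branch_order"] = float(bo.mean())
    out["std_branch_order"] = float(bo.std())
    if len(terms):
        out["min_terminal_branch_order"] = float(bo[terms].min())
        out["mean_terminal_branch_order"] = float(bo[terms].mean())
        out["std_terminal_branch_order"] = float(bo[terms].std())
    else:
        out["min_terminal_branch_order"] = np.nan
        out["mean_terminal_branch_order"] = np.nan
        out["std_terminal_branch_order"] = np.nan

    asym = _van_pelt_asymmetry(t)
    out["mean_van_pelt_asymmetry"] = float(asym.mean()) if len(asym) else np.nan
    out["std_van_pelt_asymmetry"] = float(asym.std()) if len(asym) else np.nan

    out["total_length"] = t.total_length
    out["mean_diameter"] = float(diam.mean())
    out["std_diameter"] = float(diam.std())

    ratios = []
    ch = t.children()
    for b in t.branch_points():
        for c in ch[b]:
            if diam[b] > 0:
                ratios.append(diam[c] / diam[b])
    out["mean_taper_ratio"] = float(np.mean(ratios)) if ratios else np.nan
    out["std_taper_ratio"] = float(np.std(ratios)) if ratios else np.nan

    out["total_surface"] = float(np.sum(np.pi * diam * seg))
    out["total_volume"] = float(np.sum(np.pi * (diam / 2) ** 2 * seg))

    # isoneuronal distances: tip to all nodes off its root path
    means, mins = [], []
    for tip in terms:
        on_path = np.zeros(t.n_nodes, dtype=bool)
        on_path[t.path_to_root(int(tip))] = True
        others = t.xyz[~on_path]
        if len(others):
            d = np.linalg.norm(others - t.xyz[tip], axis=1)
            means.append(d.mean())
            mins.append(d.min())
    out["mean_isoneuronal_distance"] = float(np.mean(means)) if means else np.nan
    out["min_isoneuronal_distance"] = float(np.mean(mins)) if mins else np.nan

    out["max_euclidean_distance"] = float(eucl.max())
    out["mean_euclidean_distance"] = float(eucl.mean())
    out["std_euclidean_distance"] = float(eucl.std())
    out["mean_euclidean_compactness"] = float((eucl / (bo + 1)).mean())
    out["std_euclidean_compactness"] = float((eucl / (bo + 1)).std())
    out["max_path_distance"] = float(plen.max())
    out["mean_path_distance"] = float(plen.mean())
    out["std_path_distance"] = float(plen.std())
    out["mean_path_compactness"] = float((plen / (bo + 1)).mean())
    out["std_path_compactness"] = float((plen / (bo + 1)).std())

    if aligned is None:
        aligned = find_main_branch(t)
    branches = lateral_branch_table(aligned)
    at = aligned.tree

    # tortuosity per blo-defined branch (path length / chord); the branch
    # starts at its attachment/previous-order node
    torts = []
    for _, row in branches.iterrows():
        start = int(t.parent[row["nodes"][0]])
        chord = np.linalg.norm(at.xyz[row["tip"]] - at.xyz[start])
        if chord > 0:
            torts.append(row["length"] / chord)
    if not torts and aligned.mb_length > 0:
        chord = np.linalg.norm(at.xyz[aligned.mb_tip] - at.xyz[at.root])
        if chord > 0:
            torts = [aligned.mb_length / chord]
    out["mean_tortuosity"] = float(np.mean(torts)) if torts else np.nan
    out["std_tortuosity"] = float(np.std(torts)) if torts else np.nan

    bangles = []
    for b in t.branch_points():
        kids = sorted(ch[b])[:2]
        v1 = t.xyz[kids[0]] - t.xyz[b]
        v2 = t.xyz[kids[1]] - t.xyz[b]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 > 0 and n2 > 0:
            cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1, 1)
            bangles.append(np.degrees(np.arccos(cosang)))
    out["mean_branching_angle"] = float(np.mean(bangles)) if bangles else np.nan
    out["std_branching_angle"] = float(np.std(bangles)) if bangles else np.nan

    S = geometry.spanning_area(t)
    out["spanning_area"] = S
    out["cable_density"] = t.total_length / S if S > 0 else np.nan
    out["space_filling"] = _space_filling(t, mesh=mesh)

    xmin, xmax, ymin, ymax = geometry.bounding_box(at)
    width, height = xmax - xmin, ymax - ymin
    out["field_width"] = float(width)
    out["field_height"] = float(height)
    out["field_ratio"] = float(width / height) if height > 0 else np.nan
    out["mb_ratio"] = float(aligned.mb_length / height) if height > 0 else np.nan
    out["n_terminals"] = float(len(terms))
    out["terminal_lateral_density"] = (
        float(len(terms) / (height / 2)) if height > 0 else np.nan
    )

    seg_angles = np.concatenate(
        [np.asarray(a, dtype=float) for a in branches["segment_angles"]]
    ) if len(branches) else np.array([])
    out["perpendicularity"] = float(seg_angles.mean()) if len(seg_angles) else np.nan

    lengths = branches["length"].to_numpy(dtype=float) if len(branches) else np.array([])
    if len(lengths) == 0:
        lengths = np.array([aligned.mb_length]) if aligned.mb_length > 0 else np.array([])
    out["min_branch_length"] = float(lengths.min()) if len(lengths) else np.nan
    out["mean_branch_length"] = float(lengths.mean()) if len(lengths) else np.nan
    out["std_branch_length"] = float(lengths.std()) if len(lengths) else np.nan
    out["max_branch_length"] = float(lengths.max()) if len(lengths) else np.nan

    valid = seg > 0
    valid[t.root] = False
    if valid.any():
        lr = diam[valid] / seg[valid]
        out["min_length_radius_ratio"] = float(lr.min())
        out["max_length_radius_ratio"] = float(lr.max())
    else:
        out["min_length_radius_ratio"] = np.nan
        out["max_length_radius_ratio"] = np.nan

    if S > 0:
        out["scaled_length"] = scale_to_area(t, target_area).total_length
    else:
        out["scaled_length"] = np.nan

    return pd.Series(out, index=MORPHOMETRIC_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# Bootstrap hypothesis testing


def bootstrap_median_test(
    a,
    b,
    n_boot: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided pooled-resampling bootstrap test for a difference of medians.

    The null resamples both groups (with replacement, original sizes) from
    the pooled data; the p-value is the fraction of null median differences
    at least as extreme as the observed one, with the +1 small-sample
    correction.  Degenerate constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("samples must be non-empty")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs = float(np.median(a) - np.median(b))
    pool = np.concatenate([a, b])
    if np.ptp(pool) == 0:
        return obs, 1.0
    null = np.empty(n_boot)
    chunk = max(1, int(2e6 // (len(pool) or 1)))
    done = 0
    while done < n_boot:
        k = min(chunk, n_boot - done)
        ra = rng.choice(pool, size=(k, len(a)), replace=True)
        rb = rng.choice(pool, size=(k, len(b)), replace=True)
        null[done : done + k] = np.median(ra, axis=1) - np.median(rb, axis=1)
        done += k
    p = (1.0 + np.sum(np.abs(null) >= abs(obs) - 1e-12)) / (n_boot + 1.0)
    return obs, float(min(p, 1.0))
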