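"""Planar geometry helpers: spanning-field area, contours, bounding boxes.

The dendritic spanning field is the 2D region covered by the arbor.  Its
area S enters the wire-optimality scaling law and several morphometrics;
its tight contour bounds the growth simulations.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint, Polygon

from .tree import Tree, resample_tree

__all__ = ["spanning_area", "field_contour", "bounding_box", "tree_points_2d"]


def tree_points_2d(tree: Tree, resample_spacing: float | None = 0.5) -> np.ndarray:
    """2D point cloud of the tree cable, optionally resampled so that long
    straight edges contribute interior points."""
    t = resample_tree(tree, resample_spacing) if resample_spacing else tree
    return t.xyz[:, :2]


def spanning_area(
    points: np.ndarray | Tree,
    method: str = "convex",
    concavity: float = 0.1,
) -> float:
    """Area (µm²) of the dendritic spanning field of a 2D point cloud.

    ``method="convex"`` (default) is the convex-hull spanning field used for
    scaling-law normalization and the morphometric table; ``"concave"`` is a
    tight connected concave hull (no holes) whose ``concavity`` ratio in
    [0, 1] interpolates from maximally concave (0) to the convex hull (1).
    Degenerate clouds (collinear, < 3 points) have zero area.
    """
    if isinstance(points, Tree):
        points = tree_points_2d(points)
    pts = np.asarray(points, dtype=float)[:, :2]
    if len(pts) < 3:
        return 0.0
    if method == "convex":
        try:
            return float(ConvexHull(pts).volume)
        except QhullError:
            return 0.0
    if method == "concave":
        hull = shapely.concave_hull(MultiPoint(pts), ratio=concavity, allow_holes=False)
        return float(hull.area)
    raise ValueError(f"unknown spanning-area method {method!r}")


def field_contour(
    tree: Tree, concavity: float = 0.1, resample_spacing: float = 0.5
) -> Polygon:
    """Tight connected contour of the dendritic spanning field.

    Used as the physical boundary of the growth arena.  Falls back to the
    convex hull when the concave hull degenerates (thin or tiny arbors).
    """
    pts = tree_points_2d(tree, resample_spacing)
    mp = MultiPoint(pts)
    hull = shapely.concave_hull(mp, ratio=concavity, allow_holes=False)
    if not isinstance(hull, Polygon) or hull.area <= 0 or not hull.is_valid:
        hull = mp.convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("degenerate tree: cannot build a contour polygon")
    return hull


def bounding_box(points: np.ndarray | Tree) -> tuple[float, float, float, float]:
    """Axis-aligned bounding box ``(xmin, xmax, ymin, ymax)`` of 2D points."""
    if isinstance(points, Tree):
        points = points.xyz[:, :2]
    pts = np.asarray(points, dtype=float)
    return (
        float(pts[:, 0].min()),
        float(pts[:, 0].max()),
        float(pts[:, 1].min()),
        float(pts[:, 1].max()),
    )
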