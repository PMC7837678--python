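"""Geometric model of branch bending on a cylindrical body wall.

During a peristaltic contraction the larval cuticle folds; in the marginal
case the fold is the surface of a cylinder of radius R whose symmetry axis
runs dorsoventrally.  A dendritic branch of length L_b lying on the body
wall at orientation angle theta to that axis (theta = pi/2: along the
anteroposterior contraction direction) follows an elliptical profile with
semi-diameters a = L_b / (2*pi) and b = a / sin(theta), approximated by a
circle of radius Rc = (a + b) / 2.  For a thin branch tube (R >> r) the
second principal curvature is unchanged by bending, so the curvature
change is carried by the first principal curvature c1 = 1 / Rc.

Rescaling c1 by its value for a fully bent branch (theta = pi/2) gives the
normalized curvature increase

    c(theta) = 2 * sin(theta) / (1 + sin(theta)),

which rises strictly from 0 (straight branch along the cylinder axis) to 1
(circular branch along the contraction direction) and is independent of
both branch length and cylinder size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalized_curvature_increase", "branch_curvature_increase"]


def normalized_curvature_increase(theta):
    """Normalized first-principal-curvature increase for orientation
    ``theta`` (radians in [0, pi/2]); scalar or array.

    Raises ``ValueError`` outside [0, pi/2]: callers must fold orientation
    angles first.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(th < -1e-12) or np.any(th > np.pi / 2 + 1e-12):
        raise ValueError("theta must lie in [0, pi/2]")
    s = np.sin(np.clip(th, 0.0, np.pi / 2))
    out = 2.0 * s / (1.0 + s)
    return float(out) if np.isscalar(theta) else out


def branch_curvature_increase(branches: pd.DataFrame) -> pd.DataFrame:
    """Per-branch normalized curvature increase from per-segment angles.

    ``branches`` is a lateral branch table (see
    :func:`combmorph.morphometrics.lateral_branch_table`) whose
    ``segment_angles`` are degrees folded to [0, 90].  Each segment's angle
    is mapped through :func:`normalized_curvature_increase`; per branch the
    values are aggregated as a segment-length-weighted mean (invariant to
    resampling) in ``curvature``, with the plain median also reported in
    ``curvature_median``.  Branches without valid segments get NaN.
    """
    means, medians = [], []
    for _, row in branches.iterrows():
        ang = np.asarray(row["segment_angles"], dtype=float)
        w = np.asarray(row["segment_lengths"], dtype=float)
        ok = ~np.isnan(ang) & (w > 0)
        if not ok.any():
            means.append(np.nan)
            medians.append(np.nan)
            continue
        c = normalized_curvature_increase(np.radians(ang[ok]))
        means.append(float(np.average(c, weights=w[ok])))
        medians.append(float(np.median(c)))
    out = branches.copy()
    out["curvature"] = means
    out["curvature_median"] = medians
    return out
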