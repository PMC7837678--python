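"""Segment-contraction kinematics and ratiometric calcium transients.

The body-wall contraction a proprioceptive neuron senses is read out from
the trajectories of a triplet of adjacent somata: the sum of the distances
of the central soma to its anterior and posterior neighbours shrinks as
the segment contracts.  Calcium activity is the fold change dR/R0 of the
green/red fluorescence ratio, baselined on the first five frames.  Trials
are aligned to maximal segment contraction before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TripletTrajectory",
    "contraction_rate",
    "delta_r_over_r",
    "align_and_average",
]


@dataclass
class TripletTrajectory:
    """Per-frame 2D positions (µm) of a central soma and its anterior and
    posterior neighbours; ``times`` in seconds."""

    times: np.ndarray
    central: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        for name in ("central", "anterior", "posterior"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (len(self.times), 2):
                raise ValueError(f"{name} must be (n_frames, 2)")
            setattr(self, name, arr)


def contraction_rate(traj: TripletTrajectory) -> np.ndarray:
    """Normalized contraction series in [0, 1].

    d(t) = |central - anterior| + |central - posterior|; the output maps
    the maximum of d (maximal distension) to 0 and the minimum (maximal
    contraction) to 1.  A constant d leaves the normalization undefined.
    """
    if len(traj.times) < 2:
        raise ValueError("need at least 2 frames")
    d = np.linalg.norm(traj.central - traj.anterior, axis=1) + np.linalg.norm(
        traj.central - traj.posterior, axis=1
    )
    if np.ptp(d) == 0:
        raise ValueError("constant inter-soma distance: normalization undefined")
    return (d.max() - d) / (d.max() - d.min())


def delta_r_over_r(trace: pd.DataFrame, n_baseline: int = 5) -> np.ndarray:
    """Fold change (R - R0) / R0 of R = F_g / F_t, with R0 the mean ratio
    over the first ``n_baseline`` frames.  Frames with F_t = 0 are NaN."""
    fg = trace["F_g"].to_numpy(dtype=float)
    ft = trace["F_t"].to_numpy(dtype=float)
    if len(fg) < n_baseline:
        raise ValueError(f"need at least {n_baseline} frames")
    r = np.where(ft != 0, fg / np.where(ft != 0, ft, 1.0), np.nan)
    r0 = np.nanmean(r[:n_baseline])
    return (r - r0) / r0


def align_and_average(
    contractions: list[np.ndarray],
    drr_traces: list[np.ndarray],
    dt: float = 0.2,
    min_trials: int = 5,
) -> pd.DataFrame:
    """Align trials to maximal contraction and average.

    Every trial is shifted so its contraction maximum sits at t = 0 s
    (ties: earliest frame); each dR/R0 trace is normalized by its positive
    maximum.  Returns a frame indexed by time offset with mean +- SEM of
    both signals where at least ``min_trials`` trials contribute (NaN
    elsewhere, with the contributing count in ``n``), plus the lag of the
    mean dR/R0 peak relative to maximal contraction in ``attrs['peak_lag']``.
    """
    if len(contractions) != len(drr_traces) or len(contractions) == 0:
        raise ValueError("need equally many contraction and dR/R0 traces")
    peaks = [int(np.argmax(c)) for c in contractions]
    offsets = []
    for c, s, p in zip(contractions, drr_traces, peaks):
        if len(c) != len(s):
            raise ValueError("contraction and dR/R0 traces must be same length")
        idx = np.arange(len(c)) - p
        smax = np.nanmax(s)
        s_norm = s / smax if smax > 0 else s
        offsets.append(pd.DataFrame({"offset": idx, "contraction": c, "drr": s_norm}))
    stacked = pd.concat(offsets)
    g = stacked.groupby("offset")
    out = pd.DataFrame(
        {
            "time": g.size().index * dt,
            "n": g.size(),
            "contraction_mean": g["contraction"].mean(),
            "contraction_sem": g["contraction"].sem(),
            "drr_mean": g["drr"].mean(),
            "drr_sem": g["drr"].sem(),
        }
    )
    thin = out["n"] < min_trials
    out.loc[thin, ["contraction_mean", "contraction_sem", "drr_mean", "drr_sem"]] = np.nan
    valid = out.dropna(subset=["drr_mean"])
    peak_lag = float(valid["time"][valid["drr_mean"].idxmax()]) if len(valid) else np.nan
    out.attrs["peak_lag"] = peak_lag
    return out
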