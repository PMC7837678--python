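"""Single-branch dynamics across 1-hour time-lapse frames.

Terminal branches are followed between consecutive reconstructions through
a registration of termination points (frame, node_id, track_id) — produced
manually for real data, exactly for synthetic data — and classified into
five dynamics classes: newly formed, retracted, shortened, elongated and
stable (change below the optical resolution).  The per-bin class
proportions and rates parameterise the growth model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import TimeSeries, Tree, dissect_terminal_branches

__all__ = [
    "RegistrationError",
    "match_branches",
    "classify_dynamics",
    "dynamics_summary",
    "track_series",
    "CLASSES",
]

CLASSES = ("new", "retracted", "shortened", "elongated", "stable")


class RegistrationError(ValueError):
    """Raised for ambiguous (one-to-many) registrations."""


def _frame_tracks(registration: pd.DataFrame, frame: int) -> dict[int, int]:
    sub = registration[registration["frame"] == frame]
    for col in ("node_id", "track_id"):
        dup = sub[col][sub[col].duplicated()]
        if len(dup):
            raise RegistrationError(
                f"one-to-many registration in frame {frame}: {sorted(set(dup))}"
            )
    return dict(zip(sub["node_id"].astype(int), sub["track_id"].astype(int)))


def match_branches(
    t0: Tree,
    t1: Tree,
    registration: pd.DataFrame,
    frame0: int,
    frame1: int,
):
    """Match terminal branches of two frames through registered tips.

    Returns ``(pairs, unmatched0, unmatched1)`` where ``pairs`` maps
    ``track_id -> (TerminalBranch at t0, TerminalBranch at t1)`` and the
    unmatched dicts map ``track_id -> TerminalBranch`` (candidates for
    retracted and new branches respectively).
    """
    reg0 = _frame_tracks(registration, frame0)
    reg1 = _frame_tracks(registration, frame1)
    tb0 = {
        reg0[int(t0.node_ids[tb.tip])]: tb
        for tb in dissect_terminal_branches(t0)
        if int(t0.node_ids[tb.tip]) in reg0
    }
    tb1 = {
        reg1[int(t1.node_ids[tb.tip])]: tb
        for tb in dissect_terminal_branches(t1)
        if int(t1.node_ids[tb.tip]) in reg1
    }
    common = sorted(set(tb0) & set(tb1))
    pairs = {tr: (tb0[tr], tb1[tr]) for tr in common}
    unmatched0 = {tr: tb0[tr] for tr in sorted(set(tb0) - set(tb1))}
    unmatched1 = {tr: tb1[tr] for tr in sorted(set(tb1) - set(tb0))}
    return pairs, unmatched0, unmatched1


def classify_dynamics(
    pairs: dict,
    unmatched0: dict,
    unmatched1: dict,
    t0: float,
    t1: float,
    resolution: float = 0.3,
) -> pd.DataFrame:
    """Classify matched/unmatched terminal branches into the five dynamics
    classes for one frame interval.

    Matched branches with |delta length| <= ``resolution`` (µm, the
    approximate optical resolution) are stable; otherwise elongated or
    shortened.  Rates are µm/hr signed by the length change (a retracted
    branch loses its whole initial length; a new branch gains its full
    final length).
    """
    if t1 <= t0:
        raise ValueError("t1 must be after t0")
    dt = t1 - t0
    rows = []
    for tr, (b0, b1) in pairs.items():
        delta = b1.length - b0.length
        if abs(delta) <= resolution:
            cls = "stable"
        elif delta > 0:
            cls = "elongated"
        else:
            cls = "shortened"
        rows.append(
            dict(branch_id=tr, t0=t0, t1=t1, dynamics_class=cls,
                 length_t0=b0.length, length_t1=b1.length,
                 delta_length=delta, rate=delta / dt)
        )
    for tr, b0 in unmatched0.items():
        rows.append(
            dict(branch_id=tr, t0=t0, t1=t1, dynamics_class="retracted",
                 length_t0=b0.length, length_t1=0.0,
                 delta_length=-b0.length, rate=-b0.length / dt)
        )
    for tr, b1 in unmatched1.items():
        rows.append(
            dict(branch_id=tr, t0=t0, t1=t1, dynamics_class="new",
                 length_t0=0.0, length_t1=b1.length,
                 delta_length=b1.length, rate=b1.length / dt)
        )
    return pd.DataFrame(
        rows,
        columns=["branch_id", "t0", "t1", "dynamics_class", "length_t0",
                 "length_t1", "delta_length", "rate"],
    )


def track_series(series: TimeSeries, resolution: float = 0.3) -> pd.DataFrame:
    """Events for all consecutive frame pairs of a registered time series."""
    if series.registration is None:
        raise ValueError("series carries no registration table")
    events = []
    for k in range(len(series) - 1):
        pairs, un0, un1 = match_branches(
            series.trees[k], series.trees[k + 1], series.registration, k, k + 1
        )
        events.append(
            classify_dynamics(
                pairs, un0, un1, series.times[k], series.times[k + 1], resolution
            )
        )
    return pd.concat(events, ignore_index=True)


def dynamics_summary(events: pd.DataFrame, bin_edges) -> pd.DataFrame:
    """Per-time-bin class proportions and mean rates.

    Events are assigned to bins by their end time ``t1`` using
    right-closed edges (an event with t1 = 17.2 falls in the bin with
    upper edge 17.5).  Per bin: the fraction of each dynamics class (these
    sum to 1 over classified branches), the mean absolute extension rate
    (elongated + new) and reduction rate (shortened + retracted), the mean
    length of retracted branches and the mean length of new branches.
    Empty bins give NaN.
    """
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = events[(events["t1"] > lo) & (events["t1"] <= hi)]
        row: dict[str, float] = {"bin_start": lo, "bin_end": hi, "n_events": len(sub)}
        if len(sub) == 0:
            for c in CLASSES:
                row[f"frac_{c}"] = np.nan
            row.update(mean_extension_rate=np.nan, mean_reduction_rate=np.nan,
                       mean_retracted_length=np.nan, mean_new_length=np.nan)
            rows.append(row)
            continue
        counts = sub["dynamics_class"].value_counts()
        for c in CLASSES:
            row[f"frac_{c}"] = counts.get(c, 0) / len(sub)
        ext = sub[sub["dynamics_class"].isin(["elongated", "new"])]["rate"]
        red = sub[sub["dynamics_class"].isin(["shortened", "retracted"])]["rate"]
        retr = sub[sub["dynamics_class"] == "retracted"]["length_t0"]
        newb = sub[sub["dynamics_class"] == "new"]["length_t1"]
        row.update(
            mean_extension_rate=float(ext.abs().mean()) if len(ext) else np.nan,
            mean_reduction_rate=float(red.abs().mean()) if len(red) else np.nan,
            mean_retracted_length=float(retr.mean()) if len(retr) else np.nan,
            mean_new_length=float(newb.mean()) if len(newb) else np.nan,
        )
        rows.append(row)
    return pd.DataFrame(rows)
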