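"""In-silico terminal-branch retraction schemes.

The embryonic retraction phase removes a sizeable fraction of terminal
branches.  To ask which selection rule best explains the reorganisation,
four extreme schemes remove the observed number of branches from the
pre-retraction tree: shortest branches first, lowest orientation angle
first, highest branch length order first, or uniformly at random (the
stochastic control, averaged over repetitions).  The simulated trees are
then compared with the real post-retraction morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .morphometrics import (
    bootstrap_median_test,
    find_main_branch,
    lateral_branch_table,
)
from .curvature import branch_curvature_increase
from .tree import TimeSeries, Tree, dissect_terminal_branches, remove_terminal_branch

__all__ = [
    "RetractionPlan",
    "SCHEMES",
    "plan_removal_count",
    "apply_retraction_scheme",
    "compare_schemes",
]

SCHEMES = ("shortest_first", "low_angle_first", "high_blo_first", "random")


@dataclass(frozen=True)
class RetractionPlan:
    scheme: str
    n_remove: int
    n_random_reps: int = 100

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.n_remove < 0:
            raise ValueError("n_remove must be non-negative")


def plan_removal_count(series: TimeSeries) -> int:
    """Branch removals implied by a time series: the difference in branch
    points between the maximum (pre-retraction) and the subsequent minimum
    (post-retraction) reconstruction."""
    counts = series.branch_point_counts()
    i_max = int(np.argmax(counts))
    after = counts[i_max:]
    n = int(counts[i_max] - after.min())
    if n == 0:
        warnings.warn("no retraction found in series (monotone branch counts)")
    return n


def _branch_metrics(tree: Tree, aligned=None) -> pd.DataFrame:
    """Terminal branches of ``tree`` with sort keys: length, mean angle, blo.

    The terminal branch containing the MB tip is excluded — retraction acts
    on lateral branches, not on the main branch.
    """
    if aligned is None:
        aligned = find_main_branch(tree)
    table = lateral_branch_table(aligned)
    tip_info = {int(row["tip"]): row for _, row in table.iterrows()}
    rows = []
    for tb in dissect_terminal_branches(tree):
        info = tip_info.get(int(tb.tip))
        if info is None:
            continue  # the MB's own terminal piece
        rows.append(
            dict(
                tip=int(tb.tip),
                length=tb.length,
                mean_angle=float(info["mean_angle"]),
                blo=int(info["blo"]),
                branch=tb,
            )
        )
    return pd.DataFrame(rows, columns=["tip", "length", "mean_angle", "blo", "branch"])


def _remove_one(tree: Tree, metrics: pd.DataFrame, scheme: str, rng) -> Tree:
    if scheme == "shortest_first":
        order = np.lexsort((metrics["tip"], metrics["length"]))
    elif scheme == "low_angle_first":
        order = np.lexsort((metrics["tip"], metrics["mean_angle"]))
    elif scheme == "high_blo_first":
        order = np.lexsort((metrics["tip"], -metrics["blo"]))
    else:
        order = [rng.integers(len(metrics))]
    tb = metrics.iloc[int(order[0])]["branch"]
    new_tree, _ = remove_terminal_branch(tree, tb)
    return new_tree


def apply_retraction_scheme(
    tree: Tree,
    plan: RetractionPlan,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    resort: bool = True,
):
    """Remove ``plan.n_remove`` terminal branches under ``plan.scheme``.

    With ``resort=True`` (default) branches are re-dissected and re-sorted
    after every removal, so cable exposed by a removal becomes eligible;
    ``resort=False`` removes from the initial static branch list instead.
    The deterministic schemes return a single :class:`Tree`; the random
    scheme returns a list of ``plan.n_random_reps`` trees.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    reps = plan.n_random_reps if plan.scheme == "random" else 1
    results = []
    for _ in range(reps):
        t = tree
        if resort:
            for _ in range(plan.n_remove):
                metrics = _branch_metrics(t)
                if len(metrics) == 0:
                    break
                t = _remove_one(t, metrics, plan.scheme, rng)
        else:
            metrics = _branch_metrics(t)
            if plan.scheme == "shortest_first":
                order = np.lexsort((metrics["tip"], metrics["length"]))
            elif plan.scheme == "low_angle_first":
                order = np.lexsort((metrics["tip"], metrics["mean_angle"]))
            elif plan.scheme == "high_blo_first":
                order = np.lexsort((metrics["tip"], -metrics["blo"]))
            else:
                order = rng.permutation(len(metrics))
            drop = set()
            for k in order[: plan.n_remove]:
                drop.update(metrics.iloc[int(k)]["branch"].node_path[1:])
            keep = np.ones(t.n_nodes, dtype=bool)
            keep[list(drop)] = False
            t, _ = t.keep_nodes(keep)
        results.append(t)
    return results if plan.scheme == "random" else results[0]


def _angle_and_curvature_samples(tree: Tree) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    aligned = find_main_branch(tree)
    table = branch_curvature_increase(lateral_branch_table(aligned))
    angles = table["mean_angle"].to_numpy(dtype=float)
    curv = table["curvature"].to_numpy(dtype=float)
    return angles[~np.isnan(angles)], curv[~np.isnan(curv)], table


def compare_schemes(
    sim_trees: dict[str, Tree | list[Tree]],
    real_post_tree: Tree,
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Morphometric comparison of retraction-scheme outputs against the
    post-retraction target tree.

    Per scheme (random ensembles averaged over repetitions): branch-point,
    terminal and higher-order branch counts with their errors against the
    target, total length, Wasserstein distances between branch angle and
    curvature distributions, and a bootstrap test of the median angle
    difference.
    """
    rng = np.random.default_rng(seed)
    tgt_angles, tgt_curv, tgt_table = _angle_and_curvature_samples(real_post_tree)
    tgt_N = int(real_post_tree.is_branch_point().sum())
    tgt_higher = int((tgt_table["blo"] >= 2).sum())
    rows = []
    for scheme, trees in sim_trees.items():
        trees_list = trees if isinstance(trees, list) else [trees]
        per_rep = []
        for t in trees_list:
            ang, curv, table = _angle_and_curvature_samples(t)
            per_rep.append(
                dict(
                    n_branch_points=int(t.is_branch_point().sum()),
                    n_terminals=int(t.is_terminal().sum()),
                    total_length=t.total_length,
                    n_higher_order=int((table["blo"] >= 2).sum()),
                    angle_distance=(
                        wasserstein_distance(ang, tgt_angles)
                        if len(ang) and len(tgt_angles) else np.nan
                    ),
                    curvature_distance=(
                        wasserstein_distance(curv, tgt_curv)
                        if len(curv) and len(tgt_curv) else np.nan
                    ),
                    _angles=ang,
                )
            )
        pooled_angles = np.concatenate([r.pop("_angles") for r in per_rep]) if per_rep else np.array([])
        mean = pd.DataFrame(per_rep).mean(numeric_only=True)
        if len(pooled_angles) and len(tgt_angles):
            diff, p = bootstrap_median_test(pooled_angles, tgt_angles, n_boot=n_boot, rng=rng)
        else:
            diff, p = np.nan, np.nan
        rows.append(
            dict(
                scheme=scheme,
                n_reps=len(trees_list),
                **mean.to_dict(),
                branch_point_error=abs(mean["n_branch_points"] - tgt_N),
                higher_order_error=abs(mean["n_higher_order"] - tgt_higher),
                median_angle_diff=diff,
                angle_p_value=p,
            )
        )
    return pd.DataFrame(rows).set_index("scheme")
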