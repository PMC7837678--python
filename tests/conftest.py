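import io

import numpy as np
import pytest

import combmorph as cm
from combmorph.tree import Tree, add_branch


def make_path_tree(length=10.0, n_nodes=11, direction=(0.0, 1.0)):
    """Straight path graph of given total length."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    offs = np.linspace(0, length, n_nodes)
    xyz = np.column_stack([offs[:, None] * d[None, :], np.zeros(n_nodes)])
    return Tree(
        xyz=xyz,
        radii=np.full(n_nodes, 0.25),
        parent=np.arange(-1, n_nodes - 1),
    )


def make_y_tree(arm1=10.0, arm2=3.0, stem=5.0):
    """Stem up the y-axis splitting into two straight arms."""
    t = make_path_tree(length=stem, n_nodes=6)
    top = t.n_nodes - 1
    d1 = np.array([np.sin(np.radians(40)), np.cos(np.radians(40))])
    d2 = np.array([-np.sin(np.radians(40)), np.cos(np.radians(40))])
    p1 = t.xyz[top, :2] + d1[None, :] * np.linspace(arm1 / 5, arm1, 5)[:, None]
    t = add_branch(t, top, p1)
    p2 = t.xyz[top, :2] + d2[None, :] * np.linspace(arm2 / 3, arm2, 3)[:, None]
    t = add_branch(t, top, p2)
    return t


def make_manual_comb(lateral_lengths, angles=None, mb_length=20.0, spacing=0.5):
    """Comb with exactly specified lateral lengths/angles (degrees),
    attached at evenly spaced heights, alternating sides."""
    n_mb = int(mb_length / spacing) + 1
    t = make_path_tree(length=mb_length, n_nodes=n_mb)
    if angles is None:
        angles = [90.0] * len(lateral_lengths)
    heights = np.linspace(0.2, 0.9, len(lateral_lengths)) * mb_length
    for j, (L, a) in enumerate(zip(lateral_lengths, angles)):
        attach = int(round(heights[j] / spacing))
        side = 1.0 if j % 2 == 0 else -1.0
        th = np.radians(a)
        d = np.array([side * np.sin(th), np.cos(th)])
        n_pts = max(int(np.ceil(L / spacing)), 2)
        pts = t.xyz[attach, :2] + d[None, :] * np.linspace(L / n_pts, L, n_pts)[:, None]
        t = add_branch(t, attach, pts)
    return t


def swc_from_text(text):
    return cm.read_swc(io.StringIO(text))


@pytest.fixture(scope="session")
def comb_and_truth():
    return cm.make_comb_tree(cm.CombParams(), seed=1)


@pytest.fixture(scope="session")
def comb(comb_and_truth):
    return comb_and_truth[0]


@pytest.fixture(scope="session")
def aligned_comb(comb):
    return cm.find_main_branch(comb)


@pytest.fixture(scope="session")
def timelapse():
    base, _ = cm.make_comb_tree(cm.CombParams(n_laterals=14), seed=2)
    series, truth = cm.make_timelapse(cm.TimelapseParams(), base, seed=3)
    return series, truth


@pytest.fixture(scope="session")
def tracked_events(timelapse):
    series, _ = timelapse
    return cm.track_series(series)
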