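import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import combmorph as cm
from combmorph.morphometrics import (
    MORPHOMETRIC_NAMES,
    branch_length_order,
    segment_orientation_angles,
)
from combmorph.tree import add_branch

from conftest import make_manual_comb, make_path_tree, make_y_tree


class TestFindMainBranch:
    def test_comb_recovers_mb(self, comb, aligned_comb):
        at = aligned_comb
        # recovered MB is an initial run of the constructed vertical MB
        # (the search ends at the last branch point shared by the two
        # top-corner-nearest nodes)
        mb_x = comb.xyz[list(at.mb_node_path), 0]
        assert np.allclose(mb_x, 0.0, atol=1e-9)
        assert at.mb_length > 0.7 * 30.0
        assert abs(at.rotation_angle) < np.radians(2)
        root_xy = at.tree.xyz[at.tree.root, :2]
        assert np.allclose(root_xy, 0.0, atol=1e-9)
        assert abs(at.tree.xyz[at.mb_tip, 0]) <= 1.0

    def test_rotation_equivariance(self, comb, aligned_comb):
        rot = comb.rotated(np.radians(37.0))
        at = cm.find_main_branch(rot)
        assert at.mb_node_path == aligned_comb.mb_node_path
        assert np.degrees(at.rotation_angle) == pytest.approx(-37.0, abs=2.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        angle=st.floats(-np.pi, np.pi),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    def test_rigid_motion_equivariance(self, comb, angle, dx, dy):
        moved = comb.rotated(angle).translated([dx, dy])
        at = cm.find_main_branch(moved)
        ref = cm.find_main_branch(comb)
        assert at.mb_node_path == ref.mb_node_path

    def test_symmetric_v_tree(self):
        # two equal arms straight from the root, no laterals
        from combmorph.tree import Tree, add_branch

        t = Tree(xyz=np.zeros((1, 3)), radii=np.array([0.25]), parent=np.array([-1]))
        for sgn in (1.0, -1.0):
            d = np.array([sgn * np.sin(0.7), np.cos(0.7)])
            pts = d[None, :] * np.linspace(2.0, 10.0, 5)[:, None]
            t = add_branch(t, 0, pts)
        at = cm.find_main_branch(t)
        # MB is the longest path; converges on the first bounding-box pass
        plen = t.path_length_to_root()
        assert at.mb_length == pytest.approx(plen.max(), rel=1e-6)
        assert at.n_iterations == 1


def _blo_oracle(tree, root, allowed):
    """Independent recursive longest-path labelling."""
    ch = tree.children()
    seg = tree.segment_lengths()
    labels = {}

    def deepest(start):
        best = (0.0, start, [start])
        for c in ch[start]:
            if c not in allowed or c in labels:
                continue
            d, tip, path = deepest(c)
            cand = (d + seg[c], tip, [start] + path)
            if cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] < best[1]
            ):
                best = cand
        return best

    def assign(start, order):
        _, _, path = deepest(start)
        for n in path[1:]:
            labels[n] = order
        for n in path:
            for c in ch[n]:
                if c in allowed and c not in labels and c not in path:
                    assign_from_parent(n, c, order + 1)

    def assign_from_parent(parent, child, order):
        d, tip, path = deepest(child)
        full = [parent, child] + path[1:]
        for n in full[1:]:
            labels[n] = order
        for n in full:
            for c in ch[n]:
                if c in allowed and c not in labels and c not in full:
                    assign_from_parent(n, c, order + 1)

    assign(root, 1)
    return labels


class TestBranchLengthOrder:
    def test_path_graph_all_order_one(self):
        t = make_path_tree()
        labels = branch_length_order(t)
        assert np.all(labels[np.arange(t.n_nodes) != t.root] == 1)

    def test_y_long_arm_continues(self):
        t = make_y_tree(arm1=10.0, arm2=3.0)
        labels = branch_length_order(t)
        plen = t.path_length_to_root()
        tips = t.terminals()
        long_tip = tips[np.argmax(plen[tips])]
        short_tip = tips[np.argmin(plen[tips])]
        assert labels[long_tip] == 1
        assert labels[short_tip] == 2

    def test_matches_recursive_oracle(self, comb):
        allowed = set(range(comb.n_nodes))
        labels = branch_length_order(comb)
        oracle = _blo_oracle(comb, comb.root, allowed)
        for n, lab in oracle.items():
            assert labels[n] == lab, f"node {n}: {labels[n]} != {lab}"


class TestOrientationAngles:
    @pytest.mark.parametrize(
        "angle_deg,expected",
        [(90.0, 90.0), (0.0, 0.0), (45.0, 45.0)],
    )
    def test_single_lateral_angle(self, angle_deg, expected):
        t = make_manual_comb([4.0], angles=[angle_deg])
        at = cm.find_main_branch(t)
        table = cm.lateral_branch_table(at)
        assert len(table) == 1
        assert table.iloc[0]["mean_angle"] == pytest.approx(expected, abs=1e-6)

    def test_reflection_invariance(self):
        left = make_manual_comb([4.0, 4.0], angles=[45.0, 45.0])
        at = cm.find_main_branch(left)
        angles = segment_orientation_angles(at)
        valid = angles[~np.isnan(angles)]
        # both sides fold to the same 45 degrees
        assert np.allclose(valid[valid > 1], 45.0, atol=1e-6)

    def test_straight_branch_mean_equals_endpoint_angle(self):
        t = make_manual_comb([6.0], angles=[63.0])
        at = cm.find_main_branch(t)
        table = cm.lateral_branch_table(at)
        row = table.iloc[0]
        tip_xy = at.tree.xyz[row["tip"], :2]
        origin_xy = at.tree.xyz[at.tree.parent[row["nodes"][0]], :2]
        d = tip_xy - origin_xy
        endpoint_angle = np.degrees(np.arctan2(abs(d[0]), abs(d[1])))
        assert row["mean_angle"] == pytest.approx(endpoint_angle, abs=1e-9)

    def test_comb_angles_recover_planted(self, comb_and_truth):
        tree, truth = comb_and_truth
        at = cm.find_main_branch(tree)
        table = cm.lateral_branch_table(at)
        # match recovered branches to planted ones via tip coordinates
        planted = truth[truth["order_class"] == "second"]
        recovered = table[table["order_class"] == "second"]
        tip_xy = {tuple(np.round(tree.xyz[r.tip_node, :2], 6)): r.angle
                  for r in planted.itertuples()}
        n_checked = 0
        for r in recovered.itertuples():
            key = tuple(np.round(at.tree.xyz[r.tip, :2], 6))
            if key in tip_xy:
                assert r.mean_angle == pytest.approx(tip_xy[key], abs=0.5)
                n_checked += 1
        assert n_checked >= len(planted) - 2


class TestMorphometrics:
    def test_all_49_present_and_finite(self, comb):
        m = cm.compute_morphometrics(comb)
        assert list(m.index) == MORPHOMETRIC_NAMES
        assert len(m) == 49
        assert np.isfinite(m).all()

    def test_path_graph_degenerate(self):
        t = make_path_tree(length=10.0)
        m = cm.compute_morphometrics(t)
        assert m["n_branch_points"] == 0
        assert m["total_length"] == pytest.approx(10.0)
        assert m["max_branch_order"] == 0
        assert np.isnan(m["mean_van_pelt_asymmetry"])

    def test_symmetric_tree_zero_asymmetry(self):
        t = make_y_tree(arm1=8.0, arm2=8.0)
        for tip in t.terminals():
            for sgn in (1.0, -1.0):
                d = np.array([sgn * 0.6, 0.8])
                pts = t.xyz[int(tip), :2] + d[None, :] * np.array([[1.0], [2.0]])
                t = add_branch(t, int(tip), pts)
        m = cm.compute_morphometrics(t)
        assert m["mean_van_pelt_asymmetry"] == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_cross_checks(self, comb):
        m = cm.compute_morphometrics(comb)
        eucl = np.linalg.norm(comb.xyz - comb.xyz[comb.root], axis=1)
        assert m["mean_euclidean_distance"] == pytest.approx(eucl.mean())
        assert m["max_euclidean_distance"] == pytest.approx(eucl.max())
        assert m["n_terminals"] == int(comb.is_terminal().sum())
        from scipy.spatial import ConvexHull
        from combmorph.geometry import tree_points_2d
        hull = ConvexHull(tree_points_2d(comb))
        assert m["spanning_area"] == pytest.approx(hull.volume, rel=1e-9)
        assert m["cable_density"] == pytest.approx(
            comb.total_length / hull.volume, rel=1e-9
        )

    def test_scaled_length_area_invariant(self, comb):
        from combmorph.geometry import spanning_area
        scaled = cm.scale_to_area(comb, 100.0)
        assert spanning_area(scaled) == pytest.approx(100.0, abs=0.1)
        m = cm.compute_morphometrics(comb)
        assert m["scaled_length"] == pytest.approx(scaled.total_length, rel=1e-6)


class TestBootstrap:
    def test_identical_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 100)
        diff, p = cm.bootstrap_median_test(a, a.copy(), n_boot=2000, seed=1)
        assert diff == 0.0
        assert p > 0.5

    def test_constant_samples(self):
        diff, p = cm.bootstrap_median_test(np.ones(10), np.ones(15), n_boot=1000, seed=0)
        assert p == 1.0

    def test_separated_samples_significant(self):
        # N(0,1) vs N(2,1) at n=200 rejects decisively for every seed tried
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a, b = rng.normal(0, 1, 200), rng.normal(2, 1, 200)
            _, p = cm.bootstrap_median_test(a, b, n_boot=2000, seed=seed)
            assert p < 0.001

    def test_reproducible(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 50)
        r1 = cm.bootstrap_median_test(a, b, n_boot=1000, seed=7)
        r2 = cm.bootstrap_median_test(a, b, n_boot=1000, seed=7)
        assert r1 == r2
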