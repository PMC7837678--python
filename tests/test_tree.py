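import io

import numpy as np
import pytest

import combmorph as cm
from combmorph.tree import SWCFormatError, Tree

from conftest import make_path_tree, make_y_tree, make_manual_comb, swc_from_text


CHAIN_SWC = """# three-node chain
1 3 0 0 0 0.5 -1
2 3 0 1 0 0.5 1
3 3 0 2 0 0.5 2
"""

Y_SWC = """1 3 0 0 0 0.5 -1
2 3 0 1 0 0.5 1
3 3 1 2 0 0.5 2
4 3 -1 2 0 0.5 2
"""


class TestReadSWC:
    def test_chain(self):
        t = swc_from_text(CHAIN_SWC)
        assert t.n_nodes == 3
        assert int(t.is_branch_point().sum()) == 0
        assert int(t.is_terminal().sum()) == 1

    def test_y_shape(self):
        t = swc_from_text(Y_SWC)
        assert int(t.is_branch_point().sum()) == 1
        assert int(t.is_terminal().sum()) == 2

    def test_multiple_roots_rejected(self):
        bad = "1 3 0 0 0 0.5 -1\n2 3 0 1 0 0.5 -1\n"
        with pytest.raises(SWCFormatError, match="root"):
            swc_from_text(bad)

    def test_dangling_parent_rejected(self):
        bad = "1 3 0 0 0 0.5 -1\n2 3 0 1 0 0.5 7\n"
        with pytest.raises(SWCFormatError, match="dangling"):
            swc_from_text(bad)

    def test_roundtrip_bit_exact(self, comb):
        buf = io.StringIO()
        cm.write_swc(comb, buf)
        buf.seek(0)
        again = cm.read_swc(buf)
        order = comb._traversal_order()
        assert np.array_equal(comb.xyz[order], again.xyz)
        assert np.array_equal(comb.radii[order], again.radii)
        assert int(again.is_branch_point().sum()) == int(comb.is_branch_point().sum())
        assert int(again.is_terminal().sum()) == int(comb.is_terminal().sum())


class TestTreeInvariants:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Tree(
                xyz=np.zeros((3, 3)),
                radii=np.ones(3),
                parent=np.array([-1, 2, 1]),
            )

    def test_counts_and_lengths_path(self):
        t = make_path_tree(length=7.0, n_nodes=8)
        N, L = cm.counts_and_lengths(t)
        assert N == 0
        assert L == pytest.approx(7.0)

    def test_counts_binary_tree(self):
        # stem with two arms, each arm splitting again: 3 branch points
        t = make_y_tree()
        for tip in t.terminals():
            for sgn in (1.0, -1.0):
                d = np.array([sgn * 0.3, 0.8]) / np.hypot(0.3, 0.8)
                pts = t.xyz[int(tip), :2] + d[None, :] * np.array([[1.0], [2.0]])
                t = cm.tree.add_branch(t, int(tip), pts)
        assert int(t.is_branch_point().sum()) == 3

    def test_total_length_matches_edge_sum(self, comb):
        brute = sum(
            np.linalg.norm(comb.xyz[i] - comb.xyz[p])
            for i, p in enumerate(comb.parent)
            if p >= 0
        )
        assert comb.total_length == pytest.approx(brute, rel=1e-12)


class TestResample:
    def test_straight_segment(self):
        t = make_path_tree(length=10.0, n_nodes=3)
        r = cm.resample_tree(t, 1.0)
        assert r.n_nodes == 11
        assert r.total_length == pytest.approx(10.0)

    def test_topology_preserved(self):
        t = make_y_tree()
        r = cm.resample_tree(t, 0.1)
        assert int(r.is_branch_point().sum()) == int(t.is_branch_point().sum())
        assert int(r.is_terminal().sum()) == int(t.is_terminal().sum())

    @pytest.mark.parametrize("spacing", [0.1, 1.0])
    def test_length_preserved(self, comb, spacing):
        r = cm.resample_tree(comb, spacing)
        assert r.total_length == pytest.approx(comb.total_length, rel=0.01)

    def test_idempotent(self, comb):
        spacing = 0.5
        once = cm.resample_tree(comb, spacing)
        twice = cm.resample_tree(once, spacing)
        assert once.n_nodes == twice.n_nodes
        assert np.abs(once.xyz - twice.xyz).max() < spacing / 100

    def test_positive_segments(self, comb):
        r = cm.resample_tree(comb, 0.3)
        seg = r.segment_lengths()
        assert np.all(seg[np.arange(r.n_nodes) != r.root] > 0)


class TestDissect:
    def test_y_tree(self):
        assert len(cm.dissect_terminal_branches(make_y_tree())) == 2

    def test_comb_five_laterals(self):
        t = make_manual_comb([2.0, 2.5, 3.0, 3.5, 4.0])
        # 5 laterals plus the main-branch tip
        assert len(cm.dissect_terminal_branches(t)) == 6

    def test_path_graph_single_branch(self):
        t = make_path_tree(length=10.0, n_nodes=11)
        tbs = cm.dissect_terminal_branches(t)
        assert len(tbs) == 1
        assert tbs[0].origin == t.root
        assert tbs[0].length == pytest.approx(10.0)

    def test_lengths_partition_cable(self, comb):
        tbs = cm.dissect_terminal_branches(comb)
        seg = comb.segment_lengths()
        terminal_nodes = set()
        for tb in tbs:
            terminal_nodes.update(tb.node_path[1:])
        terminal_cable = sum(seg[i] for i in terminal_nodes)
        assert sum(tb.length for tb in tbs) == pytest.approx(terminal_cable, rel=1e-12)
        non_terminal = comb.total_length - terminal_cable
        assert terminal_cable + non_terminal == pytest.approx(comb.total_length)


class TestEditing:
    def test_remove_terminal_branch_counts(self, comb):
        tbs = cm.dissect_terminal_branches(comb)
        before_t = int(comb.is_terminal().sum())
        before_b = int(comb.is_branch_point().sum())
        out, _ = cm.tree.remove_terminal_branch(comb, tbs[0])
        assert int(out.is_terminal().sum()) == before_t - 1
        assert before_b - int(out.is_branch_point().sum()) in (0, 1)
        assert out.total_length < comb.total_length

    def test_trim_exact_amount(self):
        t = make_manual_comb([5.0])
        tb = [b for b in cm.dissect_terminal_branches(t) if b.length < 10][0]
        out, _ = cm.tree.trim_terminal_branch(t, tb, 2.0)
        assert out.total_length == pytest.approx(t.total_length - 2.0, abs=1e-3)

    def test_trim_whole_branch_removes_it(self):
        t = make_manual_comb([5.0])
        tb = [b for b in cm.dissect_terminal_branches(t) if b.length < 10][0]
        out, _ = cm.tree.trim_terminal_branch(t, tb, 99.0)
        assert int(out.is_terminal().sum()) == int(t.is_terminal().sum()) - 1
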