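import dataclasses

import numpy as np
import pytest
import shapely

import combmorph as cm
from combmorph.growth import _lateral_terminal_branches, _mark_mb
from combmorph.tracking import track_series
from combmorph.tree import TimeSeries, add_branch, dissect_terminal_branches


@pytest.fixture(scope="module")
def arena():
    return cm.make_arena()


@pytest.fixture(scope="module")
def fast_params():
    return cm.GrowthParams(n_probe=3000, b_r=4.0)


@pytest.fixture(scope="module")
def sim(arena, fast_params):
    return cm.simulate_development(arena, fast_params, seed=11)


def nodes_inside(tree, contour):
    xy = tree.xyz[:, :2]
    inside = shapely.contains_xy(contour, xy[:, 0], xy[:, 1])
    edge = shapely.dwithin(
        contour.exterior, shapely.points(xy[:, 0], xy[:, 1]), 1e-6
    )
    return bool(np.all(inside | edge))


class TestGrowStep:
    def test_first_attachment_within_radius(self, arena, fast_params):
        rng = np.random.default_rng(0)
        state = _mark_mb(arena.mb)
        out = cm.grow_step(state, arena, fast_params, rng, n_branches=1)
        new = out.xyz[state.n_nodes:, :2]
        assert len(new) >= 1
        d = np.min(
            np.linalg.norm(new[:, None, :] - state.xyz[None, :, :2], axis=2), axis=1
        )
        assert np.all(d <= fast_params.r_grow_pre + 1e-9)

    def test_segment_cap(self, sim, fast_params):
        # grown cable is subdivided at the attachment spacing (the initial
        # main branch keeps its own coarser node spacing)
        final = sim.trees[-1]
        seg = final.segment_lengths()
        new = final.ntype == 3
        assert new.any()
        assert seg[new].max() <= fast_params.attach_spacing + 1e-9

    def test_nodes_inside_contour(self, sim, arena):
        assert nodes_inside(sim.trees[-1], arena.contour)


class TestRetractionStep:
    def test_full_shorten_removes_all_laterals(self, arena, fast_params, sim):
        tree = sim.trees[14]  # mid-development, has lateral branches
        rng = np.random.default_rng(1)
        out = cm.retraction_step(
            tree, arena, fast_params,
            shorten_fraction=1.0, shorten_length=1e6, new_fraction=0.0,
            radius=2.5, rng=rng,
        )
        assert len(_lateral_terminal_branches(out)) == 0

    def test_zero_fraction_identity(self, arena, fast_params, sim):
        tree = sim.trees[14]
        rng = np.random.default_rng(1)
        out = cm.retraction_step(
            tree, arena, fast_params,
            shorten_fraction=0.0, shorten_length=1.8, new_fraction=0.0,
            radius=2.5, rng=rng,
        )
        assert np.array_equal(out.xyz, tree.xyz)

    def test_expected_cable_removed(self, arena, fast_params, sim):
        tree = sim.trees[14]
        frac, ell = 0.5, 1.5
        terminals = _lateral_terminal_branches(tree)
        n_sel = int(np.floor(frac * len(terminals) + 0.5))
        # expectation over uniform subsets of fixed size
        per_branch = np.array([min(ell, tb.length) for tb in terminals])
        expected = n_sel * per_branch.mean()
        removed = []
        for s in range(100):
            rng = np.random.default_rng(1000 + s)
            out = cm.retraction_step(
                tree, arena, fast_params,
                shorten_fraction=frac, shorten_length=ell, new_fraction=0.0,
                radius=2.5, rng=rng,
            )
            removed.append(tree.total_length - out.total_length)
        removed = np.array(removed)
        sem = removed.std() / 10
        assert abs(removed.mean() - expected) < 4 * sem + 0.05


class TestSimulateDevelopment:
    def test_pure_growth_monotone_roughly_linear(self, arena):
        p = cm.GrowthParams(
            n_probe=3000, b_r=3.0, poisson_branching=False,
            shorten_fraction=(0.0,) * 6, new_fraction=(0.0,) * 6,
        )
        series = cm.simulate_development(arena, p, seed=5, with_retraction=False)
        bp = series.branch_point_counts()
        assert np.all(np.diff(bp) >= 0)
        r = np.corrcoef(series.times, bp)[0, 1]
        assert r > 0.97

    def test_seeded_reproducibility(self, arena, fast_params, sim):
        again = cm.simulate_development(arena, fast_params, seed=11)
        assert np.array_equal(sim.trees[-1].xyz, again.trees[-1].xyz)
        other = cm.simulate_development(arena, fast_params, seed=12)
        assert not np.array_equal(sim.trees[-1].xyz, other.trees[-1].xyz)

    def test_doubling_branch_rate_doubles_increments(self, arena):
        counts = {}
        for b_r in (2.0, 4.0):
            finals = []
            for s in range(8):
                p = cm.GrowthParams(n_probe=2000, b_r=b_r)
                series = cm.simulate_development(
                    arena, p, seed=100 + s, with_retraction=False
                )
                finals.append(series.branch_point_counts()[-1])
            counts[b_r] = np.mean(finals)
        ratio = counts[4.0] / counts[2.0]
        assert 1.5 < ratio < 2.5

    def test_all_frames_inside_contour(self, sim, arena):
        for t in sim.trees[:: max(len(sim) // 6, 1)]:
            assert nodes_inside(t, arena.contour)


class TestExtractParameters:
    def test_recovers_planted_rates(self):
        """Series built by hand: 4 clean interstitial branches per hour
        of fixed 2.2 µm length, and known retractions."""
        from combmorph.synthetic import _clean_attach_nodes, _polyline

        base, _ = cm.make_comb_tree(
            cm.CombParams(n_laterals=10, mean_children_per_lateral=0.0), seed=8
        )
        rng = np.random.default_rng(3)
        times = [16.5, 17.5, 18.5, 19.5]
        tree = base
        frames = [tree]
        reg_rows = []
        track = {}
        next_track = 0
        plen = tree.path_length_to_root()
        mb_tip_id = int(tree.node_ids[int(np.argmax(plen))])
        for tb in dissect_terminal_branches(tree):
            nid = int(tree.node_ids[tb.tip])
            if nid == mb_tip_id:
                continue
            track[nid] = next_track
            reg_rows.append(dict(frame=0, node_id=nid, track_id=next_track))
            next_track += 1
        for f in range(1, len(times)):
            for _ in range(4):
                sites = _clean_attach_nodes(
                    tree,
                    {int(np.flatnonzero(tree.node_ids == m)[0]) for m in track},
                )
                # continuation nodes only: each sprout adds one branch point
                sites = sites[tree.n_children()[sites] == 1]
                attach = int(rng.choice(sites))
                th = np.radians(rng.uniform(30, 70))
                side = rng.choice([-1.0, 1.0])
                d = np.array([side * np.sin(th), np.cos(th)])
                pts = _polyline(tree.xyz[attach, :2], d, 2.2, 0.5)
                tree = add_branch(tree, attach, pts)
                nid = int(tree.node_ids[tree.n_nodes - 1])
                track[nid] = next_track
                next_track += 1
            frames.append(tree)
            for nid, tr in track.items():
                reg_rows.append(dict(frame=f, node_id=nid, track_id=tr))
        import pandas as pd

        series = TimeSeries(
            times=np.array(times), trees=frames,
            registration=pd.DataFrame(reg_rows),
        )
        events = track_series(series)
        params = cm.extract_growth_parameters(
            series, events, bin_edges=(16.0, 17.5, 18.5, 19.5),
            base=cm.GrowthParams(
                retraction_times=(16.5, 17.5, 18.5),
                shorten_fraction=(0.0,) * 3, new_fraction=(0.0,) * 3,
                shorten_length=(0.0,) * 3,
            ),
        )
        # 4 interstitial branch points per hour -> 1 per 15-min iteration
        assert params.b_r == pytest.approx(1.0, abs=1e-9)
        # growth radius = mean length of newly formed branches
        assert params.r_grow_pre == pytest.approx(2.2, abs=1e-6)
        assert params.new_fraction[1] > 0

    def test_missing_bins_error(self, timelapse, tracked_events):
        series, _ = timelapse
        with pytest.raises(ValueError, match="no events in bins"):
            cm.extract_growth_parameters(
                series, tracked_events, bin_edges=(16.0, 17.5, 40.0, 41.0)
            )
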