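"""Trajectory metrics: preprocessing, tortuosity, Fréchet, occupancy, circular spread."""

import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pushpull import agents
from pushpull.kinematics import (
    DegenerateTrajectoryError,
    Trajectory,
    Workspace,
    angular_deviation,
    explored_area,
    frechet_distance,
    mean_angular_deviation,
    movement_velocity,
    preprocess,
    session_frechet_mean,
    summarize_session,
    tortuosity,
    workspace_from_trajectories,
)


def traj(points, t=None, **kw):
    pts = np.asarray(points, dtype=float)
    if t is None:
        t = np.arange(len(pts), dtype=float)
    return Trajectory(t=t, x=pts[:, 0], y=pts[:, 1], **kw)


def frechet_oracle(p, q):
    """Memoized naive recursion — the textbook definition."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)

    @functools.lru_cache(maxsize=None)
    def c(i, j):
        d = float(np.linalg.norm(p[i] - q[j]))
        if i == 0 and j == 0:
            return d
        if i == 0:
            return max(c(0, j - 1), d)
        if j == 0:
            return max(c(i - 1, 0), d)
        return max(min(c(i - 1, j), c(i, j - 1), c(i - 1, j - 1)), d)

    return c(len(p) - 1, len(q) - 1)


class TestPreprocess:
    def test_dedup_and_center(self):
        tr = preprocess(traj([(1, 1), (1, 1), (2, 2)]))
        assert len(tr) == 2
        # medians of [(1,1),(2,2)] are (1.5, 1.5)
        assert np.allclose(tr.points, [(-0.5, -0.5), (0.5, 0.5)])

    def test_symmetric_path_unchanged(self):
        pts = [(-1, 0), (0, 0), (1, 0)]
        tr = preprocess(traj(pts))
        assert np.allclose(tr.points, pts)

    def test_median_shift(self):
        pts = np.array([(3.0, -1.0), (4.0, -1.0), (3.0, 2.0)])
        tr = preprocess(traj(pts))
        assert np.allclose(tr.points, pts - [3.0, -1.0])

    def test_all_identical_degenerate(self):
        with pytest.raises(DegenerateTrajectoryError):
            preprocess(traj([(1, 1), (1, 1), (1, 1)]))


class TestTortuosity:
    def test_straight_path_is_one(self):
        assert tortuosity(traj([(0, 0), (1, 0), (3, 0)])) == pytest.approx(1.0)

    def test_right_angle_path(self):
        # legs 3 + 4 over chord 5
        assert tortuosity(traj([(0, 0), (3, 0), (3, 4)])) == pytest.approx(1.4)

    def test_closed_loop_excluded(self):
        with pytest.raises(DegenerateTrajectoryError):
            tortuosity(traj([(0, 0), (2, 2), (0, 0)]))

    def test_outbound_mode_handles_closed_loop(self):
        val = tortuosity(traj([(0, 0), (2, 0), (0, 0)]), segment="outbound")
        assert val == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=2, max_size=12
        )
    )
    def test_at_least_one(self, pts):
        try:
            assert tortuosity(traj(pts)) >= 1.0 - 1e-12
        except DegenerateTrajectoryError:
            pass


class TestFrechet:
    def test_identical_is_zero(self):
        p = traj([(0, 0), (1, 1), (2, 0)])
        assert frechet_distance(p, p) == 0.0

    def test_parallel_segments(self):
        assert frechet_distance(
            [(0, 0), (1, 0)], [(0, 1), (1, 1)]
        ) == pytest.approx(1.0)

    def test_matches_recursive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            p = rng.uniform(-3, 3, size=(rng.integers(1, 7), 2))
            q = rng.uniform(-3, 3, size=(rng.integers(1, 7), 2))
            assert frechet_distance(p, q) == pytest.approx(
                frechet_oracle(p, q), abs=1e-12
            )

    def test_symmetry_and_endpoint_lower_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(-3, 3, size=(5, 2))
            q = rng.uniform(-3, 3, size=(6, 2))
            d = frechet_distance(p, q)
            assert d == pytest.approx(frechet_distance(q, p))
            lb = max(
                np.linalg.norm(p[0] - q[0]), np.linalg.norm(p[-1] - q[-1])
            )
            assert d >= lb - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frechet_distance(np.empty((0, 2)), np.array([[0.0, 0.0]]))


class TestSessionFrechetMean:
    def test_identical_trajectories_zero(self):
        p = traj([(0, 0), (1, 1)])
        assert session_frechet_mean([p, p, p]) == 0.0

    def test_mean_of_pairwise_distances(self):
        # single-point curves at 0, 1, 3 -> pairwise distances 1, 3, 2
        ts = [traj([(v, 0)]) for v in (0.0, 1.0, 3.0)]
        assert session_frechet_mean(ts) == pytest.approx(2.0)

    def test_fewer_than_two_undefined(self):
        with pytest.raises(ValueError):
            session_frechet_mean([traj([(0, 0), (1, 0)])])

    def test_tight_cluster_smaller_than_dispersed(self):
        rng = np.random.default_rng(14)
        tight = [
            Trajectory.from_trace(
                agents.generate_trajectory_2d(
                    agents.TrajectoryStyle(stage=1.0, jitter_mm=0.2), rng
                )
            )
            for _ in range(8)
        ]
        loose = [
            Trajectory.from_trace(
                agents.generate_trajectory_2d(
                    agents.TrajectoryStyle(stage=0.0, jitter_mm=3.0), rng
                )
            )
            for _ in range(8)
        ]
        assert session_frechet_mean(tight) < session_frechet_mean(loose)


class TestMovementVelocity:
    def test_straight_excursion(self):
        tr = traj([(0, 0), (2, 0), (4, 0)], t=np.array([0.0, 100.0, 200.0]))
        assert movement_velocity(tr) == pytest.approx(20.0)

    def test_time_scaling(self):
        tr1 = traj([(0, 0), (4, 0)], t=np.array([0.0, 200.0]))
        tr2 = traj([(0, 0), (4, 0)], t=np.array([0.0, 400.0]))
        assert movement_velocity(tr1) == pytest.approx(2 * movement_velocity(tr2))

    def test_uses_turning_point_not_endpoint(self):
        tr = traj(
            [(0, 0), (4, 0), (1, 0)], t=np.array([0.0, 100.0, 300.0])
        )
        # max displacement (4 mm) reached at 100 ms, not the 1 mm endpoint
        assert movement_velocity(tr) == pytest.approx(40.0)

    def test_zero_interval_rejected(self):
        with pytest.raises(ValueError):
            movement_velocity(traj([(0, 0), (0, 0)], t=np.array([0.0, 10.0])))


class TestExploredArea:
    WS = Workspace(0.0, 10.0, 0.0, 10.0)

    def test_stationary_point_one_bin(self):
        area, _ = explored_area(traj([(2.5, 2.5), (2.5, 2.5)]), self.WS)
        assert area == 1.0

    def test_half_open_bins_along_a_line(self):
        # 5.5 mm span starting at a bin edge touches 6 bins
        xs = np.linspace(1.0, 6.5, 200)
        tr = traj(np.column_stack([xs, np.full_like(xs, 0.5)]))
        area, _ = explored_area(tr, self.WS)
        assert area == 6.0

    def test_outside_point_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            explored_area(traj([(11.0, 1.0)]), self.WS)

    def test_union_subadditivity(self):
        a = traj([(1.2, 1.2), (2.2, 1.2)])
        b = traj([(1.2, 1.2), (1.2, 2.2)])
        area_a, _ = explored_area(a, self.WS)
        area_b, _ = explored_area(b, self.WS)
        area_ab, _ = explored_area([a, b], self.WS)
        assert area_ab <= area_a + area_b

    def test_grid_counts_sum_to_samples(self):
        tr = traj([(0.5, 0.5), (1.5, 0.5), (2.5, 0.5)])
        _, grid = explored_area(tr, self.WS)
        assert grid.sum() == 3


class TestAngularDeviation:
    def test_identical_angles_zero(self):
        assert angular_deviation([0.7] * 10) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_angles_sqrt2(self):
        a = np.linspace(0, 2 * np.pi, 360, endpoint=False)
        assert angular_deviation(a) == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_opposite_pair_sqrt2(self):
        assert angular_deviation([0.0, np.pi]) == pytest.approx(np.sqrt(2))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 2 * np.pi, 40)
        assert angular_deviation(a) == pytest.approx(angular_deviation(a + 1.1))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    def test_range(self, angles):
        assert 0.0 <= angular_deviation(angles) <= np.sqrt(2) + 1e-12

    def test_session_mean_pools_by_bin(self):
        ws = Workspace(-5.0, 5.0, -5.0, 5.0)
        # straight parallel paths: every bin's angles are identical -> 0
        t1 = traj([(-2, 0.5), (-1, 0.5), (0, 0.5), (1, 0.5)])
        t2 = traj([(-2, 0.5), (-1, 0.5), (0, 0.5), (1, 0.5)])
        assert mean_angular_deviation([t1, t2], ws) == pytest.approx(0.0, abs=1e-12)


def staged_batches(n=25, stages=(0.0, 0.5, 1.0), seed=31):
    rng = np.random.default_rng(seed)
    out = {}
    for stage in stages:
        batch = []
        for k in range(n):
            style = agents.TrajectoryStyle(
                stage=stage, direction="push" if k % 2 else "pull",
                speed_mm_s=80.0,
            )
            tr = agents.generate_trajectory_2d(style, rng)
            # decimate for the pairwise Fréchet sweep
            sl = slice(None, None, 4)
            batch.append(
                Trajectory(
                    t=tr.t[sl], x=tr.x[sl], y=tr.y[sl],
                    label=style.direction, trial=k,
                )
            )
        out[stage] = batch
    return out


def test_learning_stage_trends():
    """Expert batches are straighter, more similar, more compact, faster.

    The synthetic analogue of the training-course trends: mean tortuosity,
    session Fréchet mean and explored area all non-increasing in stage;
    movement velocity non-decreasing.
    """
    batches = staged_batches()
    ws = workspace_from_trajectories(
        [t for batch in batches.values() for t in batch]
    )
    tort, frech, area, vel = [], [], [], []
    for stage in sorted(batches):
        batch = batches[stage]
        tort.append(np.mean([tortuosity(t, segment="outbound") for t in batch]))
        frech.append(session_frechet_mean(batch))
        area.append(explored_area(batch, ws)[0])
        vel.append(np.mean([movement_velocity(t) for t in batch]))
    assert tort[0] >= tort[1] >= tort[2]
    assert frech[0] >= frech[1] >= frech[2]
    assert area[0] >= area[1] >= area[2]
    assert vel[0] <= vel[1] <= vel[2]


def test_summarize_session_reports_exclusions():
    good = traj([(0, 0), (1, 0), (3, 1)], label="push")
    closed = traj([(0, 0), (1, 1), (0, 0)], label="push")
    out = summarize_session([good, closed], do_preprocess=False,
                            tortuosity_segment="full")
    assert len(out.tortuosity) == 1
    assert len(out.excluded) == 1
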