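"""Local diffusion maps, eccentricity windows and ECS width estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from ecs_rheomap import nanotube, simkit


class TestDinstError:
    def test_worked_example_30nm_3x30ms(self):
        assert nanotube.dinst_error(0.030, 3, 0.030) == pytest.approx(0.01)

    def test_quadratic_in_precision(self):
        assert nanotube.dinst_error(0.060) == pytest.approx(4 * nanotube.dinst_error(0.030))

    def test_zero_precision_zero_error(self):
        assert nanotube.dinst_error(0.0) == 0.0

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            nanotube.dinst_error(0.03, 0, 0.030)

    def test_error_model_container_consistent(self):
        em = nanotube.ErrorModel(dx=0.030, t_fit=0.090)
        assert em.delta_D == pytest.approx(0.01)


class TestDriftCorrection:
    @staticmethod
    def _table(tracks):
        rows = [{"traj_id": tid, "frame": f, "x_um": x, "y_um": y}
                for tid, pts in tracks.items() for f, (x, y) in enumerate(pts)]
        return pd.DataFrame(rows)

    def test_zero_drift_identity(self):
        df = self._table({0: [(0.0, 0.0)] * 3,
                          1: [(1.0, 1.0), (1.1, 1.0), (1.2, 1.0)]})
        out = nanotube.correct_drift(df, [0])
        pd.testing.assert_frame_equal(out, df)

    def test_injected_linear_drift_removed(self, rng):
        drift = 0.005  # 5 nm/frame
        n = 50
        ref = [(drift * f, 0.0) for f in range(n)]
        free = [(1.0 + drift * f + 0.0 * f, 2.0) for f in range(n)]
        df = self._table({0: ref, 1: free})
        out = nanotube.correct_drift(df, [0])
        moving = out[out["traj_id"] == 1].sort_values("frame")
        residual = np.diff(moving["x_um"].to_numpy())
        assert np.all(np.abs(residual) < 0.001)  # < 1 nm/frame

    def test_identical_references_match_single_reference(self):
        ref = [(0.01 * f, -0.02 * f) for f in range(10)]
        target = [(5.0, 5.0)] * 10
        one = nanotube.correct_drift(self._table({0: ref, 2: target}), [0])
        two = nanotube.correct_drift(self._table({0: ref, 1: ref, 2: target}), [0, 1])
        pd.testing.assert_frame_equal(one[one.traj_id == 2].reset_index(drop=True),
                                      two[two.traj_id == 2].reset_index(drop=True))

    def test_no_references_warns_and_keeps_input(self):
        df = self._table({1: [(0, 0), (1, 1)]})
        with pytest.warns(UserWarning, match="reference"):
            out = nanotube.correct_drift(df, [99])
        pd.testing.assert_frame_equal(out, df)


class TestSlidingDinst:
    def test_static_positions_give_zero(self):
        d = nanotube.sliding_dinst(np.zeros((20, 2)), 0.033)
        assert (d["local_D"] == 0).all()

    def test_short_trajectory_empty_series(self):
        d = nanotube.sliding_dinst(np.zeros((5, 2)), 0.033)
        assert len(d) == 0

    def test_free_walk_median_recovery_within_15_percent(self):
        D = 0.038
        trajs = simkit.simulate_free_trajectories(D, 40, 300, 0.033, rng=17)
        meds = []
        for t in trajs:
            d = nanotube.sliding_dinst(t.positions, 0.033)
            meds.append(d["local_D"].median())
        assert np.median(meds) == pytest.approx(D, rel=0.15)

    def test_piecewise_diffusivity_resolved(self):
        """A trajectory that switches from D=0.02 to D=0.10 halfway shows a
        ~5x step between the window medians of the two halves."""
        rng = np.random.default_rng(23)
        dt = 0.033
        n = 400
        steps_a = rng.normal(0, math.sqrt(2 * 0.02 * dt), (n // 2, 2))
        steps_b = rng.normal(0, math.sqrt(2 * 0.10 * dt), (n // 2, 2))
        pos = np.vstack([np.zeros((1, 2)),
                         np.cumsum(np.vstack([steps_a, steps_b]), axis=0)])
        d = nanotube.sliding_dinst(pos, dt)
        first = d[d.window_index < n // 2 - 10]["local_D"].median()
        second = d[d.window_index > n // 2]["local_D"].median()
        assert second / first == pytest.approx(5.0, rel=0.5)


class TestExcludeImmobile:
    @staticmethod
    def _table(tracks):
        rows = [{"traj_id": tid, "frame": f, "x_um": x, "y_um": y}
                for tid, pts in tracks.items() for f, (x, y) in enumerate(pts)]
        return pd.DataFrame(rows)

    def test_jitter_only_excluded_free_walk_retained(self, rng):
        jit = [(x, y) for x, y in rng.normal(0, 0.03, (80, 2))]
        walk = simkit.simulate_free_trajectories(0.05, 1, 80, 0.033, rng=3)[0]
        df = self._table({0: jit, 1: [tuple(p) for p in walk.positions]})
        kept, report = nanotube.exclude_immobile(df, 0.033)
        assert set(kept["traj_id"]) == {1}
        assert set(report.columns) >= {"traj_id", "plateau_ratio", "global_D", "excluded"}
        assert len(report) == 2


class TestEccentricity:
    def test_isotropic_cloud_near_one(self, rng):
        pos = rng.normal(0, 1.0, (600, 2))
        ecc = nanotube.window_eccentricity(pos, window=600, precision=0.0)
        assert ecc["eccentricity"].iloc[0] == pytest.approx(1.0, abs=0.15)

    def test_collinear_points_flagged_infinite_without_floor(self):
        pos = np.column_stack([np.arange(6.0), np.zeros(6)])
        ecc = nanotube.window_eccentricity(pos, precision=0.0)
        assert math.isinf(ecc["eccentricity"].iloc[0])
        assert ecc["flags"].iloc[0] == "collinear"

    def test_noisy_line_large_eccentricity(self, rng):
        x = np.linspace(0, 10, 50)
        pos = np.column_stack([x, rng.normal(0, 0.01, 50)])
        ecc = nanotube.window_eccentricity(pos, window=50, precision=0.01)
        assert ecc["eccentricity"].iloc[0] > 10

    def test_two_to_one_gaussian_cloud_approaches_two(self, rng):
        pos = rng.normal(0, 1.0, (5000, 2)) * [2.0, 1.0]
        ecc = nanotube.window_eccentricity(pos, window=5000, precision=0.0)
        assert ecc["eccentricity"].iloc[0] == pytest.approx(2.0, rel=0.05)

    def test_rotation_invariance(self, rng):
        pos = rng.normal(0, 1.0, (6, 2)) * [3.0, 1.0]
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        e0 = nanotube.window_eccentricity(pos, precision=0.01)["eccentricity"].iloc[0]
        e1 = nanotube.window_eccentricity(pos @ rot.T, precision=0.01)["eccentricity"].iloc[0]
        assert e1 == pytest.approx(e0, rel=1e-9)


class TestSelectMaxConfinement:
    def test_monotone_series_picks_last(self):
        assert nanotube.select_max_confinement([1.0, 2.0, 3.0]) == 2

    def test_single_window(self):
        assert nanotube.select_max_confinement([5.0]) == 0

    def test_tie_picks_earliest(self):
        assert nanotube.select_max_confinement([1.0, 7.0, 7.0, 2.0]) == 1

    def test_all_infinite_is_missing(self):
        assert nanotube.select_max_confinement([math.inf, math.nan]) is None

    def test_infinite_entries_skipped(self):
        assert nanotube.select_max_confinement([math.inf, 3.0, 2.0]) == 1


class TestWidthEstimation:
    def test_noise_free_uniform_channel_recovers_range(self, rng):
        """sqrt(12)·SD of uniform transverse occupancy equals the range:
        a noise-free 100 nm channel reads back 100 nm (before calibration)."""
        n = 20_000
        pos = np.column_stack([rng.normal(0, 10.0, n),
                               rng.uniform(-0.05, 0.05, n)])
        w, below = nanotube.estimate_local_width(pos, precision=0.0, calibration=1.0)
        assert not below
        assert w == pytest.approx(100.0, rel=0.02)

    def test_spread_at_noise_floor_flagged(self, rng):
        pos = rng.normal(0, 0.030, (30, 2))
        pos[:, 0] += np.linspace(0, 1, 30)   # elongate major axis
        w, below = nanotube.estimate_local_width(
            np.column_stack([np.linspace(0, 1, 30), np.zeros(30)]), precision=0.030)
        assert below and w == 0.0

    @pytest.mark.parametrize("width_nm", [60.0, 78.0, 100.0, 140.0])
    def test_median_width_recovery_within_20_percent(self, width_nm):
        """Channel simulations across the physiological width range recover
        the true width within 20% with the one-time frozen calibration."""
        trajs = simkit.simulate_channel_trajectories(
            width_nm, D=0.04, n_trajectories=120, n_frames=100,
            jitter=0.030, rng=int(width_nm))
        widths = [nanotube.trajectory_width(t.positions).width_nm for t in trajs]
        assert np.median(widths) == pytest.approx(width_nm, rel=0.20)


class TestLocalMap:
    def test_map_schema_and_width_at_max_confinement(self):
        trajs = simkit.simulate_channel_trajectories(
            100.0, n_trajectories=1, n_frames=60, jitter=0.030, rng=5)
        m = nanotube.local_map(trajs[0].positions, 0.033)
        assert {"window_index", "x_um", "y_um", "local_D",
                "eccentricity", "width_nm"} <= set(m.columns)
        assert m["width_nm"].notna().sum() == 1

    def test_homogeneous_map_has_no_spatial_trend(self):
        """Local D in homogeneous free diffusion shows no spatial trend:
        regressing each trajectory's median local D on its mean position
        (independent samples) gives a slope consistent with zero."""
        from scipy import stats
        rng = np.random.default_rng(29)
        xs, ds = [], []
        for i in range(120):
            t = simkit.simulate_free_trajectories(0.05, 1, 60, 0.033, rng=rng)[0]
            offset = rng.uniform(-20, 20)
            m = nanotube.sliding_dinst(t.positions + [offset, 0.0], 0.033)
            xs.append(m["x_um"].mean())
            ds.append(m["local_D"].median())
        res = stats.linregress(xs, ds)
        assert abs(res.slope) < 3 * res.stderr
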