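import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from accumtowers.agents import AgentSpec, TrajectoryParams, simulate_dataset
from accumtowers.datamodel import UndefinedStatisticError
from accumtowers.kinematics import (
    DEFAULT_Y_GRID,
    choice_decoder,
    speed_summary,
    tower_triggered_view_angle,
    trajectory_angles_on_grid,
    view_angle_at,
    view_angle_by_evidence,
)

from conftest import make_trial


class TestViewAngleAt:
    def test_exact_sample(self):
        y = np.array([0.0, 50.0, 100.0])
        th = np.array([0.0, 0.1, 0.2])
        assert view_angle_at(y, th, 50.0) == pytest.approx(0.1)

    def test_backtracking_first_crossing(self):
        y = np.array([0.0, 50.0, 40.0, 60.0])
        th = np.deg2rad([0.0, 5.0, 6.0, 7.0])
        assert view_angle_at(y, th, 45.0) == pytest.approx(np.deg2rad(5.0))

    def test_y_zero_first_sample(self):
        y = np.array([0.0, 10.0])
        th = np.array([0.42, 0.5])
        assert view_angle_at(y, th, 0.0) == pytest.approx(0.42)

    def test_unreached_position(self):
        with pytest.raises(UndefinedStatisticError):
            view_angle_at(np.array([0.0, 100.0]), np.array([0.0, 0.1]), 150.0)

    def test_resampling_stability(self):
        # finer sampling of the same monotone path moves the first-crossing
        # sample by at most one step of the underlying profile
        t = np.linspace(0, 5, 51)
        y = 60.0 * t
        th = 0.01 * y
        coarse = view_angle_at(y, th, 123.0)
        t2 = np.linspace(0, 5, 501)
        fine = view_angle_at(60.0 * t2, 0.01 * 60.0 * t2, 123.0)
        assert abs(coarse - fine) < 0.01 * 60.0 * (t[1] - t[0]) + 1e-9


class TestChoiceDecoder:
    def test_fully_separated(self):
        theta = np.concatenate([np.full((50, 3), 1.0), np.full((50, 3), -1.0)])
        choices = ["R"] * 50 + ["L"] * 50
        res = choice_decoder(choices, theta, y_grid=np.array([0.0, 5.0, 10.0]))
        assert np.allclose(res.accuracy_percent, 100.0)

    def test_identical_distributions_chance(self, rng):
        theta = rng.normal(size=(400, 2))
        choices = ["R"] * 200 + ["L"] * 200
        res = choice_decoder(choices, theta, y_grid=np.array([0.0, 5.0]))
        assert np.all(np.abs(res.accuracy_percent - 50.0) < 10.0)

    def test_gaussian_overlap_analytic(self, rng):
        # mu = +/-1, sigma = 1: the equal-error boundary is 0 and accuracy
        # approaches Phi(1) ~ 84.1%
        n = 8000
        theta = np.concatenate([
            rng.normal(1.0, 1.0, size=(n, 1)), rng.normal(-1.0, 1.0, size=(n, 1))
        ])
        choices = ["R"] * n + ["L"] * n
        res = choice_decoder(choices, theta, y_grid=np.array([0.0]))
        assert res.boundary[0] == pytest.approx(0.0, abs=0.1)
        assert res.accuracy_percent[0] == pytest.approx(100 * norm.cdf(1.0), abs=1.5)

    def test_monotone_transform_invariance(self, rng):
        theta = np.concatenate([
            rng.normal(0.5, 1.0, size=(500, 1)), rng.normal(-0.5, 1.0, size=(500, 1))
        ])
        choices = ["R"] * 500 + ["L"] * 500
        a = choice_decoder(choices, theta, y_grid=np.array([0.0]))
        b = choice_decoder(choices, np.exp(theta), y_grid=np.array([0.0]))
        assert a.accuracy_percent[0] == pytest.approx(b.accuracy_percent[0], abs=0.5)

    def test_mirror_flips_boundary(self, rng):
        theta = np.concatenate([
            rng.normal(0.8, 1.0, size=(500, 1)), rng.normal(-0.4, 1.0, size=(500, 1))
        ])
        choices = ["R"] * 500 + ["L"] * 500
        a = choice_decoder(choices, theta, y_grid=np.array([0.0]))
        flipped = ["L" if c == "R" else "R" for c in choices]
        b = choice_decoder(flipped, -theta, y_grid=np.array([0.0]))
        assert a.boundary[0] == pytest.approx(-b.boundary[0], abs=0.05)
        assert a.accuracy_percent[0] == pytest.approx(b.accuracy_percent[0], abs=1.0)


def _traj_df(trial, speed, dt=0.05, theta_fn=lambda y: 0.0):
    rows = []
    t, y = 0.0, 0.0
    while y <= 330.0:
        rows.append((trial.mouse_id, trial.session_id, trial.trial_index,
                     t, 0.0, y, theta_fn(y)))
        y += speed * dt
        t += dt
    return pd.DataFrame(
        rows, columns=["mouse_id", "session_id", "trial_index", "t", "x", "y", "view_angle"]
    )


class TestSpeed:
    def test_constant_velocity_exact(self):
        t = make_trial((40.0,), (25.0, 80.0))
        df = _traj_df(t, 60.0)
        summary = speed_summary(df)
        assert summary.mean_speed == pytest.approx(60.0, rel=1e-9)

    def test_variability_recovery(self):
        params = TrajectoryParams(within_session_speed_sd=5.0, across_session_speed_sd=8.0,
                                  noise_sd=0.0)
        ds = simulate_dataset(
            AgentSpec(kind="k_random_tower", k=1),
            n_sessions=40, trials_per_session=25,
            rng=np.random.default_rng(31), trajectory_params=params,
            include_protocol=False,
        )
        summary = speed_summary(ds.trajectories)
        # direct SD targets; tolerances ~2 SE of an SD estimate at these n
        assert summary.within_session_sd == pytest.approx(5.0, abs=1.0)
        assert summary.across_session_sd == pytest.approx(8.0, abs=2.6)


class TestTowerTriggered:
    def test_deterministic_agent_zero_deviation(self):
        params = TrajectoryParams(noise_sd=0.0, evidence_gain_cm=0.0,
                                  within_session_speed_sd=0.0,
                                  across_session_speed_sd=0.0)
        ds = simulate_dataset(
            AgentSpec(kind="k_random_tower", k=1),
            n_sessions=2, trials_per_session=60,
            rng=np.random.default_rng(41), trajectory_params=params,
            include_protocol=False,
        )
        angles = trajectory_angles_on_grid(ds.trajectories)
        amap = {tuple(r[:3]): np.array(r[3:], dtype=float) for r in angles.to_numpy()}
        sel = [t for t in ds.trials if (t.mouse_id, t.session_id, t.trial_index) in amap]
        theta = np.array([amap[(t.mouse_id, t.session_id, t.trial_index)] for t in sel])
        res = tower_triggered_view_angle(sel, theta)
        assert np.nanmax(np.abs(res.mean_right)) < 1e-9
        assert np.nanmax(np.abs(res.mean_left)) < 1e-9

    def test_planted_step_recovered(self, rng):
        # synthetic: flat trajectories with a +0.1 rad step 10 cm after each
        # right tower only
        trials, frames = [], []
        for i in range(200):
            nl = int(rng.integers(0, 3))
            nr = nl + 1 + int(rng.integers(0, 3))
            tl = tuple(float(v) for v in np.sort(rng.uniform(10, 150, nl) // 12 * 12 + 10))
            tr = tuple(float(v) for v in np.sort(rng.uniform(10, 150, nr) // 12 * 12 + 11))
            t = make_trial(tl, tr, index=i)
            trials.append(t)

            def theta_fn(y, tr=tr):
                return 0.1 * sum(1 for ty in tr if y >= ty + 10.0)

            frames.append(_traj_df(t, 60.0, theta_fn=theta_fn))
        traj = pd.concat(frames, ignore_index=True)
        angles = trajectory_angles_on_grid(traj)
        amap = {tuple(r[:3]): np.array(r[3:], dtype=float) for r in angles.to_numpy()}
        theta = np.array([amap[(t.mouse_id, t.session_id, t.trial_index)] for t in trials])
        res = tower_triggered_view_angle(trials, theta)
        win = (res.offsets_cm >= 10.0) & (res.offsets_cm <= 30.0)
        step_r = res.mean_right[win].mean()
        step_l = res.mean_left[win].mean()
        assert step_r > step_l + 0.02  # step present after right towers only

    def test_default_agent_spread_dominates(self):
        ds = simulate_dataset(
            AgentSpec(kind="k_random_tower", k=1, lapse_r=0.1, lapse_l=0.1),
            n_sessions=4, trials_per_session=100,
            rng=np.random.default_rng(51), trajectory_params=TrajectoryParams(),
            include_protocol=False,
        )
        angles = trajectory_angles_on_grid(ds.trajectories)
        amap = {tuple(r[:3]): np.array(r[3:], dtype=float) for r in angles.to_numpy()}
        sel = [t for t in ds.trials if (t.mouse_id, t.session_id, t.trial_index) in amap]
        theta = np.array([amap[(t.mouse_id, t.session_id, t.trial_index)] for t in sel])
        res = tower_triggered_view_angle(sel, theta)
        assert res.spread_ratio >= 5.0


class TestEvidenceConditionedTrajectories:
    def test_larger_delta_diverges_earlier(self):
        ds = simulate_dataset(
            AgentSpec(kind="k_random_tower", k=1, lapse_r=0.05, lapse_l=0.05),
            n_sessions=6, trials_per_session=150,
            rng=np.random.default_rng(61),
            trajectory_params=TrajectoryParams(noise_sd=0.1),
            include_protocol=False,
        )
        angles = trajectory_angles_on_grid(ds.trajectories)
        amap = {tuple(r[:3]): np.array(r[3:], dtype=float) for r in angles.to_numpy()}
        sel = [t for t in ds.trials if (t.mouse_id, t.session_id, t.trial_index) in amap]
        theta = np.array([amap[(t.mouse_id, t.session_id, t.trial_index)] for t in sel])
        curves = view_angle_by_evidence(sel, theta, delta_bins=((0, 2), (5, 20)))
        mid = np.argmin(np.abs(DEFAULT_Y_GRID - 150.0))
        assert curves[(5, 20)][mid] > curves[(0, 2)][mid]
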