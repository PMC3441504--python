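"""Time-stepping: Euler/OU updates, determinism, containment, schedules."""

import numpy as np
import pytest
from scipy import stats as sps

from ptwschool import (ModelParams, SimConfig, SpeedSchedule, TankGeometry,
                       simulate, speed_schedule_scenario, step, track_summary)


def open_tank():
    return TankGeometry(radius=2.0, bounded=False)


class TestStep:
    def test_omega_decay_closed_form(self):
        # sigma=0, no stimuli: omega follows the linear recursion exactly
        p = ModelParams(noise_scale=0.0)
        rng = np.random.default_rng(0)
        pos = np.zeros((1, 2))
        heading = np.zeros(1)
        omega = np.array([1.3])
        dt, v = 0.02, 0.5
        a = 1.0 - dt * v / p.persistence_length
        for n in range(1, 51):
            pos, heading, omega, _ = step(pos, heading, omega, np.array([v]),
                                          p, open_tank(), dt, rng)
            assert omega[0] == pytest.approx(1.3 * a**n, rel=1e-12)

    def test_displacement_norm_is_v_dt(self):
        p = ModelParams()
        rng = np.random.default_rng(1)
        pos = np.zeros((1, 2))
        out, _, _, _ = step(pos.copy(), np.array([0.3]), np.array([2.0]),
                            np.array([0.7]), p, open_tank(), 0.02, rng)
        assert np.hypot(*(out[0] - pos[0])) == pytest.approx(0.7 * 0.02)

    def test_forced_constant_omega_gives_circle(self):
        # l huge => tau huge => omega effectively frozen; chord polygon of a circle
        p = ModelParams(noise_scale=0.0, persistence_length=1e9)
        rng = np.random.default_rng(2)
        v, om, n_steps = 0.5, 2.0, 600
        dt = 2 * np.pi / (om * n_steps)  # the chord polygon closes exactly
        r = v / om
        pos = np.array([[r, 0.0]])
        heading = np.array([np.pi / 2])
        omega = np.array([om])
        pts = [pos[0].copy()]
        for _ in range(n_steps):
            pos, heading, omega, _ = step(pos, heading, omega, np.array([v]),
                                          p, open_tank(), dt, rng)
            pts.append(pos[0].copy())
        pts = np.array(pts[:-1])  # last vertex closes onto the first
        center = pts.mean(axis=0)
        radii = np.hypot(*(pts - center).T)
        # vertices lie on a common circle whose radius tends to v/omega as dt -> 0
        assert radii.max() - radii.min() < r * (om * dt) ** 2
        assert radii.mean() == pytest.approx(r, rel=om * dt)

    def test_nonfinite_state_aborts(self):
        p = ModelParams()
        rng = np.random.default_rng(3)
        with pytest.raises(FloatingPointError):
            step(np.array([[np.inf, 0.0]]), np.zeros(1), np.zeros(1),
                 np.array([0.5]), p, open_tank(), 0.02, rng)


class TestSimulate:
    def test_straight_line_without_forces(self):
        cfg = SimConfig(tank=open_tank(), n_fish=1,
                        params=ModelParams(noise_scale=0.0), speeds=0.5,
                        dt=1 / 48, duration=10.0, transient=0.0, seed=0,
                        initial=(np.zeros((1, 2)), np.zeros(1), np.zeros(1)))
        tr = simulate(cfg)
        assert tr["y"].abs().max() == 0.0
        assert tr["x"].iloc[-1] == pytest.approx(0.5 * 10.0, rel=1e-12)
        np.testing.assert_allclose(np.diff(tr["x"]), 0.5 / 12, atol=1e-12)

    def test_fixed_seed_bit_reproducible(self, tank, params):
        cfg = SimConfig(tank=tank, n_fish=2, params=params, speeds=0.5,
                        duration=20.0, transient=5.0, seed=42)
        a, b = simulate(cfg), simulate(cfg)
        assert a.equals(b)

    def test_rotational_invariance(self, tank, params):
        n = 3
        pos = np.array([[0.5, 0.2], [0.1, -0.6], [-0.4, 0.3]])
        th = np.array([0.3, -1.2, 2.0])
        beta = 0.77
        R = np.array([[np.cos(beta), -np.sin(beta)], [np.sin(beta), np.cos(beta)]])
        base = SimConfig(tank=tank, n_fish=n, params=params, speeds=0.5,
                         duration=20.0, transient=0.0, seed=9,
                         initial=(pos, th, np.zeros(n)), graph_method="all")
        rot = SimConfig(tank=tank, n_fish=n, params=params, speeds=0.5,
                        duration=20.0, transient=0.0, seed=9,
                        initial=(pos @ R.T, th + beta, np.zeros(n)),
                        graph_method="all")
        ta, tb = simulate(base), simulate(rot)
        xy_a = ta[["x", "y"]].to_numpy() @ R.T
        np.testing.assert_allclose(tb[["x", "y"]].to_numpy(), xy_a, atol=1e-9)
        dh = np.mod(tb["heading"].to_numpy() - ta["heading"].to_numpy() - beta
                    + np.pi, 2 * np.pi) - np.pi
        np.testing.assert_allclose(dh, 0.0, atol=1e-9)

    def test_frame_count_and_grid(self, pair_track):
        per_fish = pair_track.groupby("id").size()
        assert list(per_fish) == [1440, 1440]  # 120 s x 12 fps after transient
        ts = np.sort(pair_track["t"].unique())
        assert ts[0] == 0.0
        np.testing.assert_allclose(np.diff(ts), 1 / 12, atol=1e-12)

    def test_all_inside_bounded_tank(self, pair_track):
        r = np.hypot(pair_track["x"], pair_track["y"])
        assert (r < 2.0).all()

    def test_containment_at_002_step(self, tank, params):
        # 2 simulated minutes here; the 10-minute stress runs live in the
        # acceptance suite
        cfg = SimConfig(tank=tank, n_fish=1, params=params, speeds=0.5,
                        dt=0.02, duration=120.0, transient=0.0, seed=5,
                        fps_out=10.0)
        assert simulate(cfg).attrs["n_projections"] == 0

    def test_dt_must_divide_frame_interval(self, tank, params):
        with pytest.raises(ValueError, match="divide"):
            SimConfig(tank=tank, params=params, dt=0.02, fps_out=12.0)
        with pytest.raises(ValueError, match="frame interval"):
            SimConfig(tank=tank, params=params, dt=0.5, fps_out=12.0)

    def test_dt_refinement_stable_summary(self, tank, params):
        # halving dt changes the summary statistics by less than the
        # replicate spread
        def means(dt, seeds):
            out = []
            for s in seeds:
                cfg = SimConfig(tank=tank, n_fish=2, params=params, speeds=0.5,
                                dt=dt, duration=60.0, transient=10.0, seed=s)
                summ = track_summary(simulate(cfg))
                out.append((summ["P"].mean(), summ["D"].mean()))
            return np.array(out)
        coarse = means(1 / 48, range(6))
        fine = means(1 / 96, range(6, 12))
        for col in (0, 1):
            se = np.std(coarse[:, col]) / np.sqrt(6)
            assert abs(coarse[:, col].mean() - fine[:, col].mean()) < 3 * se + 0.05


class TestSpeedSchedules:
    def test_constant_schedule_equals_constant_speed(self, params):
        sched = SpeedSchedule(np.array([0.0, 10.0]), np.array([0.5, 0.5]))
        base = SimConfig(tank=open_tank(), n_fish=3, params=params, speeds=0.5,
                         duration=10.0, transient=0.0, seed=4, graph_method="all")
        a = simulate(base)
        b = speed_schedule_scenario(base, sched)
        assert a.equals(b)

    def test_ramp_evaluation(self):
        s = SpeedSchedule.ramp(0.2, 0.8, t_start=10.0, t_ramp=60.0)
        assert s(0.0) == pytest.approx(0.2)
        assert s(40.0) == pytest.approx(0.2 + 0.6 * 0.5)
        assert s(100.0) == pytest.approx(0.8)

    def test_slow_ramp_raises_polarization(self, params):
        # shoaling -> schooling transition under a slow common speed ramp
        sched = SpeedSchedule.ramp(0.15, 0.9, t_start=15.0, t_ramp=30.0)
        wins = 0
        n_runs = 20
        for s in range(n_runs):
            base = SimConfig(tank=open_tank(), n_fish=5, params=params,
                             speeds=0.15, duration=60.0, transient=0.0, seed=100 + s)
            tr = speed_schedule_scenario(base, sched)
            summ = track_summary(tr)
            early = summ.loc[summ["t"] < 10, "P"].mean()
            late = summ.loc[summ["t"] > 50, "P"].mean()
            wins += late > early
        assert sps.binomtest(wins, n_runs, alternative="greater").pvalue < 0.05

    def test_speed_step_flash_expansion(self, params):
        # an abrupt speed step transiently increases nearest-neighbor distance
        sched = SpeedSchedule.ramp(0.15, 0.9, t_start=30.0, t_ramp=0.2)
        wins = 0
        n_runs = 20
        for s in range(n_runs):
            base = SimConfig(tank=open_tank(), n_fish=5, params=params,
                             speeds=0.15, duration=45.0, transient=0.0, seed=200 + s)
            tr = speed_schedule_scenario(base, sched)
            summ = track_summary(tr)
            before = summ.loc[(summ["t"] > 25) & (summ["t"] < 30), "NND"].mean()
            after = summ.loc[(summ["t"] > 30) & (summ["t"] < 35), "NND"].max()
            wins += after > before
        assert wins > n_runs / 2
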