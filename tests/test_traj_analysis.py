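"""Trajectory pipeline: MSD estimation, fits, diagnostics, empirical splitting."""

import numpy as np
import pytest

from memfp.traj_analysis import (
    Trajectory,
    check_drift,
    check_gaussian_increments,
    empirical_splitting,
    estimate_msd,
    fit_msd_viscoelastic,
    gen_synthetic_bead_trajectory,
    post_fpt_mean,
)


class TestTrajectory:
    def test_uniform_dt_required(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(ValueError, match="non-uniform"):
            Trajectory(t, np.zeros(4))

    def test_csv_roundtrip(self, tmp_path):
        traj = gen_synthetic_bead_trajectory(duration=200.0, dt=0.1, seed=1)
        p = tmp_path / "traj.csv"
        traj.to_csv(p)
        back = Trajectory.from_csv(p)
        assert np.allclose(back.positions, traj.positions)
        assert back.dt == pytest.approx(traj.dt)


class TestEstimateMsd:
    def test_ballistic_is_exact(self):
        t = np.arange(2000) * 0.1
        traj = Trajectory(t, 0.7 * t)
        curve = estimate_msd(traj, 10.0)
        assert np.allclose(curve.values, (0.7 * curve.lags) ** 2, rtol=1e-12)

    def test_brownian_recovery(self):
        rng = np.random.default_rng(5)
        dt, D = 0.1, 0.8
        x = np.cumsum(np.sqrt(2 * D * dt) * rng.standard_normal(120000))
        traj = Trajectory(np.arange(x.size) * dt, x)
        curve = estimate_msd(traj, 100.0)
        for k in (0, 20, -1):
            se = np.sqrt(curve.variances[k])
            assert curve.values[k] == pytest.approx(2 * D * curve.lags[k], abs=3 * se)

    def test_localization_noise_plateau(self):
        rng = np.random.default_rng(6)
        sigma = 0.3
        x = sigma * rng.standard_normal(50000)  # pure static error
        traj = Trajectory(np.arange(x.size) * 0.05, x)
        curve = estimate_msd(traj, 20.0)
        assert np.allclose(curve.values, 2 * sigma ** 2, rtol=0.05)

    def test_truncation_warning(self):
        traj = Trajectory(np.arange(1000) * 0.1, np.arange(1000) * 0.0 + 1.0)
        with pytest.warns(UserWarning, match="truncated"):
            estimate_msd(traj, 50.0)


class TestViscoelasticFit:
    def test_parameter_recovery(self):
        traj = gen_synthetic_bead_trajectory(1.0, 3.0, 0.5, duration=15000.0,
                                             dt=0.15, seed=42)
        fit = fit_msd_viscoelastic(estimate_msd(traj, 700.0))
        assert fit.tau0 == pytest.approx(3.0, rel=0.15)
        assert fit.alpha == pytest.approx(0.5, rel=0.10)
        assert fit.amplitude == pytest.approx(1.0, rel=0.15)

    def test_brownian_input_gives_alpha_one(self):
        traj = gen_synthetic_bead_trajectory(1.0, 3.0, 1.0, duration=8000.0,
                                             dt=0.1, seed=43)
        fit = fit_msd_viscoelastic(estimate_msd(traj, 300.0))
        assert fit.alpha > 0.9

    def test_identifiability_flag_when_no_subdiffusive_decade(self):
        # lags all far above the crossover: tau0 poorly identified
        traj = gen_synthetic_bead_trajectory(1.0, 0.01, 0.5, duration=4000.0,
                                             dt=0.2, seed=44)
        fit = fit_msd_viscoelastic(estimate_msd(traj, 200.0))
        assert fit.flags  # widened-CI / unreliable warning recorded


class TestGaussianCheck:
    def test_gaussian_null_not_rejected(self):
        traj = gen_synthetic_bead_trajectory(1.0, 3.0, 0.5, duration=8000.0,
                                             dt=0.15, seed=45)
        rep = check_gaussian_increments(traj, [3.0, 1.5])
        assert rep["pass"]

    def test_laplace_alternative_rejected(self):
        rng = np.random.default_rng(46)
        x = np.cumsum(rng.laplace(size=40000))
        traj = Trajectory(np.arange(x.size) * 0.1, x)
        rep = check_gaussian_increments(traj, [0.1])
        assert not rep["pass"]

    def test_needs_enough_increments(self):
        traj = Trajectory(np.arange(100) * 0.1, np.zeros(100))
        with pytest.raises(ValueError):
            check_gaussian_increments(traj, [0.1])


class TestDriftCheck:
    def test_unbiased_input_covers_zero(self):
        traj = gen_synthetic_bead_trajectory(1.0, 3.0, 0.5, duration=8000.0,
                                             dt=0.15, seed=47)
        rep = check_drift(traj, memory_time=3.0)
        assert rep["unbiased"]

    def test_drift_detected(self):
        rng = np.random.default_rng(48)
        dt, v = 0.1, 0.05
        x = np.cumsum(v * dt + 0.1 * rng.standard_normal(50000))
        traj = Trajectory(np.arange(x.size) * dt, x)
        rep = check_drift(traj)
        assert not rep["unbiased"]
        assert rep["mean_increment"] == pytest.approx(v * dt, rel=0.3)

    def test_blocked_se_exceeds_naive_for_persistent_input(self):
        # positively correlated increments: honest SE must be larger
        rng = np.random.default_rng(49)
        n = 60000
        ou = np.empty(n)
        ou[0] = 0.0
        e = np.exp(-0.02)
        s = np.sqrt(1 - e * e)
        g = rng.standard_normal(n)
        for i in range(1, n):
            ou[i] = ou[i - 1] * e + s * g[i]
        x = np.cumsum(0.05 * ou)
        traj = Trajectory(np.arange(n) * 0.1, x)
        rep = check_drift(traj, memory_time=5.0)
        assert rep["se_block"] > 2.0 * rep["se_naive"]


class TestEmpiricalSplitting:
    def test_hand_built_upcrossing(self):
        # ten frames, one up-crossing of the far target (at relative 2.0)
        x = np.array([0.5, 0.62, 0.8, 1.0, 1.22, 1.4, 1.62, 1.85, 2.05, 2.0])
        traj = Trajectory(np.arange(10) * 1.0, x)
        table, events = empirical_splitting(traj, L=2.0, x0_bins=[0.5],
                                            spacing=5.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.eta == 1           # relative targets at 0.0 and 2.0
        assert ev.hit_index == 8
        assert ev.hit_frac == pytest.approx((2.0 - 1.85) / 0.2)
        assert table.n_events[0] == 1
        assert table.pi2_hat[0] == 1.0

    def test_resolution_guard(self):
        rng = np.random.default_rng(50)
        x = np.cumsum(rng.standard_normal(5000))
        traj = Trajectory(np.arange(x.size) * 1.0, x)
        with pytest.raises(ValueError, match="frame rate"):
            empirical_splitting(traj, L=2.0, x0_bins=[1.0], spacing=5.0)

    def test_brownian_markovian_line(self):
        traj = gen_synthetic_bead_trajectory(1.0, 3.0, 1.0, duration=20000.0,
                                             dt=0.02, seed=51)
        table, _ = empirical_splitting(traj, 2.0, [0.5, 1.0, 1.5], spacing=4.0)
        # agreement up to the frame-resolution shift of the absorbing points
        assert np.all(np.abs(table.pi2_hat - np.array([0.25, 0.5, 0.75]))
                      < np.maximum(2.0 * table.ci, 0.04))

    def test_post_fpt_brownian_flat(self):
        traj = gen_synthetic_bead_trajectory(1.0, 3.0, 1.0, duration=20000.0,
                                             dt=0.02, seed=52)
        L = 2.0
        _, events = empirical_splitting(traj, L, [1.0], spacing=4.0,
                                        follow_duration=3.0)
        rep = post_fpt_mean(events, 3.0, dt=0.02)
        step = np.sqrt(traj.meta["amplitude"] * 0.02 / 3.0)
        for key, target in (("mu1", 0.0), ("mu2", L)):
            mu, ci, n = rep[key]["mean"], rep[key]["ci"], rep[key]["n"]
            assert n >= 50
            # flat at the target up to the frame-overshoot scale
            assert np.all(np.abs(mu - target) < ci + 3 * step)


class TestGenerator:
    def test_msd_matches_model_and_is_seeded(self):
        traj = gen_synthetic_bead_trajectory(2.0, 1.5, 0.6, duration=3000.0,
                                             dt=0.05, seed=53)
        again = gen_synthetic_bead_trajectory(2.0, 1.5, 0.6, duration=3000.0,
                                              dt=0.05, seed=53)
        assert np.array_equal(traj.positions, again.positions)
        from memfp.msd_models import make_viscoelastic

        m = make_viscoelastic(2.0, 1.5, 0.6)
        curve = estimate_msd(traj, 30.0)
        z = (curve.values - m(curve.lags)) / np.sqrt(curve.variances)
        assert np.all(np.abs(z) < 4.0)

    def test_duration_guard(self):
        with pytest.raises(ValueError):
            gen_synthetic_bead_trajectory(1.0, 10.0, 0.5, duration=50.0, dt=0.1)
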