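"""Sampler exactness and Monte Carlo first-passage machinery."""

import numpy as np
import pytest

from memfp.msd_models import (
    make_bidiffusive,
    make_brownian,
    make_powerlaw,
    make_rouse_monomer_msd,
    make_viscoelastic,
)
from memfp.simulate import (
    FirstPassageEvent,
    PathEnsemble,
    ensemble_msd,
    estimate_splitting_mc,
    first_passage_two_targets,
    sample_bidiffusive_exact,
    sample_fgn,
    sample_gaussian_increment_process,
    sample_rouse,
    splitting_mc,
)


def lag1_autocorr(positions):
    inc = np.diff(positions, axis=1)
    a = inc[:, :-1].ravel()
    b = inc[:, 1:].ravel()
    return np.corrcoef(a, b)[0, 1], 1.0 / np.sqrt(a.size)


class TestSamplerExactness:
    """Master calibration: ensemble MSD must match psi(t) at three decades of lag."""

    def test_fgn_lag1_autocorrelation(self):
        # H = 1/2: independent increments; H = 3/4: (2^{2H} - 2)/2
        ens = sample_fgn(0.5, 1.0, 2000, 1.0, 60, seed=1)
        r, se = lag1_autocorr(ens.positions)
        assert abs(r) < 3 * se
        ens = sample_fgn(0.75, 1.0, 2000, 1.0, 60, seed=2)
        r, se = lag1_autocorr(ens.positions)
        assert r == pytest.approx((2.0 ** 1.5 - 2.0) / 2.0, abs=3 * se)

    @pytest.mark.parametrize("name", ["fbm_sub", "fbm_super", "bidiffusive", "viscoelastic"])
    def test_ensemble_msd_matches_psi(self, model_zoo, name):
        m = model_zoo[name]
        ens = sample_gaussian_increment_process(m, 1000, 0.05, 3000, seed=hash(name) % 2 ** 16)
        t, msd, se = ensemble_msd(ens, [1, 10, 100, 1000])
        assert np.all(np.abs(msd - m(t)) < 3 * se)

    def test_bidiffusive_exact_updates(self):
        B = 10.0
        m = make_bidiffusive(B)
        ens = sample_bidiffusive_exact(B, 600, 0.05, 4000, seed=3)
        t, msd, se = ensemble_msd(ens, [1, 20, 400])
        assert np.all(np.abs(msd - m(t)) < 3 * se)

    def test_bidiffusive_stationarity_shifted_origin(self):
        # MSD measured from a mid-path origin must match (equilibrium OU start)
        ens = sample_bidiffusive_exact(10.0, 800, 0.05, 4000, seed=4)
        pos = ens.positions
        k0 = 400
        lags = np.array([1, 20, 200])
        sq = (pos[:, k0 + lags] - pos[:, [k0]]) ** 2
        msd = sq.mean(axis=0)
        se = sq.std(axis=0, ddof=1) / np.sqrt(pos.shape[0])
        m = make_bidiffusive(10.0)
        assert np.all(np.abs(msd - m(lags * ens.dt)) < 3 * se)

    def test_viscoelastic_alpha1_has_independent_increments(self):
        m = make_viscoelastic(1.0, 1.0, 1.0)
        ens = sample_gaussian_increment_process(m, 1500, 0.1, 80, seed=5)
        r, se = lag1_autocorr(ens.positions)
        assert abs(r) < 3 * se

    def test_rouse_msd_matches_mode_sum(self):
        m = make_rouse_monomer_msd(20)
        ens = sample_rouse(20, 1, 800, 0.05, 3000, seed=6)
        t, msd, se = ensemble_msd(ens, [1, 10, 100, 800])
        assert np.all(np.abs(msd - m(t)) < 3 * se)

    def test_rouse_n1_is_free_diffusion(self):
        ens = sample_rouse(1, 2, 300, 0.1, 2000, seed=7)
        t, msd, se = ensemble_msd(ens, [1, 10, 100])
        assert np.all(np.abs(msd - 2.0 * t) < 3 * se)

    def test_seed_determinism(self):
        a = sample_fgn(0.6, 1.0, 256, 0.1, 10, seed=11).positions
        b = sample_fgn(0.6, 1.0, 256, 0.1, 10, seed=11).positions
        assert np.array_equal(a, b)
        c = sample_rouse(5, 2, 64, 0.1, 4, seed=12).positions
        d = sample_rouse(5, 2, 64, 0.1, 4, seed=12).positions
        assert np.array_equal(c, d)


class TestFirstPassage:
    def test_deterministic_upcrossing(self):
        # hand-checkable fixture: crossing of L between samples 2 and 3
        x0, L = 0.3, 1.0
        path = np.array([x0, 0.4 * L, 0.9 * L, 1.02 * L, 1.1 * L]) - x0
        ens = PathEnsemble(dt=1.0, positions=path[None, :], seed=None, model="fixture")
        events, n_cens = first_passage_two_targets(ens, x0, L, follow_duration=1.0)
        assert n_cens == 0
        (ev,) = events
        assert ev.target_index == 2
        # crossing fraction (1.0 - 0.9) / (1.02 - 0.9) between indices 2 and 3
        assert ev.hit_time == pytest.approx(2.0 + 0.1 / 0.12)
        assert ev.post_path[0] == pytest.approx(1.02 * L)

    def test_deterministic_downcrossing_wins(self):
        x0, L = 0.3, 1.0
        path = np.array([x0, 0.1, -0.05, 1.2]) - x0
        ens = PathEnsemble(dt=0.5, positions=path[None, :], seed=None, model="fixture")
        events, _ = first_passage_two_targets(ens, x0, L)
        assert events[0].target_index == 1
        assert events[0].hit_time == pytest.approx(0.5 * (1 + 0.1 / 0.15))

    def test_censoring_thresholds(self):
        x0, L = 0.5, 1.0
        flat = np.zeros((10, 5))  # stays at x0: all censored
        ens = PathEnsemble(dt=1.0, positions=flat, seed=None, model="fixture")
        with pytest.raises(RuntimeError, match="censored"):
            first_passage_two_targets(ens, x0, L)

    def test_brownian_splitting_matches_x0_over_L(self):
        st = splitting_mc(make_brownian(0.5), 0.3, 1.0, 4000, 4000, 1e-3, seed=21)
        assert st.censored_fraction < 0.01
        assert st.pi2_hat == pytest.approx(0.3, abs=3 * st.se)
        assert st.se == pytest.approx(
            np.sqrt(st.pi2_hat * (1 - st.pi2_hat) / st.n_events), rel=1e-12
        )

    def test_estimate_splitting_from_events(self):
        ens = sample_gaussian_increment_process(make_brownian(0.5), 3000, 1e-3, 800, seed=22)
        events, n_cens = first_passage_two_targets(ens, 0.3, 1.0, follow_duration=0.05,
                                                   censored_warn=1.0)
        st = estimate_splitting_mc(events, n_cens)
        assert 0 <= st.pi2_hat <= 1
        # Brownian post-hit means sit at the targets (within 3 SE plus overshoot ~ sqrt(psi(dt)))
        tol = 3 * np.nanmax(st.mu1_se) + 2 * np.sqrt(1e-3)
        assert np.all(np.abs(st.mu1_hat) < tol)
        assert np.all(np.abs(st.mu2_hat - 1.0) < tol)

    def test_bidiffusive_recoil_reenters_interval(self):
        # B = 10, L = 20: after hitting 0 the mean trajectory comes back inside
        st = splitting_mc(make_bidiffusive(10.0), 4.16, 20.0, 3000, 30000, 0.04,
                          seed=23, follow_steps=40, follow_stride=25)
        inner = st.mu1_hat[5:] > 0
        assert inner.any()

    def test_discretization_robustness_dt_halving(self):
        # fBM H = 0.4: halving dt moves pi2 by < 2 combined SE (bias under control)
        m = make_powerlaw(1.0, 0.4)
        st1 = splitting_mc(m, 0.208, 1.0, 6000, 30000, 1e-4, seed=24)
        st2 = splitting_mc(m, 0.208, 1.0, 6000, 60000, 5e-5, seed=25)
        assert abs(st1.pi2_hat - st2.pi2_hat) < 2 * np.hypot(st1.se, st2.se)

    def test_cross_sampler_agreement_bidiffusive(self):
        # circulant embedding vs exact Markovian embedding: same splitting (3 sigma)
        kw = dict(x0=4.16, L=20.0, n_paths=3000, n_steps=20000, dt=0.06)
        m = make_bidiffusive(10.0)
        st_c = splitting_mc(m, seed=26, **kw)

        def sampler(n_steps, dt, n_paths, rng):
            return sample_bidiffusive_exact(10.0, n_steps, dt, n_paths,
                                            seed=int(rng.integers(2 ** 31)))

        st_m = splitting_mc(m, seed=27, sampler=sampler, **kw)
        assert abs(st_c.pi2_hat - st_m.pi2_hat) < 3 * np.hypot(st_c.se, st_m.se)
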