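"""Unit tests for the MSD model families and their derived quantities."""

import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

from memfp.msd_models import (
    InvalidParameterError,
    characteristic_time,
    correlation_M,
    increment_autocov,
    make_bidiffusive,
    make_brownian,
    make_powerlaw,
    make_rouse_monomer_msd,
    make_tabulated,
    make_viscoelastic,
    viscoelastic_f,
)


class TestFactories:
    def test_powerlaw_evaluates_kappa_t_2h(self):
        m = make_powerlaw(1.0, 0.4)
        assert m(4.0) == pytest.approx(4.0 ** 0.8, rel=1e-12)
        assert m.H_infinity == 0.4

    def test_powerlaw_brownian_is_linear(self):
        m = make_powerlaw(2.0 * 0.7, 0.5)  # 2D with D=0.7
        t = np.linspace(0.1, 9.0, 7)
        assert np.allclose(m(t), 1.4 * t)

    def test_bidiffusive_limits(self):
        m = make_bidiffusive(10.0)
        t = 1e-8
        assert m(t) == pytest.approx(11.0 * t, rel=1e-6)       # short-time (1+B)t
        assert m(20.0) == pytest.approx(30.0, rel=1e-6)        # 20 + 10(1 - e^-20)
        assert make_bidiffusive(0.0)(3.0) == pytest.approx(3.0)

    def test_viscoelastic_alpha_one_is_brownian(self):
        v = make_viscoelastic(2.0, 5.0, 1.0)
        ref = make_powerlaw(2.0 / 5.0, 0.5)
        t = np.geomspace(1e-4, 1e6, 40)
        assert np.allclose(v(t), ref(t), rtol=1e-10)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.9])
    def test_viscoelastic_short_time_exponent(self, alpha):
        # f(y) ~ y^alpha / Gamma(1 + alpha) for small y
        y = np.array([1e-6, 1e-5])
        f = viscoelastic_f(y, alpha)
        assert f == pytest.approx(y ** alpha / gamma_fn(1 + alpha), rel=1e-3)
        # numerical log-slope equals alpha
        slope = np.diff(np.log(f)) / np.diff(np.log(y))
        assert slope[0] == pytest.approx(alpha, rel=1e-4)

    def test_viscoelastic_f_vanishes_at_zero(self):
        assert viscoelastic_f(0.0, 0.5) == 0.0

    def test_rouse_free_monomer(self):
        m = make_rouse_monomer_msd(1)
        t = np.linspace(0.01, 5, 11)
        assert np.allclose(m(t), 2.0 * t)

    def test_rouse_intermediate_subdiffusion_and_com_limit(self):
        m = make_rouse_monomer_msd(80)
        t = np.geomspace(20.0, 300.0, 9)
        slopes = np.diff(np.log(m(t))) / np.diff(np.log(t))
        assert np.all(np.abs(slopes - 0.5) < 0.1)
        assert m(1e7) / (2e7 / 80) == pytest.approx(1.0, rel=1e-3)

    @pytest.mark.parametrize(
        "factory,args",
        [
            (make_powerlaw, (1.0, 0.0)),
            (make_powerlaw, (1.0, 1.0)),
            (make_powerlaw, (-1.0, 0.5)),
            (make_bidiffusive, (-0.1,)),
            (make_viscoelastic, (1.0, 1.0, 0.0)),
            (make_viscoelastic, (1.0, 1.0, 1.5)),
            (make_viscoelastic, (-1.0, 1.0, 0.5)),
            (make_rouse_monomer_msd, (0,)),
        ],
    )
    def test_invalid_parameters_raise(self, factory, args):
        with pytest.raises(InvalidParameterError):
            factory(*args)


class TestInvariants:
    def test_psi_zero_and_monotone(self, model_zoo):
        for name, m in model_zoo.items():
            tc = characteristic_time(m, 1.0)
            t = np.geomspace(1e-6 * tc, 1e6 * tc, 200)
            psi = m(t)
            assert m(0.0) == pytest.approx(0.0, abs=1e-14), name
            assert np.all(np.diff(psi) > 0), name

    def test_long_time_tail(self, model_zoo):
        for name, m in model_zoo.items():
            tc = characteristic_time(m, 1.0)
            t = 1e5 * tc
            ratio = m(t) / (m.kappa * t ** (2 * m.H_infinity))
            assert ratio == pytest.approx(1.0, rel=0.05), name


class TestCorrelationM:
    def test_brownian_is_unity(self):
        m = make_brownian(1.3)
        t = np.geomspace(1e-3, 1e3, 13)
        for tau in (1e-4, 0.7, 50.0):
            assert np.allclose(correlation_M(m, t, tau), 1.0, atol=1e-13)

    def test_fbm_equal_arguments(self):
        m = make_powerlaw(1.0, 0.4)
        assert correlation_M(m, 2.0, 2.0) == pytest.approx(2.0 ** (2 * 0.4 - 1), rel=1e-12)

    def test_small_tau_limit(self, model_zoo):
        for m in model_zoo.values():
            # subdiffusive psi(tau) ~ tau^alpha makes the approach slow but sure
            assert correlation_M(m, 1.0, 1e-12) == pytest.approx(1.0, abs=1e-4)

    def test_t_zero_raises(self):
        with pytest.raises(ValueError):
            correlation_M(make_brownian(), 0.0, 1.0)


class TestIncrementAutocov:
    def test_brownian_increments_independent(self):
        m = make_brownian(0.5)
        k = np.arange(6)
        c = increment_autocov(m, 0.3, k)
        assert c[0] == pytest.approx(0.3)
        assert np.allclose(c[1:], 0.0, atol=1e-14)

    def test_fgn_closed_form(self):
        H, kappa, dt = 0.7, 2.0, 0.5
        m = make_powerlaw(kappa, H)
        k = np.arange(1, 8)
        expected = 0.5 * kappa * dt ** (2 * H) * (
            (k + 1.0) ** (2 * H) - 2 * k ** (2.0 * H) + (k - 1.0) ** (2 * H)
        )
        assert np.allclose(increment_autocov(m, dt, k), expected, rtol=1e-12)

    def test_variance_telescopes_to_psi(self, model_zoo):
        # sum over the covariance matrix of n increments reconstructs psi(n dt)
        n, dt = 37, 0.31
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        for name, m in model_zoo.items():
            c = increment_autocov(m, dt, np.arange(n))
            assert c[idx].sum() == pytest.approx(m(n * dt), rel=1e-8), name


class TestCharacteristicTime:
    def test_closed_forms(self):
        assert characteristic_time(make_brownian(1.0), 3.0) == pytest.approx(4.5, rel=1e-10)
        m = make_powerlaw(2.0, 0.4)
        assert characteristic_time(m, 5.0) == pytest.approx((25.0 / 2.0) ** (1 / 0.8), rel=1e-10)

    def test_bidiffusive_root(self):
        t = characteristic_time(make_bidiffusive(10.0), 20.0)
        assert t == pytest.approx(390.0, rel=1e-6)
        assert make_bidiffusive(10.0)(t) == pytest.approx(400.0, rel=1e-10)


class TestTabulated:
    def test_roundtrip_and_tails(self):
        m = make_powerlaw(1.5, 0.4)
        t = np.geomspace(1e-2, 1e2, 60)
        tab = make_tabulated(t, m(t))
        s = np.geomspace(1e-1, 1e1, 17)
        assert np.allclose(tab(s), m(s), rtol=1e-4)
        assert tab.H_infinity == pytest.approx(0.4, rel=1e-3)
        # extrapolation follows the declared tail
        assert tab(1e5) == pytest.approx(m(1e5), rel=0.05)
        assert tab(1e-5) == pytest.approx(m(1e-5), rel=0.05)
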