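"""Mean-square-displacement models for centered Gaussian processes with stationary increments.

A 1D unbiased Gaussian process with stationary increments is fully characterized by its
mean-square displacement (MSD) :math:`\\psi(t) = \\langle [x(t)-x(0)]^2 \\rangle`.  Every
process handled by this package — fractional Brownian motion, the bidiffusive
(Brownian + Ornstein-Uhlenbeck) process, viscoelastic bead motion, and the Rouse
monomer — is represented here solely through its :class:`MsdModel`.

All models are required to behave as :math:`\\psi(t) \\simeq \\kappa t^{2H}` at long
times with :math:`0 < H < 1`: subdiffusive for ``H < 1/2``, superdiffusive for
``H > 1/2``, diffusive for ``H = 1/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import optimize, special
from scipy.interpolate import PchipInterpolator

__all__ = [
    "MsdModel",
    "InvalidParameterError",
    "make_powerlaw",
    "make_brownian",
    "make_bidiffusive",
    "make_viscoelastic",
    "make_rouse_monomer_msd",
    "make_tabulated",
    "make_custom",
    "viscoelastic_f",
    "rouse_mode_spectrum",
    "correlation_M",
    "increment_autocov",
    "characteristic_time",
]


class InvalidParameterError(ValueError):
    """A model parameter is outside its admissible range."""


@dataclass(frozen=True)
class MsdModel:
    """An MSD function psi(t) together with its long-time power-law tail.

    Parameters
    ----------
    name : str
        Human-readable label (``"powerlaw"``, ``"bidiffusive"``, ...).
    params : mapping
        The named parameters the model was built from.
    psi : callable
        Vectorized map ``t -> psi(t)`` valid for ``t >= 0``; ``psi(0) = 0`` and
        psi is strictly increasing.
    H_infinity : float
        Long-time exponent: ``psi(t) ~ kappa * t**(2*H_infinity)`` as t -> inf.
    kappa : float
        Amplitude of the long-time power law (units length^2 / time^(2H)).
    """

    name: str
    params: Mapping[str, float]
    psi: Callable[[np.ndarray], np.ndarray]
    H_infinity: float
    kappa: float

    def __post_init__(self) -> None:
        if not (0.0 < self.H_infinity < 1.0):
            raise InvalidParameterError(
                f"H_infinity must lie in (0, 1), got {self.H_infinity}"
            )
        if self.kappa <= 0:
            raise InvalidParameterError(f"kappa must be positive, got {self.kappa}")

    def __call__(self, t):
        return self.psi(np.asarray(t, dtype=float))

    def __repr__(self) -> str:  # params inline, scipy-style
        ps = ", ".join(f"{k}={v:.6g}" for k, v in self.params.items())
        return f"MsdModel({self.name}: {ps}; H={self.H_infinity:.4g}, kappa={self.kappa:.4g})"


def make_powerlaw(kappa: float, H: float) -> MsdModel:
    """Scale-invariant (fBM-type) MSD ``psi(t) = kappa * t**(2H)``.

    ``H = 1/2`` with ``kappa = 2D`` is ordinary Brownian motion.
    """
    if not (0.0 < H < 1.0):
        raise InvalidParameterError(f"H must lie in (0, 1), got {H}")
    if kappa <= 0:
        raise InvalidParameterError(f"kappa must be positive, got {kappa}")

    def psi(t, _k=float(kappa), _e=2.0 * H):
        t = np.asarray(t, dtype=float)
        return _k * np.power(t, _e)

    return MsdModel("powerlaw", {"kappa": kappa, "H": H}, psi, H, kappa)


def make_brownian(D: float = 0.5) -> MsdModel:
    """Brownian motion with ``psi(t) = 2 D t`` (default D=1/2, i.e. psi(t)=t)."""
    return make_powerlaw(2.0 * D, 0.5)


def make_bidiffusive(B: float) -> MsdModel:
    """Bidiffusive MSD ``psi(t) = t + B (1 - exp(-t))`` (dimensionless units).

    Sum of a white noise and a single-relaxation-time colored noise (Maxwell
    fluid); short times ``psi ~ (1+B) t``, long times ``psi ~ t``.
    """
    if B < 0:
        raise InvalidParameterError(f"B must be nonnegative, got {B}")

    def psi(t, _B=float(B)):
        t = np.asarray(t, dtype=float)
        return t + _B * (-np.expm1(-t))

    return MsdModel("bidiffusive", {"B": B}, psi, 0.5, 1.0)


def viscoelastic_f(y, alpha: float):
    """Crossover function ``f(y) = [(y - alpha + 1) gamma(alpha, y) + y^alpha e^-y] / Gamma(alpha)``.

    ``gamma`` is the lower incomplete gamma function; ``f(y) ~ y^alpha / Gamma(1+alpha)``
    for small y (subdiffusive) and ``f(y) ~ y - alpha + 1`` for large y (diffusive).
    Evaluated through the regularized incomplete gamma P(alpha, y), which is
    accurate in both limits.
    """
    y = np.asarray(y, dtype=float)
    # gamma(alpha, y)/Gamma(alpha) = P(alpha, y)
    P = special.gammainc(alpha, y)
    with np.errstate(divide="ignore"):
        # y^alpha e^-y / Gamma(alpha), stable in logs for extreme y
        log_term = alpha * np.log(np.where(y > 0, y, 1.0)) - y - special.gammaln(alpha)
    term = np.where(y > 0, np.exp(log_term), 0.0)
    return (y - alpha + 1.0) * P + term


def make_viscoelastic(amplitude: float, tau0: float, alpha: float) -> MsdModel:
    """Viscoelastic-fluid MSD ``psi(t) = amplitude * f(t / tau0)``.

    Induced by an overdamped generalized Langevin equation whose friction kernel
    decays as a power law cut off at the solution's memory time ``tau0``; the
    thermal prefactor (2 k_B T tau0 / gamma_0) is kept as the single fitted
    ``amplitude``.  Short times: ``psi ~ t^alpha`` (subdiffusive); long times:
    diffusive with ``kappa = amplitude / tau0``.
    """
    if amplitude <= 0:
        raise InvalidParameterError(f"amplitude must be positive, got {amplitude}")
    if tau0 <= 0:
        raise InvalidParameterError(f"tau0 must be positive, got {tau0}")
    if not (0.0 < alpha <= 1.0):
        raise InvalidParameterError(f"alpha must lie in (0, 1], got {alpha}")

    def psi(t, _a=float(amplitude), _t0=float(tau0), _al=float(alpha)):
        t = np.asarray(t, dtype=float)
        return _a * viscoelastic_f(t / _t0, _al)

    return MsdModel(
        "viscoelastic",
        {"amplitude": amplitude, "tau0": tau0, "alpha": alpha},
        psi,
        0.5,
        amplitude / tau0,
    )


def rouse_mode_spectrum(N: int):
    """Relaxation rates and first-monomer weights of the free-end Rouse chain.

    Modes ``p = 0 .. N-1`` of the nearest-neighbour Laplacian with free-end
    prescription ``x_0 = x_1``, ``x_{N+1} = x_N``:
    eigenvalue ``lambda_p = 4 sin^2(p pi / 2N)`` and orthonormal eigenvector
    ``phi_p(i) = sqrt(2/N) cos(p pi (i - 1/2)/N)`` (``phi_0 = 1/sqrt(N)``).

    Returns
    -------
    lam : ndarray, shape (N,)
    phi1 : ndarray, shape (N,)
        Eigenvector components at the first monomer.
    """
    if N < 1 or int(N) != N:
        raise InvalidParameterError(f"N must be a positive integer, got {N}")
    p = np.arange(N)
    lam = 4.0 * np.sin(np.pi * p / (2.0 * N)) ** 2
    phi1 = np.sqrt(2.0 / N) * np.cos(np.pi * p * 0.5 / N)
    phi1[0] = 1.0 / np.sqrt(N)
    return lam, phi1


def make_rouse_monomer_msd(N: int) -> MsdModel:
    """Per-coordinate MSD of the first monomer of a free-end Rouse chain.

    The chain obeys ``dx_i/dt = x_{i+1} - 2 x_i + x_{i-1} + f_i`` with
    ``<f f> = 2 delta(t - t')`` per coordinate.  Normal-mode decomposition gives

        psi(t) = 2 t / N + sum_{p>=1} phi_p(1)^2 (2/lambda_p) (1 - exp(-lambda_p t))

    with equilibrium-initialized internal modes (stationary increments for the
    monomer).  Long times: center-of-mass diffusion ``2t/N``; intermediate times
    (1 << t << N^2): Rouse subdiffusion with log-slope ~ 1/2.
    """
    lam, phi1 = rouse_mode_spectrum(int(N))
    w = phi1[1:] ** 2 * 2.0 / np.where(lam[1:] > 0, lam[1:], 1.0)
    lam_int = lam[1:]

    def psi(t, _N=int(N), _w=w, _lam=lam_int):
        t = np.asarray(t, dtype=float)
        out = 2.0 * t / _N
        if _w.size:
            out = out + np.sum(
                _w * (-np.expm1(-np.multiply.outer(t, _lam))), axis=-1
            )
        return out

    return MsdModel("rouse", {"N": int(N)}, psi, 0.5, 2.0 / int(N))


def make_tabulated(t, psi_values, kappa: float | None = None,
                   H: float | None = None, name: str = "table") -> MsdModel:
    """MSD from a user table, interpolated monotonically in log-log space.

    Beyond the table the declared ``(kappa, H)`` tail is used (fitted from the
    last decade of the table when not given); below the table the local
    power law of the first two points extends to t -> 0.  The solver integrates
    over ~10 decades of time, hence the log-log treatment.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(psi_values, dtype=float)
    if t.ndim != 1 or t.size < 4 or np.any(np.diff(t) <= 0) or np.any(t <= 0):
        raise InvalidParameterError("table times must be >0, increasing, length >= 4")
    if np.any(v <= 0) or np.any(np.diff(v) <= 0):
        raise InvalidParameterError("table psi values must be positive and increasing")
    lt, lv = np.log(t), np.log(v)
    interp = PchipInterpolator(lt, lv, extrapolate=False)
    if H is None or kappa is None:
        # tail fit over the last decade of the table
        mask = t >= t[-1] / 10.0
        slope, intercept = np.polyfit(lt[mask], lv[mask], 1)
        H = H if H is not None else slope / 2.0
        kappa = kappa if kappa is not None else float(np.exp(intercept))
    slope_lo = (lv[1] - lv[0]) / (lt[1] - lt[0])
    t_lo, t_hi = t[0], t[-1]
    v_lo, v_hi = v[0], v[-1]

    def psi(s, _H=float(H)):
        s = np.asarray(s, dtype=float)
        out = np.zeros_like(s)
        pos = s > 0
        sp = s[pos]
        res = np.empty_like(sp)
        lo = sp < t_lo
        hi = sp > t_hi
        mid = ~(lo | hi)
        res[mid] = np.exp(interp(np.log(sp[mid])))
        res[lo] = v_lo * (sp[lo] / t_lo) ** slope_lo
        res[hi] = v_hi * (sp[hi] / t_hi) ** (2.0 * _H)
        out[pos] = res
        return out

    return MsdModel(name, {"n_points": t.size, "kappa": float(kappa), "H": float(H)},
                    psi, float(H), float(kappa))


def make_custom(psi: Callable, H_infinity: float, kappa: float,
                name: str = "custom", params: Mapping[str, float] | None = None) -> MsdModel:
    """Wrap an arbitrary vectorized psi(t) callable as an :class:`MsdModel`."""
    return MsdModel(name, dict(params or {}), psi, float(H_infinity), float(kappa))


def correlation_M(model: MsdModel, t, tau):
    """Conditional-mean weight ``M(t, tau) = [psi(t+tau) + psi(t) - psi(tau)] / (2 psi(t))``.

    For a Gaussian process with stationary increments, the mean of ``x(t+tau)``
    conditioned on ``x(t)`` involves exactly this combination; ``M = 1``
    identically for independent increments (Brownian motion).
    """
    t = np.asarray(t, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(t <= 0):
        raise ValueError("correlation_M requires t > 0 (use limits for t = 0)")
    return (model(t + tau) + model(t) - model(tau)) / (2.0 * model(t))


def increment_autocov(model: MsdModel, dt: float, k):
    """Autocovariance of successive displacements at integer lag(s) k.

    For stationary increments,
    ``c(k) = [psi((k+1) dt) - 2 psi(k dt) + psi(|k-1| dt)] / 2``; in particular
    ``c(0) = psi(dt)``.  This is the sequence the circulant-embedding sampler
    consumes.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = np.asarray(k)
    kk = k.astype(float)
    return 0.5 * (
        model((kk + 1.0) * dt) - 2.0 * model(kk * dt) + model(np.abs(kk - 1.0) * dt)
    )


def characteristic_time(model: MsdModel, L: float) -> float:
    """Time t_c at which the process spans L, i.e. the root of ``psi(t_c) = L^2``."""
    if L <= 0:
        raise ValueError("L must be positive")
    target = L * L
    # initial guess from the long-time law, then bracket geometrically
    t0 = (target / model.kappa) ** (1.0 / (2.0 * model.H_infinity))
    lo, hi = t0, t0
    for _ in range(200):
        if model(lo) <= target:
            break
        lo /= 4.0
    for _ in range(200):
        if model(hi) >= target:
            break
        hi *= 4.0
    if not (model(lo) <= target <= model(hi)):
        raise RuntimeError("could not bracket characteristic time")
    # widen slightly: the log/exp roundtrip below can flip a razor-thin bracket
    lo /= 2.0
    hi *= 2.0
    root = optimize.brentq(lambda u: model(np.exp(u)) - target,
                           np.log(lo), np.log(hi), xtol=1e-14)
    return float(np.exp(root))
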