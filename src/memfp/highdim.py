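"""Large-volume splitting probabilities in d dimensions.

In a large confining volume the splitting probability between two absorbing
balls of radius ``a`` reduces to time integrals of propagator differences:

.. math::

   \\pi_1 = \\frac{h_{22} - h_{12}}{h_{22} + h_{11} - h_{21} - h_{12}},
   \\qquad
   h_{ij} = \\int_0^\\infty dt\\, [q_j(r_i, t) - p(r_i, t)]

with ``p`` the free (unconfined) Gaussian density of the process and ``q_j``
the density at a time t after the first passage to target j.  Memory enters
through ``q_j``: after hitting a target the walker is *not* in a stationary
state, and its mean position recoils along the hitting direction.

Two propagator closures are offered, recorded on every output:

* ``markovian_baseline`` — ``q_j`` is the free Gaussian recentered on the hit
  target (zero post-hit mean displacement, isotropic hit angles);
* ``semi_empirical`` — post-hit radial mean-displacement curves ``m_j(t)`` and
  a hitting-angle distribution ``Pi(theta) ~ exp(kappa_angle cos(theta -
  theta0))`` calibrated from single-target simulations, under the decoupling
  approximation (post-hit statistics taken from the single-target problem).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from memfp.msd_models import MsdModel, characteristic_time

__all__ = [
    "HighDimProblem",
    "PropagatorModel",
    "free_propagator",
    "h_matrix",
    "splitting_from_h",
    "solve_splitting_highdim",
    "fit_angle_distribution",
    "calibrate_semi_empirical",
    "propagator_from_solution_1d",
]


@dataclass(frozen=True)
class HighDimProblem:
    """Two absorbing balls of radius a at r1, r2; start r0; per-coordinate MSD model.

    ``R`` (confinement radius, around r1) only matters for the Monte Carlo
    oracle; the large-volume formula is R-independent by construction.
    """

    d: int
    r0: tuple
    r1: tuple
    r2: tuple
    a: float
    model: MsdModel
    R: float = math.inf

    def __post_init__(self):
        for name in ("r0", "r1", "r2"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if v.size != self.d:
                raise ValueError(f"{name} must have dimension d={self.d}")
            object.__setattr__(self, name, tuple(v))
        if self.L <= 2.0 * self.a:
            raise ValueError("targets must be disjoint: |r1 - r2| > 2a")
        for c in (self.r1, self.r2):
            if np.linalg.norm(np.subtract(self.r0, c)) <= self.a:
                raise ValueError("r0 must lie outside both targets")

    @property
    def L(self) -> float:
        return float(np.linalg.norm(np.subtract(self.r1, self.r2)))


@dataclass
class PropagatorModel:
    """Post-first-passage propagator closure used inside the h integrals.

    For ``semi_empirical``: ``m_t`` and ``m1, m2`` give the mean displacement
    from the target *surface* along the exit direction, so the post-hit mean
    sits at ``c_j + (a + m_j(t)) u(theta)``; ``kappa_angle`` (>= 0) is the
    concentration of the exponential-cosine angle distribution and ``theta0``
    its location, measured from the axis joining the hit target to r0.
    """

    mode: str = "markovian_baseline"
    m_t: np.ndarray | None = None
    m1: np.ndarray | None = None
    m2: np.ndarray | None = None
    kappa_angle: float = 0.0
    theta0: float = 0.0

    def __post_init__(self):
        if self.mode not in ("markovian_baseline", "semi_empirical"):
            raise ValueError(f"unknown propagator mode {self.mode!r}")
        if self.kappa_angle < 0:
            raise ValueError("kappa_angle must be nonnegative")
        if self.mode == "semi_empirical":
            for c in (self.m1, self.m2):
                if c is None or self.m_t is None:
                    raise ValueError("semi_empirical mode needs m_t, m1, m2 curves")

    def m_curve(self, j: int, t: np.ndarray) -> np.ndarray:
        """m_j interpolated (log-linear) onto t, power-law tails beyond the table."""
        if self.mode == "markovian_baseline":
            return np.zeros_like(t)
        nodes = np.asarray(self.m_t, dtype=float)
        vals = np.asarray(self.m1 if j == 1 else self.m2, dtype=float)
        pos = nodes > 0
        nodes, vals = nodes[pos], vals[pos]
        out = np.interp(np.log(np.clip(t, nodes[0], nodes[-1])),
                        np.log(nodes), vals)
        lo = t < nodes[0]
        out[lo] = vals[0] * (t[lo] / nodes[0])   # m(0) = 0: linear onset
        return out


def free_propagator(model: MsdModel, r, r_start, t):
    """Free-space Gaussian density of the process at position r, started at r_start.

    Isotropy: the density is the product of d identical 1D Gaussians with
    per-coordinate variance psi(t).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    r_start = np.atleast_1d(np.asarray(r_start, dtype=float))
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("free_propagator requires t > 0")
    d = r.size
    psi = model(t)
    rho2 = float(np.sum((r - r_start) ** 2))
    return np.exp(-0.5 * rho2 / psi) / (2.0 * np.pi * psi) ** (d / 2.0)


def _q_density(problem: HighDimProblem, prop: PropagatorModel, j: int,
               r_eval: np.ndarray, t: np.ndarray, psi: np.ndarray,
               n_theta: int = 128) -> np.ndarray:
    """Density q_j(r_eval, t): Gaussian with mean on the shifted target surface,
    averaged over the hitting-angle distribution."""
    d = problem.d
    c = np.asarray(problem.r1 if j == 1 else problem.r2)
    ref = np.asarray(problem.r0) - c
    ref_norm = np.linalg.norm(ref)
    u_ref = ref / ref_norm
    s = problem.a + prop.m_curve(j, t)          # radial offset of the mean
    rho_vec = np.asarray(r_eval) - c
    if d == 1:
        mean = s * u_ref[0] * np.cos(prop.theta0)  # theta0=0: toward r0
        z2 = (rho_vec[0] - mean) ** 2 / psi
        return np.exp(-0.5 * z2) / np.sqrt(2.0 * np.pi * psi)
    if d == 2:
        th = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
        w = np.exp(prop.kappa_angle * np.cos(th - prop.theta0))
        w /= w.sum()
        # rotate the reference axis by each theta
        ca, sa = u_ref
        ux = ca * np.cos(th) - sa * np.sin(th)
        uy = sa * np.cos(th) + ca * np.sin(th)
        dx = rho_vec[0] - np.outer(s, ux)       # (n_t, n_theta)
        dy = rho_vec[1] - np.outer(s, uy)
        g = np.exp(-0.5 * (dx * dx + dy * dy) / psi[:, None]) / (2.0 * np.pi * psi[:, None])
        return g @ w
    if d == 3:
        if prop.kappa_angle != 0.0 or prop.mode == "semi_empirical" and np.any(s != problem.a):
            if prop.kappa_angle != 0.0:
                raise NotImplementedError("anisotropic hit angles implemented for d <= 2")
        # uniform average over the sphere of radius s: closed form
        rho = np.linalg.norm(rho_vec)
        pref = 1.0 / ((2.0 * np.pi * psi) ** 1.5)
        with np.errstate(over="ignore"):
            val = (np.exp(-0.5 * (rho - s) ** 2 / psi) - np.exp(-0.5 * (rho + s) ** 2 / psi))
        return pref * psi / (2.0 * rho * np.maximum(s, 1e-300)) * val * np.sqrt(2.0 * np.pi * psi)
    raise ValueError("d must be 1, 2 or 3")


def h_matrix(problem: HighDimProblem, propagator: PropagatorModel | None = None,
             n_per_decade: int = 32, t_span: tuple[float, float] = (1e-4, 1e6),
             n_theta: int = 128):
    """Time integrals h_ij = int_0^inf [q_j(r_i, t) - p(r_i, t)] dt.

    Log-trapezoidal integration over ``t_span`` (in units of the time to span
    L) plus an algebraic tail extrapolated from the decay of the integrand
    over its last decade.  Raises if the integrand has not entered a decaying
    algebraic regime by the cutoff.
    """
    if propagator is None:
        propagator = PropagatorModel()
    tc = characteristic_time(problem.model, problem.L)
    lo, hi = t_span[0] * tc, t_span[1] * tc
    n = int(round(n_per_decade * np.log10(hi / lo))) + 1
    t = np.geomspace(lo, hi, n)
    du = np.log(hi / lo) / (n - 1)
    w = t * du
    w[0] *= 0.5
    w[-1] *= 0.5
    psi = problem.model(t)
    targets = {1: np.asarray(problem.r1), 2: np.asarray(problem.r2)}
    h = np.empty((2, 2))
    for i in (1, 2):
        r_i = targets[i]
        p_i = np.array([free_propagator(problem.model, r_i, problem.r0, tk)
                        for tk in t]).reshape(-1)
        for j in (1, 2):
            q = _q_density(problem, propagator, j, r_i, t, psi, n_theta=n_theta)
            g = q - p_i
            integral = float(np.sum(w * g))
            # algebraic tail from the last decade
            mask = t >= t[-1] / 10.0
            gt = g[mask]
            if np.all(np.abs(gt) > 0) and np.all(gt * gt[-1] > 0):
                slope = np.polyfit(np.log(t[mask]), np.log(np.abs(gt)), 1)[0]
                if slope > -1.05:
                    raise RuntimeError(
                        f"h_{i}{j} integrand decays as t^{slope:.2f} at the cutoff; "
                        "integral not convergent on this span"
                    )
                integral += gt[-1] * t[-1] / (-(slope + 1.0))
            h[i - 1, j - 1] = integral
    return h[0, 0], h[0, 1], h[1, 0], h[1, 1]


def splitting_from_h(h11: float, h12: float, h21: float, h22: float):
    """Splitting probabilities from the four propagator integrals.

    ``pi1 = (h22 - h12) / (h22 + h11 - h21 - h12)``; ``pi2 = 1 - pi1``.
    """
    denom = h22 + h11 - h21 - h12
    scale = max(abs(h11), abs(h12), abs(h21), abs(h22))
    if abs(denom) < 1e-12 * scale:
        raise ZeroDivisionError("degenerate geometry: h denominator vanishes")
    pi1 = (h22 - h12) / denom
    return float(pi1), float(1.0 - pi1)


def solve_splitting_highdim(problem: HighDimProblem,
                            propagator: PropagatorModel | None = None,
                            **h_kw) -> dict:
    """Convenience wrapper: h integrals + splitting, with the mode echoed."""
    propagator = propagator or PropagatorModel()
    h11, h12, h21, h22 = h_matrix(problem, propagator, **h_kw)
    pi1, pi2 = splitting_from_h(h11, h12, h21, h22)
    return {
        "pi1": pi1, "pi2": pi2,
        "h": {"h11": h11, "h12": h12, "h21": h21, "h22": h22},
        "propagator_mode": propagator.mode,
        "kappa_angle": propagator.kappa_angle,
        "theta0": propagator.theta0,
    }


def fit_angle_distribution(angles, cap: float = 50.0):
    """Maximum-likelihood fit of Pi(theta) ~ exp(kappa cos(theta - theta0)).

    This is the von Mises family; returns (kappa_angle, theta0).  Nearly
    degenerate samples have the concentration capped at ``cap`` (with a
    warning) — beyond that the distribution is indistinguishable from a point
    mass at theta0.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 200:
        raise ValueError(f"need >= 200 angle samples, got {angles.size}")
    kappa, loc, _ = stats.vonmises.fit(angles, fscale=1)
    if kappa > cap:
        warnings.warn(f"angle concentration {kappa:.1f} capped at {cap}", stacklevel=2)
        kappa = cap
    return float(kappa), float(loc)


def calibrate_semi_empirical(problem: HighDimProblem, single_target_runs: dict,
                             min_events: int = 500) -> PropagatorModel:
    """Build a semi-empirical propagator from single-target simulation output.

    ``single_target_runs`` maps target index (1, 2) to a
    :class:`~memfp.confined2d.ConfinedFPResult` from a run with only that
    target absorbing and post-hit recording enabled.  The decoupling
    approximation takes the post-hit statistics of the two-target problem from
    these single-target runs: ``m_j(t)`` is the mean distance from the target
    center minus a, and (kappa_angle, theta0) are fitted on the contact
    angles pooled over both targets.
    """
    curves = {}
    lags = None
    all_angles = []
    for j in (1, 2):
        res = single_target_runs[j]
        n_ev = res.n_events
        if n_ev < min_events:
            raise ValueError(
                f"calibration needs >= {min_events} events for target {j}, got {n_ev}"
            )
        # target index inside a single-target run is always 1
        tgt_idx = int(np.max(res.target))
        m, _ = res.radial_mean(tgt_idx)
        curves[j] = m
        lags = res.post_lags
        all_angles.append(res.hit_angles(tgt_idx))
    kappa_angle, theta0 = fit_angle_distribution(np.concatenate(all_angles))
    return PropagatorModel(mode="semi_empirical", m_t=lags,
                           m1=curves[1], m2=curves[2],
                           kappa_angle=kappa_angle, theta0=theta0)


def propagator_from_solution_1d(solution, L: float) -> PropagatorModel:
    """Exact 1D post-hit mean curves repackaged as a PropagatorModel.

    ``m_j`` is the mean displacement from target j *into* the interval, so
    ``m1 = mu1`` and ``m2 = L - mu2``; used for the d = 1 consistency check
    between the h-integral route and the self-consistent route.
    """
    return PropagatorModel(
        mode="semi_empirical",
        m_t=np.asarray(solution.tau_grid),
        m1=np.asarray(solution.mu1),
        m2=L - np.asarray(solution.mu2),
        kappa_angle=0.0,
        theta0=0.0,
    )
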