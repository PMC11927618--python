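"""Self-consistent splitting-probability theory for 1D Gaussian processes with memory.

Two perfectly absorbing point targets sit at ``x1 = 0`` and ``x2 = L``; the
walker starts at ``x0`` in between.  For a non-Markovian process the splitting
probabilities are controlled by the mean trajectories *after* the first
passage, ``mu_1(t)`` and ``mu_2(t)`` (the average position a time t after
first hitting target 1 or 2, were the motion allowed to continue).  Two exact
ingredients close the system:

* a partition identity — averaging the position over which target is hit
  first: ``x0 = lim_{t->inf} [pi_1 mu_1(t) + pi_2 mu_2(t)]``;
* a self-consistent equation obtained by assuming the post-hit trajectories
  remain Gaussian with the covariance of the free process: for each target
  ``x_i`` and every lag ``tau``,

  .. math::

     0 = \\sum_j \\pi_j \\int_0^\\infty dt\\,\\Big\\{ p(x_i,t)(x_0-x_i)[1-M(t,\\tau)]
         - q_j(x_i,t)\\big[\\mu_j(t+\\tau)-x_i-(\\mu_j(t)-x_i)M(t,\\tau)\\big]\\Big\\}

  with ``M(t,tau) = [psi(t+tau)+psi(t)-psi(tau)]/(2 psi(t))``, ``p`` the free
  Gaussian density at the target and ``q_j`` the Gaussian density centered on
  ``mu_j(t)``.

For Brownian motion ``M == 1`` and the system collapses to the classical
``pi_2 = x0 / L``.  The solver discretizes ``mu_j`` on a geometric lag grid,
freezes the Gaussian weights ``q_j``, solves the resulting linear system for
the ``mu_j`` node values, and alternates with updates of ``pi_2`` through the
partition identity, under-relaxing both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from memfp.msd_models import MsdModel, characteristic_time, make_custom, make_powerlaw

__all__ = [
    "SplittingProblem1D",
    "GridSpec",
    "SplittingSolution1D",
    "default_grid",
    "solve_splitting_1d",
    "residual_eq2",
    "pi_from_mu",
    "pi_markovian",
    "scaling_prefactor",
    "weak_memory_check",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class SplittingProblem1D:
    """Two absorbing targets at 0 and L, start at x0, dynamics given by `model`."""

    model: MsdModel
    x0: float
    L: float

    def __post_init__(self):
        if not (0.0 < self.x0 < self.L):
            raise ValueError(f"need 0 < x0 < L, got x0={self.x0}, L={self.L}")


@dataclass(frozen=True)
class GridSpec:
    """Discretization of the lag grid and the inner time quadrature.

    ``mu_j`` lives on ``n_tau`` geometric nodes in [t_min, t_max]; the t
    integral uses a trapezoidal rule in log time with ``n_quad`` nodes per
    decade over [t_min * 10^-pad, t_max * 10^pad].
    """

    t_min: float
    t_max: float
    n_tau: int = 64
    n_quad: int = 48
    pad_decades: float = 2.0

    def __post_init__(self):
        if not (0 < self.t_min < self.t_max):
            raise ValueError("need 0 < t_min < t_max")
        if self.n_tau < 32:
            raise ValueError("n_tau must be at least 32")

    @property
    def tau_grid(self) -> np.ndarray:
        return np.geomspace(self.t_min, self.t_max, self.n_tau)

    @property
    def quad_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(nodes, weights) of the log-trapezoidal t quadrature."""
        lo = self.t_min * 10.0 ** (-self.pad_decades)
        hi = self.t_max * 10.0 ** (self.pad_decades)
        decades = np.log10(hi / lo)
        n = max(int(round(self.n_quad * decades)) + 1, 64)
        t = np.geomspace(lo, hi, n)
        du = np.log(hi / lo) / (n - 1)
        w = t * du          # dt = t d(ln t)
        w[0] *= 0.5
        w[-1] *= 0.5
        return t, w


def default_grid(problem: SplittingProblem1D, n_per_decade: int = 8,
                 n_quad: int = 48) -> GridSpec:
    """Grid keyed to the times to span x0 and to span L.

    The lag grid covers [1e-4 * t_c(x0), 1e4 * t_c(L)] where ``t_c(s)`` solves
    ``psi(t) = s^2``, resolving both the approach to the near target and the
    long-time limit of the partition identity.
    """
    t_fast = characteristic_time(problem.model, min(problem.x0, problem.L - problem.x0))
    t_slow = characteristic_time(problem.model, problem.L)
    t_min = 1e-4 * min(t_fast, t_slow)
    t_max = 1e4 * t_slow
    decades = np.log10(t_max / t_min)
    n_tau = max(64, int(round(n_per_decade * decades)) + 1)
    return GridSpec(t_min=t_min, t_max=t_max, n_tau=n_tau, n_quad=n_quad)


@dataclass
class SplittingSolution1D:
    """Converged post-first-passage mean trajectories and splitting probabilities.

    ``pi1`` is stored as ``1 - pi2`` so normalization is exact.
    """

    tau_grid: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    pi2: float
    residual_norm: float
    iterations: int
    converged: bool
    tail_estimate: float = 0.0
    pi_drift: float = 0.0
    warnings: list = field(default_factory=list)

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi2


# ---------------------------------------------------------------------------
# interpolation of the mu curves between / beyond lag nodes
# ---------------------------------------------------------------------------

class _Interp:
    """Linear-in-log-time interpolation of nu = mu - x_target on the lag nodes.

    Below the first node the curve scales linearly with t (nu(0) = 0); above
    the last node it follows a power law whose exponent is refit from the
    current iterate (mu may diverge for superdiffusive models).  For fixed
    exponents the map node-values -> curve is linear; `weights` returns the
    dense matrix of that map at arbitrary evaluation times.
    """

    def __init__(self, tau: np.ndarray, s: np.ndarray, g_low: float = 1.0):
        self.tau = tau
        self.n = tau.size
        flat = np.asarray(s, dtype=float).reshape(-1)
        self.shape = np.shape(s)
        self.lo = flat < tau[0]
        self.hi = flat > tau[-1]
        mid = ~(self.lo | self.hi)
        self.ratio_lo = flat[self.lo] / tau[0]
        self.ratio_hi = flat[self.hi] / tau[-1]
        self.g_low = g_low
        W = np.zeros((flat.size, self.n))
        if mid.any():
            lt = np.log(tau)
            ls = np.log(flat[mid])
            j = np.clip(np.searchsorted(lt, ls) - 1, 0, self.n - 2)
            w1 = (ls - lt[j]) / (lt[j + 1] - lt[j])
            rows = np.nonzero(mid)[0]
            W[rows, j] = 1.0 - w1
            W[rows, j + 1] = w1
        rows_lo = np.nonzero(self.lo)[0]
        W[rows_lo, 0] = self.ratio_lo ** g_low
        self._W = W
        self._rows_hi = np.nonzero(self.hi)[0]

    def weights(self, g_up: float) -> np.ndarray:
        W = self._W.copy()
        if self._rows_hi.size:
            W[self._rows_hi, self.n - 1] = self.ratio_hi ** np.clip(g_up, -2.0, 1.95)
        return W


def _fit_tail_exponent(tau: np.ndarray, nu: np.ndarray, L: float) -> float:
    """Power-law exponent of |nu| over the last two decades (0 if ill-defined)."""
    mask = tau >= tau[-1] / 100.0
    v = nu[mask]
    if np.abs(v[-1]) < 1e-10 * L or np.any(v * v[-1] <= 0):
        return 0.0
    slope = np.polyfit(np.log(tau[mask]), np.log(np.abs(v)), 1)[0]
    if not np.isfinite(slope):
        return 0.0
    return float(np.clip(slope, -2.0, 1.95))


def pi_from_mu(x0: float, tau_grid: np.ndarray, mu1: np.ndarray, mu2: np.ndarray):
    """Splitting probability from the long-time limit of (x0 - mu1)/(mu2 - mu1).

    The ratio is extrapolated linearly in log time over the last decade of the
    grid; the returned drift diagnostic is the relative change of the ratio
    across that decade (a warning is attached above 1%).  The estimate is valid
    even when mu1 and mu2 individually diverge.

    Returns
    -------
    pi2 : float
    drift : float
    """
    denom = mu2 - mu1
    if np.any(np.abs(denom[tau_grid >= tau_grid[-1] / 10.0]) < 1e-300):
        raise ZeroDivisionError("mu2 - mu1 vanishes at large times")
    r = (x0 - mu1) / denom
    mask = tau_grid >= tau_grid[-1] / 10.0
    lt = np.log(tau_grid[mask])
    b, a = np.polyfit(lt, r[mask], 1)
    est = a + b * lt[-1]
    drift = abs(b * np.log(10.0)) / max(abs(est), 1e-300)
    return float(est), float(drift)


def pi_markovian(x0: float, L: float) -> float:
    """Memoryless baseline ``pi2 = x0 / L`` (exact for Brownian motion)."""
    if not (0.0 < x0 < L):
        raise ValueError("need 0 < x0 < L")
    return x0 / L


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class _Workspace:
    """Grid-dependent precomputations shared across iterations."""

    def __init__(self, problem: SplittingProblem1D, grid: GridSpec):
        model = problem.model
        self.problem = problem
        self.grid = grid
        self.tau = grid.tau_grid
        self.tq, self.wq = grid.quad_grid
        self.psi_q = model(self.tq)
        psi_tau = model(self.tau)
        psi_sum = model(self.tau[:, None] + self.tq[None, :])
        self.M = (psi_sum + self.psi_q[None, :] - psi_tau[:, None]) / (2.0 * self.psi_q[None, :])
        self.x = np.array([0.0, problem.L])
        self.inv_sig = 1.0 / np.sqrt(self.psi_q)
        # free density at each target
        self.p = np.empty((2, self.tq.size))
        for i in range(2):
            z = (self.x[i] - problem.x0) * self.inv_sig
            self.p[i] = np.exp(-0.5 * z * z) * self.inv_sig / _SQRT2PI
        self.interp_q = _Interp(self.tau, self.tq)
        self.interp_up = _Interp(self.tau, self.tau[:, None] + self.tq[None, :])
        self.n_tau = self.tau.size
        self.n_q = self.tq.size

    def q_density(self, nu_q: np.ndarray, j: int) -> np.ndarray:
        """Gaussian post-hit density q_j evaluated at both targets: shape (2, n_q)."""
        mu = self.x[j] + nu_q
        z = (self.x[:, None] - mu[None, :]) * self.inv_sig[None, :]
        return np.exp(-0.5 * z * z) * self.inv_sig[None, :] / _SQRT2PI

    def assemble(self, nu: np.ndarray, pi2: float, g_up: np.ndarray):
        """Linear system A @ nu_flat = rhs for frozen Gaussian weights.

        nu has shape (2, n_tau) (deviations mu_j - x_j); returns
        (A, rhs, resid_len, tail_rel) where resid_len is the length-scaled
        residual of the *current* iterate and tail_rel the relative weight of
        the last quadrature decade in the residual integrand (truncation
        diagnostic).
        """
        K, n, nq = self.n_tau, self.n_tau, self.n_q
        piv = np.array([1.0 - pi2, pi2])
        Wq = [self.interp_q.weights(g_up[j]) for j in range(2)]
        Wup = [self.interp_up.weights(g_up[j]).reshape(K, nq, n) for j in range(2)]
        nu_q = [Wq[j] @ nu[j] for j in range(2)]
        qd = [self.q_density(nu_q[j], j) for j in range(2)]
        one_minus_M = 1.0 - self.M
        A = np.zeros((2, K, 2, n))
        rhs = np.zeros((2, K))
        tail_num = np.zeros((2, K))
        tail_mask = self.tq >= self.tq[-1] / 10.0
        for j in range(2):
            # T[k, q, m]: contribution of node m of curve j to the (k, q) integrand
            T = Wup[j] - self.M[:, :, None] * Wq[j][None, :, :]
            for i in range(2):
                qw = piv[j] * self.wq * qd[j][i]
                A[i, :, j, :] = np.einsum("q,kqm->km", qw, T, optimize=True)
                rhs[i] -= (qw * (self.x[j] - self.x[i])) @ one_minus_M.T
        for i in range(2):
            pw = self.wq * self.p[i] * (self.problem.x0 - self.x[i])
            rhs[i] += pw @ one_minus_M.T
        # residual of the current iterate, scaled to length units
        resid = rhs - np.einsum("ikjm,jm->ik", A, nu)
        norm = np.array([
            (self.wq * (piv[0] * qd[0][i] + piv[1] * qd[1][i])).sum() for i in range(2)
        ])
        resid_len = resid / norm[:, None]
        # truncation estimate: integrand mass in the last quadrature decade
        for i in range(2):
            pw = self.wq * self.p[i] * (self.problem.x0 - self.x[i])
            contrib = pw[None, tail_mask] * one_minus_M[:, tail_mask]
            for j in range(2):
                qw = piv[j] * self.wq * qd[j][i]
                nu_up = np.einsum("kqm,m->kq", Wup[j][:, tail_mask, :], nu[j])
                term = qw[None, tail_mask] * (
                    nu_up - self.M[:, tail_mask] * nu_q[j][None, tail_mask]
                    + (self.x[j] - self.x[i]) * one_minus_M[:, tail_mask]
                )
                contrib = contrib - term
            tail_num[i] = np.abs(contrib).sum(axis=1)
        tail_rel = float(np.max(tail_num / norm[:, None]) / self.problem.L)
        return A, rhs, resid_len, tail_rel


def solve_splitting_1d(problem: SplittingProblem1D, grid: GridSpec | None = None,
                       tol: float = 1e-6, max_iter: int = 400,
                       damping: float = 0.8,
                       resid_tol: float = 1e-4) -> SplittingSolution1D:
    """Solve the self-consistent system for mu_1, mu_2 and pi_2.

    Deterministic for fixed grid and tolerances.  Iteration: initialize with
    the Markovian ansatz (``mu_j = x_j``, ``pi2 = x0/L``); alternately solve
    the linear system in the mu node values for frozen Gaussian weights
    (under-relaxed by ``damping``) and update pi2 through the partition
    identity.  Convergence requires ``max |d mu| / L`` and ``|d pi2|`` below
    ``tol``; correctness is judged by the residual of the self-consistent
    equation, scaled to length units, relative to L (``resid_tol``).
    """
    if not (0.0 < damping <= 1.0):
        raise ValueError("damping must be in (0, 1]")
    wlist: list[str] = []
    L = problem.L
    if min(problem.x0, L - problem.x0) < 1e-6 * L:
        # degenerate start: on (or numerically on) a target
        pi2 = 0.0 if problem.x0 < L / 2 else 1.0
        wlist.append("x0 within 1e-6 L of a target: returning deterministic split")
        tau = np.geomspace(1.0, 10.0, 32)
        return SplittingSolution1D(tau, np.zeros(32), np.full(32, L), pi2,
                                   0.0, 0, True, warnings=wlist)
    if grid is None:
        grid = default_grid(problem)
    ws = _Workspace(problem, grid)
    n = ws.n_tau
    nu = np.zeros((2, n))
    pi2 = problem.x0 / L
    g_up = np.zeros(2)
    resid_norm = np.inf
    tail_rel = 0.0
    drift = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        A, rhs, resid_len, tail_rel = ws.assemble(nu, pi2, g_up)
        resid_norm = float(np.max(np.abs(resid_len)) / L)
        sol = np.linalg.lstsq(
            A.reshape(2 * n, 2 * n), rhs.reshape(2 * n), rcond=None
        )[0].reshape(2, n)
        nu_new = (1.0 - damping) * nu + damping * sol
        g_up = np.array([_fit_tail_exponent(ws.tau, nu_new[j], L) for j in range(2)])
        pi_est, drift = pi_from_mu(problem.x0, ws.tau, nu_new[0], L + nu_new[1])
        pi_est = float(np.clip(pi_est, 1e-12, 1.0 - 1e-12))
        # trust region on the odds: at most a factor 3 per iteration, which
        # prevents the fixed point from shooting to 0/1 in hard superdiffusive
        # small-x0 problems while leaving ordinary updates untouched
        odds = pi2 / (1.0 - pi2)
        odds_est = np.clip(pi_est / (1.0 - pi_est), odds / 3.0, odds * 3.0)
        pi_est = float(odds_est / (1.0 + odds_est))
        pi_new = (1.0 - damping) * pi2 + damping * pi_est
        delta = max(float(np.max(np.abs(nu_new - nu)) / L), abs(pi_new - pi2))
        nu, pi2 = nu_new, pi_new
        if delta < tol:
            converged = True
            break
    # final residual at the converged iterate
    _, _, resid_len, tail_rel = ws.assemble(nu, pi2, g_up)
    resid_norm = float(np.max(np.abs(resid_len)) / L)
    if not converged:
        wlist.append(f"max_iter={max_iter} reached; last residual {resid_norm:.2e}")
        warnings.warn(wlist[-1], stacklevel=2)
    if resid_norm > resid_tol:
        wlist.append(f"residual {resid_norm:.2e} exceeds resid_tol {resid_tol:.1e}")
    if drift > 0.01:
        wlist.append(f"pi ratio drift {drift:.2%} over last decade (> 1%)")
    return SplittingSolution1D(
        tau_grid=ws.tau, mu1=nu[0], mu2=L + nu[1], pi2=float(pi2),
        residual_norm=resid_norm, iterations=it,
        converged=converged and resid_norm <= resid_tol,
        tail_estimate=tail_rel, pi_drift=drift, warnings=wlist,
    )


def residual_eq2(problem: SplittingProblem1D, mu1: np.ndarray, mu2: np.ndarray,
                 pi2: float, tau, i: int, grid: GridSpec | None = None,
                 tau_grid: np.ndarray | None = None):
    """Residual of the self-consistent equation for target i at lag(s) tau.

    ``mu1, mu2`` are given on ``tau_grid`` (default: ``grid.tau_grid``); the
    residual is the right-hand side of the self-consistent equation scaled to
    length units (zero at the true solution).  Mostly a diagnostic: the solver
    reports the same quantity as ``residual_norm`` (relative to L).
    """
    if i not in (1, 2):
        raise ValueError("target index i must be 1 or 2")
    if grid is None:
        grid = default_grid(problem)
    ws = _Workspace(problem, grid)
    tg = ws.tau if tau_grid is None else np.asarray(tau_grid)
    if tau_grid is not None and (tg.shape != ws.tau.shape or not np.allclose(tg, ws.tau)):
        raise ValueError("mu curves must be sampled on grid.tau_grid")
    nu = np.vstack([np.asarray(mu1) - 0.0, np.asarray(mu2) - problem.L])
    g_up = np.array([_fit_tail_exponent(ws.tau, nu[j], problem.L) for j in range(2)])
    _, _, resid_len, _ = ws.assemble(nu, pi2, g_up)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    vals = np.interp(np.log(tau), np.log(ws.tau), resid_len[i - 1])
    return vals if vals.size > 1 else float(vals[0])


# ---------------------------------------------------------------------------
# scale-invariant asymptotics and the weak-memory regime
# ---------------------------------------------------------------------------

def scaling_prefactor(model: MsdModel, ratios: Sequence[float] | None = None,
                      tol_exponent: float = 0.10, **solve_kw):
    """Small-x0/L law ``pi2 ~ A_H (x0/L)**(1/H - 1)`` for a scale-invariant model.

    Solves the splitting problem at each ratio (L = 1) and fits
    ``log pi2`` against ``log (x0/L)``.  Returns ``(A_H, exponent)``; raises if
    the fitted exponent deviates from ``1/H - 1`` by more than ``tol_exponent``
    (relative), which signals a too-coarse solver grid.
    """
    if model.name != "powerlaw":
        raise ValueError("scaling_prefactor requires a scale-invariant (powerlaw) model")
    H = model.H_infinity
    if ratios is None:
        ratios = np.geomspace(0.02, 0.1, 5)
    ratios = np.asarray(ratios, dtype=float)
    if np.any(ratios > 0.1):
        raise ValueError("ratios must be <= 0.1 (asymptotic regime)")
    pis = []
    for r in ratios:
        prob = SplittingProblem1D(model, r, 1.0)
        sol = solve_splitting_1d(prob, **solve_kw)
        pis.append(sol.pi2)
    pis = np.asarray(pis)
    slope, intercept = np.polyfit(np.log(ratios), np.log(pis), 1)
    expected = 1.0 / H - 1.0
    if abs(slope - expected) > tol_exponent * expected:
        raise RuntimeError(
            f"fitted exponent {slope:.4f} deviates from 1/H-1 = {expected:.4f} "
            f"by more than {tol_exponent:.0%}: solver grid too coarse"
        )
    return float(np.exp(intercept)), float(slope)


def weak_memory_check(psi1, epsilons: Sequence[float], x0: float = 0.3,
                      L: float = 1.0, D: float = 0.5, **solve_kw):
    """Linear response of pi2 to a weak memory perturbation psi = 2Dt + eps*psi1(t).

    Fits ``pi2(eps) - x0/L`` against eps; returns (linear coefficient,
    max relative residual of the linear model).  The residual must vanish
    quadratically in eps for a theory exact at first order.
    """
    epsilons = np.asarray(epsilons, dtype=float)
    if np.any(epsilons < 0):
        raise ValueError("epsilons must be nonnegative")
    devs = []
    for eps in epsilons:
        if eps == 0:
            devs.append(0.0)
            continue

        def psi(t, _e=eps):
            t = np.asarray(t, dtype=float)
            return 2.0 * D * t + _e * np.asarray(psi1(t))

        model = make_custom(psi, 0.5, 2.0 * D, name="weak-memory")
        sol = solve_splitting_1d(SplittingProblem1D(model, x0, L), **solve_kw)
        devs.append(sol.pi2 - x0 / L)
    devs = np.asarray(devs)
    nz = epsilons > 0
    coef = float(np.sum(devs[nz] * epsilons[nz]) / np.sum(epsilons[nz] ** 2))
    resid = devs - coef * epsilons
    rel = float(np.max(np.abs(resid[nz]) / np.abs(devs[nz]).clip(1e-300)))
    return coef, rel
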