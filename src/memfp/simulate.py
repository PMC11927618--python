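"""Exact sampling of stationary-increment Gaussian processes and Monte Carlo first passage.

The samplers here are *exact* in distribution at the sampled instants:

* circulant embedding (FFT) of the increment autocovariance for any
  :class:`~memfp.msd_models.MsdModel` — in particular fractional Gaussian noise;
* exact Ornstein-Uhlenbeck/Brownian updates for the bidiffusive process;
* exact normal-mode updates for the free-end Rouse chain.

First-passage observables (which target is hit first, interpolated hit times,
post-hit conditional mean trajectories) are measured on the sampled paths and
serve as the brute-force oracle for the self-consistent theory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import fft as sfft

from memfp.msd_models import MsdModel, increment_autocov, rouse_mode_spectrum

__all__ = [
    "PathEnsemble",
    "FirstPassageEvent",
    "HittingStats",
    "CirculantEmbeddingError",
    "sample_fgn",
    "sample_gaussian_increment_process",
    "sample_bidiffusive_exact",
    "sample_rouse",
    "first_passage_two_targets",
    "estimate_splitting_mc",
    "splitting_mc",
    "ensemble_msd",
]


class CirculantEmbeddingError(RuntimeError):
    """The circulant embedding of the increment autocovariance is not nonnegative."""


@dataclass
class PathEnsemble:
    """Sampled discrete-time trajectories.

    ``positions`` has shape (n_paths, n_steps + 1) in 1D or
    (n_paths, n_steps + 1, d) in d > 1; every path starts at 0.
    """

    dt: float
    positions: np.ndarray
    seed: int | None
    model: str

    @property
    def n_paths(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1] - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.positions.shape[1]) * self.dt


@dataclass
class FirstPassageEvent:
    """One first-passage event between two targets at 0 and L."""

    target_index: int          # 1 (target at 0) or 2 (target at L)
    hit_time: float            # linearly interpolated crossing instant
    post_path: np.ndarray      # absolute positions from the first post-hit sample
    post_dt: float


@dataclass
class HittingStats:
    """Monte Carlo splitting estimate with conditional post-hit mean trajectories."""

    pi2_hat: float
    se: float
    n_events: int
    n_censored: int
    mu_lags: np.ndarray
    mu1_hat: np.ndarray
    mu1_se: np.ndarray
    mu2_hat: np.ndarray
    mu2_se: np.ndarray
    n1: int = 0
    n2: int = 0

    @property
    def censored_fraction(self) -> float:
        tot = self.n_events + self.n_censored
        return self.n_censored / tot if tot else 0.0


# ---------------------------------------------------------------------------
# circulant embedding
# ---------------------------------------------------------------------------

def _circulant_eigenvalues(model: MsdModel, dt: float, n_steps: int,
                           tol: float = 1e-8):
    """Eigenvalues of the circulant embedding of the increment autocovariance.

    Returns (lam, m) with m the (even, FFT-friendly) circulant size.  Small
    negative eigenvalues (down to -tol * max) are clipped to zero; anything
    below that raises :class:`CirculantEmbeddingError`.
    """
    m = sfft.next_fast_len(2 * n_steps, real=True)
    if m % 2:
        m = sfft.next_fast_len(m + 1, real=True)
    half = m // 2
    c = increment_autocov(model, dt, np.arange(half + 1))
    circ = np.concatenate([c, c[-2:0:-1]])
    lam = np.fft.fft(circ).real
    neg = lam.min()
    if neg < -tol * lam.max():
        raise CirculantEmbeddingError(
            f"negative circulant eigenvalue {neg:.3e} (max {lam.max():.3e}) "
            f"for model {model.name}; embedding invalid at this dt/n"
        )
    return np.clip(lam, 0.0, None), m


def _sample_increments_circulant(lam: np.ndarray, m: int, n_steps: int,
                                 n_paths: int, rng: np.random.Generator,
                                 dtype=np.float64) -> np.ndarray:
    """Draw stationary Gaussian increment sequences from circulant eigenvalues.

    Real and imaginary parts of the transformed white noise give two
    independent samples each, so batches are generated in pairs.
    """
    out = np.empty((n_paths, n_steps), dtype=dtype)
    sq = np.sqrt(lam / m)
    # memory cap ~256 MB of complex scratch per batch
    pair_cap = max(1, int(2.5e8 / (16 * m)))
    done = 0
    while done < n_paths:
        pairs = min(pair_cap, (n_paths - done + 1) // 2)
        z = rng.standard_normal((pairs, m)) + 1j * rng.standard_normal((pairs, m))
        w = sfft.fft(sq * z, axis=-1, workers=1)
        take = min(2 * pairs, n_paths - done)
        re = w[:, :n_steps].real
        im = w[:, :n_steps].imag
        both = np.concatenate([re, im], axis=0)
        out[done:done + take] = both[:take]
        done += take
    return out


def sample_gaussian_increment_process(model: MsdModel, n_steps: int, dt: float,
                                      n_paths: int, seed: int | None = None,
                                      rng: np.random.Generator | None = None) -> PathEnsemble:
    """Exact stationary-increment Gaussian paths with the model's MSD, via circulant embedding."""
    if rng is None:
        rng = np.random.default_rng(seed)
    lam, m = _circulant_eigenvalues(model, dt, n_steps)
    inc = _sample_increments_circulant(lam, m, n_steps, n_paths, rng)
    pos = np.empty((n_paths, n_steps + 1))
    pos[:, 0] = 0.0
    np.cumsum(inc, axis=1, out=pos[:, 1:])
    return PathEnsemble(dt=dt, positions=pos, seed=seed, model=model.name)


def sample_fgn(H: float, kappa: float, n_steps: int, dt: float, n_paths: int,
               seed: int | None = None) -> PathEnsemble:
    """Exact fractional Brownian motion paths (fGN increments via circulant embedding)."""
    from memfp.msd_models import make_powerlaw

    return sample_gaussian_increment_process(
        make_powerlaw(kappa, H), n_steps, dt, n_paths, seed=seed
    )


def sample_bidiffusive_exact(B: float, n_steps: int, dt: float, n_paths: int,
                             seed: int | None = None) -> PathEnsemble:
    """Bidiffusive paths by exact Brownian + equilibrium Ornstein-Uhlenbeck updates.

    ``x(t) = W(t) + y(t) - y(0)`` with ``<W^2> = t`` and y a stationary OU
    process of unit relaxation time and variance B/2, so the total MSD is
    ``t + B (1 - e^-t)``.  Discrete updates are exact (no Euler bias).
    """
    rng = np.random.default_rng(seed)
    e = math.exp(-dt)
    s_ou = math.sqrt(B / 2.0 * (1.0 - e * e)) if B > 0 else 0.0
    pos = np.empty((n_paths, n_steps + 1))
    pos[:, 0] = 0.0
    w = np.zeros(n_paths)
    y0 = rng.standard_normal(n_paths) * math.sqrt(B / 2.0) if B > 0 else np.zeros(n_paths)
    y = y0.copy()
    sdt = math.sqrt(dt)
    for k in range(1, n_steps + 1):
        w += sdt * rng.standard_normal(n_paths)
        if B > 0:
            y = y * e + s_ou * rng.standard_normal(n_paths)
        pos[:, k] = w + y - y0
    return PathEnsemble(dt=dt, positions=pos, seed=seed, model=f"bidiffusive(B={B})")


def sample_rouse(N: int, d: int, n_steps: int, dt: float, n_paths: int,
                 seed: int | None = None) -> PathEnsemble:
    """First-monomer trajectory of a free-end Rouse chain, exact normal-mode updates.

    Internal modes are initialized at equilibrium so the monomer has stationary
    increments; each mode performs exact OU steps and the center of mass an
    exact Brownian step.  Returned positions have shape
    (n_paths, n_steps+1, d) for d > 1, (n_paths, n_steps+1) for d = 1.
    """
    if d not in (1, 2, 3):
        raise ValueError("d must be 1, 2 or 3")
    rng = np.random.default_rng(seed)
    lam, phi1 = rouse_mode_spectrum(N)
    lam_i, phi_i = lam[1:], phi1[1:]
    sigma = np.sqrt(1.0 / lam_i) if lam_i.size else lam_i
    e = np.exp(-lam_i * dt)
    step_sd = sigma * np.sqrt(1.0 - e * e)
    com_sd = phi1[0] * math.sqrt(2.0 * dt)

    pos = np.empty((n_paths, n_steps + 1, d))
    a = rng.standard_normal((n_paths, lam_i.size, d)) * sigma[None, :, None]
    com = np.zeros((n_paths, d))
    x0 = com + np.tensordot(a, phi_i, axes=(1, 0)) if lam_i.size else com.copy()
    pos[:, 0] = 0.0
    for k in range(1, n_steps + 1):
        com += com_sd * rng.standard_normal((n_paths, d))
        if lam_i.size:
            a *= e[None, :, None]
            a += step_sd[None, :, None] * rng.standard_normal((n_paths, lam_i.size, d))
            pos[:, k] = com + np.tensordot(a, phi_i, axes=(1, 0)) - x0
        else:
            pos[:, k] = com - x0
    if d == 1:
        pos = pos[:, :, 0]
    return PathEnsemble(dt=dt, positions=pos, seed=seed, model=f"rouse(N={N},d={d})")


# ---------------------------------------------------------------------------
# first passage on 1D ensembles
# ---------------------------------------------------------------------------

def _scan_first_passage(pos: np.ndarray, x0: float, L: float):
    """Vectorized two-target scan of shifted paths ``x0 + pos``.

    Returns (target, idx, frac): target in {1, 2, 0=censored}; idx is the first
    sample index at/past the crossing; frac in (0, 1] the interpolated
    sub-step crossing fraction between idx-1 and idx.
    """
    x = x0 + pos
    out = (x <= 0.0) | (x >= L)
    hit_any = out.any(axis=1)
    idx = np.argmax(out, axis=1)
    n = pos.shape[0]
    target = np.zeros(n, dtype=np.int64)
    frac = np.ones(n)
    rows = np.nonzero(hit_any)[0]
    j = idx[rows]
    prev = x[rows, j - 1]
    cur = x[rows, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_lo = np.where(cur <= 0.0, prev / (prev - cur), np.inf)
        f_hi = np.where(cur >= L, (L - prev) / (cur - prev), np.inf)
    lo_first = f_lo <= f_hi
    target[rows] = np.where(lo_first, 1, 2)
    frac[rows] = np.where(lo_first, f_lo, f_hi)
    return target, idx, frac


def first_passage_two_targets(paths: PathEnsemble, x0: float, L: float,
                              follow_duration: float = 0.0,
                              censored_warn: float = 0.01,
                              censored_max: float = 0.20):
    """First-passage events of 1D paths started at x0 between targets at 0 and L.

    Paths (which start at 0) are shifted to start at x0.  The hit instant is
    linearly interpolated at the level crossing; ``post_path`` records absolute
    positions from the first post-hit sample for ``follow_duration``.  Paths
    never reaching either target are censored and reported via the second
    return value.

    Returns
    -------
    events : list of FirstPassageEvent
    n_censored : int
    """
    if not (0.0 < x0 < L):
        raise ValueError("need 0 < x0 < L")
    pos = paths.positions
    if pos.ndim != 2:
        raise ValueError("first_passage_two_targets needs a 1D ensemble")
    dt = paths.dt
    n_follow = int(round(follow_duration / dt))
    target, idx, frac = _scan_first_passage(pos, x0, L)
    events: list[FirstPassageEvent] = []
    for r in range(pos.shape[0]):
        if target[r] == 0:
            continue
        j = idx[r]
        hit_time = (j - 1 + frac[r]) * dt
        seg = x0 + pos[r, j:j + n_follow]
        events.append(FirstPassageEvent(int(target[r]), float(hit_time), seg, dt))
    n_censored = int((target == 0).sum())
    n_tot = pos.shape[0]
    cf = n_censored / n_tot
    if cf > censored_max:
        raise RuntimeError(
            f"censored fraction {cf:.1%} exceeds {censored_max:.0%}: horizon far too short"
        )
    if cf > censored_warn:
        import warnings

        warnings.warn(f"censored fraction {cf:.1%} > {censored_warn:.0%}: "
                      "consider a longer horizon", stacklevel=2)
    return events, n_censored


def estimate_splitting_mc(events: Sequence[FirstPassageEvent],
                          n_censored: int = 0) -> HittingStats:
    """Splitting probability and post-hit conditional means from first-passage events.

    ``pi2_hat`` is the ensemble average of the indicator (1 if the target at L
    was hit first) with binomial standard error; the conditional mean curves
    average the post-hit segments per target on their common sample grid.
    """
    if len(events) < 100:
        raise ValueError(f"need at least 100 events, got {len(events)}")
    eta = np.array([e.target_index == 2 for e in events], dtype=float)
    n = eta.size
    pi2 = float(eta.mean())
    se = math.sqrt(pi2 * (1.0 - pi2) / n)
    dt = events[0].post_dt
    n_lags = min((e.post_path.size for e in events), default=0)
    lags = np.arange(n_lags) * dt
    curves = {}
    counts = {}
    for tgt in (1, 2):
        segs = [e.post_path[:n_lags] for e in events if e.target_index == tgt]
        counts[tgt] = len(segs)
        if segs and n_lags:
            arr = np.asarray(segs)
            mu = arr.mean(axis=0)
            sem = arr.std(axis=0, ddof=1) / math.sqrt(len(segs)) if len(segs) > 1 else np.full(n_lags, np.nan)
        else:
            mu = np.full(n_lags, np.nan)
            sem = np.full(n_lags, np.nan)
        curves[tgt] = (mu, sem)
    return HittingStats(
        pi2_hat=pi2, se=se, n_events=n, n_censored=n_censored,
        mu_lags=lags,
        mu1_hat=curves[1][0], mu1_se=curves[1][1],
        mu2_hat=curves[2][0], mu2_se=curves[2][1],
        n1=counts[1], n2=counts[2],
    )


# ---------------------------------------------------------------------------
# chunked Monte Carlo driver
# ---------------------------------------------------------------------------

def splitting_mc(model: MsdModel, x0: float, L: float, n_paths: int,
                 n_steps: int, dt: float, seed: int | None = None,
                 sampler: Callable[..., PathEnsemble] | None = None,
                 follow_steps: int = 0, follow_stride: int = 1,
                 chunk_paths: int | None = None) -> HittingStats:
    """Monte Carlo splitting estimate, generating and scanning paths in chunks.

    Designed for large ensembles (10^4+ paths of 10^4+ steps) that would not
    fit in memory as one :class:`PathEnsemble`.  ``sampler(n_steps, dt,
    n_paths, rng=...)`` defaults to the circulant-embedding sampler for
    ``model``.  Post-hit conditional means are accumulated at ``follow_steps``
    lags spaced ``follow_stride`` samples apart.
    """
    rng = np.random.default_rng(seed)
    lam = m = None
    if sampler is None:
        lam, m = _circulant_eigenvalues(model, dt, n_steps)
    if chunk_paths is None:
        budget = int(2.5e8 / (8 * (n_steps + 1)))
        chunk_paths = int(np.clip(budget, 16, n_paths))
    n2 = n1 = n_cen = 0
    lag_idx = np.arange(follow_steps) * follow_stride
    sums = {1: np.zeros(follow_steps), 2: np.zeros(follow_steps)}
    sumsq = {1: np.zeros(follow_steps), 2: np.zeros(follow_steps)}
    cnts = {1: np.zeros(follow_steps, dtype=np.int64), 2: np.zeros(follow_steps, dtype=np.int64)}
    done = 0
    while done < n_paths:
        b = min(chunk_paths, n_paths - done)
        if sampler is None:
            inc = _sample_increments_circulant(lam, m, n_steps, b, rng)
            pos = np.empty((b, n_steps + 1))
            pos[:, 0] = 0.0
            np.cumsum(inc, axis=1, out=pos[:, 1:])
            del inc
        else:
            pos = sampler(n_steps=n_steps, dt=dt, n_paths=b, rng=rng).positions
        target, idx, _ = _scan_first_passage(pos, x0, L)
        n_cen += int((target == 0).sum())
        n1 += int((target == 1).sum())
        n2 += int((target == 2).sum())
        if follow_steps:
            for tgt in (1, 2):
                rows = np.nonzero(target == tgt)[0]
                if rows.size == 0:
                    continue
                cols = idx[rows][:, None] + lag_idx[None, :]
                valid = cols <= n_steps
                cols = np.minimum(cols, n_steps)
                vals = x0 + pos[rows[:, None], cols]
                sums[tgt] += np.where(valid, vals, 0.0).sum(axis=0)
                sumsq[tgt] += np.where(valid, vals * vals, 0.0).sum(axis=0)
                cnts[tgt] += valid.sum(axis=0)
        del pos
        done += b
    n_events = n1 + n2
    if n_events == 0:
        raise RuntimeError("no first-passage events recorded")
    pi2 = n2 / n_events
    se = math.sqrt(pi2 * (1.0 - pi2) / n_events)
    curves = {}
    for tgt in (1, 2):
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = sums[tgt] / cnts[tgt]
            var = sumsq[tgt] / cnts[tgt] - mu * mu
            sem = np.sqrt(np.clip(var, 0.0, None) / np.maximum(cnts[tgt], 1))
            mu = np.where(cnts[tgt] > 0, mu, np.nan)
            sem = np.where(cnts[tgt] > 1, sem, np.nan)
        curves[tgt] = (mu, sem)
    return HittingStats(
        pi2_hat=float(pi2), se=float(se), n_events=int(n_events), n_censored=int(n_cen),
        mu_lags=lag_idx * dt,
        mu1_hat=curves[1][0], mu1_se=curves[1][1],
        mu2_hat=curves[2][0], mu2_se=curves[2][1],
        n1=n1, n2=n2,
    )


def ensemble_msd(paths: PathEnsemble, lag_steps):
    """Ensemble MSD (from the path origin) at the given integer lags, with SE.

    Returns (lags_time, msd, se).  Valid for stationary-increment ensembles
    started at 0.
    """
    lag_steps = np.asarray(lag_steps, dtype=int)
    pos = paths.positions
    disp = pos[:, lag_steps] - pos[:, [0]]
    if disp.ndim == 3:  # d > 1: per-coordinate MSD averaged over coordinates
        sq = (disp ** 2).mean(axis=2)
    else:
        sq = disp ** 2
    msd = sq.mean(axis=0)
    se = sq.std(axis=0, ddof=1) / math.sqrt(pos.shape[0])
    return lag_steps * paths.dt, msd, se
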