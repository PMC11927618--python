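"""Monte Carlo first passage to absorbing disks in 2D with reflective confinement.

The walker moves in the plane with independent, identical coordinate dynamics
(any stationary-increment Gaussian process).  Two absorbing disks of radius
``a`` sit at ``c1`` and ``c2``; the motion is confined to a disk of radius
``R`` centered on ``c1`` by specular (radial-fold) reflection.  For processes
with memory a naive positional reflection would corrupt the memory state, so
the fold is applied to the *memoryless* component of the motion (the Brownian
mode / center of mass), which leaves the internal relaxation modes untouched.

Processes with an exact finite-dimensional Markovian embedding (Brownian,
bidiffusive = Brownian + Ornstein-Uhlenbeck, Rouse normal modes) are stepped
exactly and streamed through a compiled kernel, so arbitrarily long horizons
cost no memory.  Any other MSD model is pre-sampled per coordinate by
circulant embedding and then folded, at the price of holding the paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from memfp.msd_models import MsdModel, rouse_mode_spectrum
from memfp.simulate import HittingStats, _circulant_eigenvalues, _sample_increments_circulant

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

__all__ = ["ConfinedFPResult", "simulate_confined_fp_2d", "markovian_embedding"]


@dataclass
class ConfinedFPResult:
    """Raw per-path outcome of a confined two-disk first-passage run.

    ``target`` is 1/2 for absorption (0 = censored); ``post`` holds the
    post-hit positions (confined, absorption off) every ``post_stride`` steps.
    """

    dt: float
    target: np.ndarray          # (n_paths,)
    hit_time: np.ndarray        # (n_paths,) interpolated
    hit_pos: np.ndarray         # (n_paths, 2) position at first sample past the hit
    post: np.ndarray            # (n_paths, n_post, 2), NaN where unused
    post_stride: int
    centers: np.ndarray         # (2, 2)
    r0: np.ndarray
    a: float
    R: float
    seed: int | None

    @property
    def n_events(self) -> int:
        return int((self.target > 0).sum())

    @property
    def censored_fraction(self) -> float:
        return float((self.target == 0).mean())

    def splitting(self) -> tuple[float, float]:
        """(pi2_hat, se) over recorded events."""
        hit = self.target > 0
        n = int(hit.sum())
        if n == 0:
            raise RuntimeError("no events")
        pi2 = float((self.target[hit] == 2).mean())
        return pi2, math.sqrt(pi2 * (1.0 - pi2) / n)

    @property
    def post_lags(self) -> np.ndarray:
        return np.arange(self.post.shape[1]) * self.dt * self.post_stride

    def post_axis_projection(self, target_index: int):
        """Mean post-hit position projected on the inter-target axis, with SE.

        The projection is the signed coordinate along the unit vector from
        c1 to c2, with origin at c1 (matching the 1D picture 0..L).
        """
        axis = self.centers[1] - self.centers[0]
        axis = axis / np.linalg.norm(axis)
        sel = self.target == target_index
        if not sel.any():
            raise RuntimeError(f"no events for target {target_index}")
        proj = (self.post[sel] - self.centers[0]) @ axis
        mu = np.nanmean(proj, axis=0)
        n = np.sum(~np.isnan(proj), axis=0)
        se = np.nanstd(proj, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        return mu, se

    def radial_mean(self, target_index: int):
        """Mean distance from the hit target's center minus a, vs time after hit."""
        sel = self.target == target_index
        if not sel.any():
            raise RuntimeError(f"no events for target {target_index}")
        r = np.linalg.norm(self.post[sel] - self.centers[target_index - 1], axis=2)
        m = np.nanmean(r, axis=0) - self.a
        n = np.sum(~np.isnan(r), axis=0)
        se = np.nanstd(r, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        return m, se

    def hit_angles(self, target_index: int) -> np.ndarray:
        """Contact-point angles relative to the axis from the hit target toward r0."""
        sel = self.target == target_index
        c = self.centers[target_index - 1]
        ref = np.asarray(self.r0) - c
        ref_angle = math.atan2(ref[1], ref[0])
        v = self.hit_pos[sel] - c
        ang = np.arctan2(v[:, 1], v[:, 0]) - ref_angle
        return np.mod(ang + np.pi, 2.0 * np.pi) - np.pi


def markovian_embedding(model: MsdModel):
    """Exact (Brownian + OU modes) embedding of a per-coordinate MSD model.

    Returns (s_w_unit, coef, lam, sigma) where the Brownian step std over dt
    is ``s_w_unit * sqrt(dt)`` and each OU mode has relaxation rate lam[p],
    stationary std sigma[p] and monomer weight coef[p].  Raises ValueError for
    models without a finite embedding (use the circulant route instead).
    """
    if model.name == "powerlaw" and abs(model.H_infinity - 0.5) < 1e-12:
        return math.sqrt(model.kappa), np.zeros(0), np.zeros(0), np.zeros(0)
    if model.name == "bidiffusive":
        B = float(model.params["B"])
        if B == 0.0:
            return 1.0, np.zeros(0), np.zeros(0), np.zeros(0)
        return 1.0, np.ones(1), np.ones(1), np.array([math.sqrt(B / 2.0)])
    if model.name == "rouse":
        N = int(model.params["N"])
        lam, phi1 = rouse_mode_spectrum(N)
        sw = phi1[0] * math.sqrt(2.0)
        sig = np.sqrt(1.0 / lam[1:]) if N > 1 else np.zeros(0)
        return sw, phi1[1:].copy(), lam[1:].copy(), sig
    raise ValueError(f"no exact Markovian embedding for model '{model.name}'")


@njit(cache=True)
def _run_streamed(seed, n_paths, n_steps, dt, s_w, coef, e_mode, sigma, step_sd,
                  r0x, r0y, c1x, c1y, c2x, c2y, a, R, two_targets,
                  n_post, post_stride,
                  target, hit_time, hit_pos, post):  # pragma: no cover - compiled
    np.random.seed(seed)
    n_modes = coef.shape[0]
    for p in range(n_paths):
        ax = np.empty(n_modes)
        ay = np.empty(n_modes)
        sx = 0.0
        sy = 0.0
        for q in range(n_modes):
            ax[q] = sigma[q] * np.random.standard_normal()
            ay[q] = sigma[q] * np.random.standard_normal()
            sx += coef[q] * ax[q]
            sy += coef[q] * ay[q]
        wx = r0x - sx
        wy = r0y - sy
        px = r0x
        py = r0y
        d1p = math.hypot(px - c1x, py - c1y)
        d2p = math.hypot(px - c2x, py - c2y)
        tgt = 0
        swdt = s_w * math.sqrt(dt)
        for k in range(1, n_steps + 1):
            wx += swdt * np.random.standard_normal()
            wy += swdt * np.random.standard_normal()
            sx = 0.0
            sy = 0.0
            for q in range(n_modes):
                ax[q] = ax[q] * e_mode[q] + step_sd[q] * np.random.standard_normal()
                ay[q] = ay[q] * e_mode[q] + step_sd[q] * np.random.standard_normal()
                sx += coef[q] * ax[q]
                sy += coef[q] * ay[q]
            px = wx + sx
            py = wy + sy
            rho = math.hypot(px - c1x, py - c1y)
            if rho > R:
                f = (2.0 * R - rho) / rho
                nx = c1x + f * (px - c1x)
                ny = c1y + f * (py - c1y)
                wx += nx - px
                wy += ny - py
                px = nx
                py = ny
            d1 = math.hypot(px - c1x, py - c1y)
            d2 = math.hypot(px - c2x, py - c2y) if two_targets else 1e300
            if d1 <= a or d2 <= a:
                if d1 <= a and (not (d2 <= a) or d1 <= d2):
                    tgt = 1
                    frac = (d1p - a) / max(d1p - d1, 1e-300)
                else:
                    tgt = 2
                    frac = (d2p - a) / max(d2p - d2, 1e-300)
                if frac > 1.0:
                    frac = 1.0
                target[p] = tgt
                hit_time[p] = (k - 1 + frac) * dt
                hit_pos[p, 0] = px
                hit_pos[p, 1] = py
                # follow the free-but-confined motion after the hit
                idx = 0
                if n_post > 0:
                    post[p, 0, 0] = px
                    post[p, 0, 1] = py
                    idx = 1
                    kk = 0
                    while idx < n_post:
                        wx += swdt * np.random.standard_normal()
                        wy += swdt * np.random.standard_normal()
                        sx = 0.0
                        sy = 0.0
                        for q in range(n_modes):
                            ax[q] = ax[q] * e_mode[q] + step_sd[q] * np.random.standard_normal()
                            ay[q] = ay[q] * e_mode[q] + step_sd[q] * np.random.standard_normal()
                            sx += coef[q] * ax[q]
                            sy += coef[q] * ay[q]
                        px = wx + sx
                        py = wy + sy
                        rho = math.hypot(px - c1x, py - c1y)
                        if rho > R:
                            f = (2.0 * R - rho) / rho
                            nx = c1x + f * (px - c1x)
                            ny = c1y + f * (py - c1y)
                            wx += nx - px
                            wy += ny - py
                            px = nx
                            py = ny
                        kk += 1
                        if kk == post_stride:
                            post[p, idx, 0] = px
                            post[p, idx, 1] = py
                            idx += 1
                            kk = 0
                break
            d1p = d1
            d2p = d2
        if tgt == 0:
            target[p] = 0
            hit_time[p] = np.nan


@njit(cache=True)
def _fold_absorb_paths(xs, ys, dt, c1x, c1y, c2x, c2y, a, R, two_targets,
                       n_post, post_stride,
                       target, hit_time, hit_pos, post):  # pragma: no cover - compiled
    n_paths, n_tot = xs.shape
    for p in range(n_paths):
        offx = 0.0
        offy = 0.0
        px = xs[p, 0]
        py = ys[p, 0]
        d1p = math.hypot(px - c1x, py - c1y)
        d2p = math.hypot(px - c2x, py - c2y)
        tgt = 0
        hit_k = -1
        for k in range(1, n_tot):
            px = xs[p, k] + offx
            py = ys[p, k] + offy
            rho = math.hypot(px - c1x, py - c1y)
            if rho > R:
                f = (2.0 * R - rho) / rho
                nx = c1x + f * (px - c1x)
                ny = c1y + f * (py - c1y)
                offx += nx - px
                offy += ny - py
                px = nx
                py = ny
            if tgt == 0:
                d1 = math.hypot(px - c1x, py - c1y)
                d2 = math.hypot(px - c2x, py - c2y) if two_targets else 1e300
                if d1 <= a or d2 <= a:
                    if d1 <= a and (not (d2 <= a) or d1 <= d2):
                        tgt = 1
                        frac = (d1p - a) / max(d1p - d1, 1e-300)
                    else:
                        tgt = 2
                        frac = (d2p - a) / max(d2p - d2, 1e-300)
                    if frac > 1.0:
                        frac = 1.0
                    target[p] = tgt
                    hit_time[p] = (k - 1 + frac) * dt
                    hit_pos[p, 0] = px
                    hit_pos[p, 1] = py
                    hit_k = k
                    if n_post == 0:
                        break
                d1p = d1
                d2p = d2
            else:
                idx = (k - hit_k) // post_stride
                if (k - hit_k) % post_stride == 0:
                    if idx < n_post:
                        post[p, idx, 0] = px
                        post[p, idx, 1] = py
                    else:
                        break
        if tgt > 0 and n_post > 0 and hit_k >= 0:
            post[p, 0, 0] = hit_pos[p, 0]
            post[p, 0, 1] = hit_pos[p, 1]
        if tgt == 0:
            target[p] = 0
            hit_time[p] = np.nan


def simulate_confined_fp_2d(model: MsdModel, r0, centers, a: float, R: float,
                            n_paths: int, dt: float, n_steps: int,
                            seed: int | None = None,
                            follow_duration: float = 0.0,
                            post_stride: int = 1,
                            single_target: bool = False,
                            chunk_paths: int | None = None) -> ConfinedFPResult:
    """First passage to two absorbing disks in a reflecting disk of radius R.

    ``model`` is the per-coordinate MSD model; ``centers`` is (2, 2) with the
    confinement centered on ``centers[0]``.  The time step must resolve the
    targets: RMS 2D step ``sqrt(2 psi(dt)) <= a / 3`` (hard error otherwise).
    ``single_target=True`` disables absorption at the second disk (used for
    semi-empirical propagator calibration).
    """
    r0 = np.asarray(r0, dtype=float)
    centers = np.asarray(centers, dtype=float).reshape(2, 2)
    if np.linalg.norm(centers[0] - centers[1]) <= 2.0 * a and not single_target:
        raise ValueError("targets overlap: need |c1 - c2| > 2a")
    for point, label in ((r0, "r0"), (centers[1], "c2")):
        if np.linalg.norm(point - centers[0]) > R:
            raise ValueError(f"{label} lies outside the confinement disk")
    if np.linalg.norm(r0 - centers[0]) <= a or (
            not single_target and np.linalg.norm(r0 - centers[1]) <= a):
        raise ValueError("r0 starts inside a target")
    rms = math.sqrt(2.0 * float(model(dt)))
    if rms > a / 3.0:
        raise ValueError(
            f"dt too coarse: RMS 2D step {rms:.3g} exceeds a/3 = {a / 3:.3g}"
        )
    n_post = int(round(follow_duration / (dt * post_stride)))
    target = np.zeros(n_paths, dtype=np.int64)
    hit_time = np.full(n_paths, np.nan)
    hit_pos = np.full((n_paths, 2), np.nan)
    post = np.full((n_paths, max(n_post, 0), 2), np.nan)
    rng = np.random.default_rng(seed)
    try:
        s_w, coef, lam, sigma = markovian_embedding(model)
    except ValueError:
        s_w = None
    if s_w is not None:
        e_mode = np.exp(-lam * dt)
        step_sd = sigma * np.sqrt(1.0 - e_mode ** 2)
        kernel_seed = int(rng.integers(0, 2 ** 31 - 1))
        _run_streamed(kernel_seed, n_paths, n_steps, dt, s_w, coef, e_mode,
                      sigma, step_sd, r0[0], r0[1],
                      centers[0, 0], centers[0, 1], centers[1, 0], centers[1, 1],
                      a, R, not single_target, n_post, post_stride,
                      target, hit_time, hit_pos, post)
    else:
        # general stationary-increment model: pre-sample free coordinates
        n_tot = n_steps + n_post * post_stride
        lam_c, m = _circulant_eigenvalues(model, dt, n_tot)
        if chunk_paths is None:
            chunk_paths = max(8, int(1.2e8 / (8 * n_tot)))
        done = 0
        while done < n_paths:
            b = min(chunk_paths, n_paths - done)
            xs = np.empty((b, n_tot + 1))
            ys = np.empty((b, n_tot + 1))
            xs[:, 0] = r0[0]
            ys[:, 0] = r0[1]
            np.cumsum(_sample_increments_circulant(lam_c, m, n_tot, b, rng),
                      axis=1, out=xs[:, 1:])
            xs[:, 1:] += r0[0]
            np.cumsum(_sample_increments_circulant(lam_c, m, n_tot, b, rng),
                      axis=1, out=ys[:, 1:])
            ys[:, 1:] += r0[1]
            _fold_absorb_paths(xs, ys, dt,
                               centers[0, 0], centers[0, 1],
                               centers[1, 0], centers[1, 1],
                               a, R, not single_target, n_post, post_stride,
                               target[done:done + b], hit_time[done:done + b],
                               hit_pos[done:done + b],
                               post[done:done + b] if n_post else post[:0])
            done += b
    return ConfinedFPResult(dt=dt, target=target, hit_time=hit_time,
                            hit_pos=hit_pos, post=post, post_stride=post_stride,
                            centers=centers, r0=r0, a=a, R=R, seed=seed)
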