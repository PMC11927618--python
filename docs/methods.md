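# Methods

`memfp` computes splitting probabilities — which of two absorbing targets a
random walker reaches first — for one-dimensional, unbiased, nonsmooth
Gaussian processes with stationary increments, together with the simulation
and data-analysis machinery needed to check the theory against sampled paths
and against particle-tracking-style trajectory data.  This note records the
model, the numerical choices, and what the shipped tests do and do not
establish.

## The model class

A centered Gaussian process with stationary increments is fully specified by
its mean-square displacement (MSD) psi(t).  Every process in the package is
represented by an `MsdModel`: psi as a vectorized callable plus its long-time
law psi(t) ~ kappa t^(2H), 0 < H < 1.  Shipped families:

| family | psi(t) | parameters | notes |
|---|---|---|---|
| power law (fBM) | kappa t^(2H) | kappa > 0, 0 < H < 1 | scale invariant; H = 1/2 is Brownian |
| bidiffusive | t + B(1 - e^-t) | B >= 0 | white + single-relaxation colored noise (Maxwell fluid) |
| viscoelastic | A f(t/tau0), f(y) = [(y - a + 1) gamma(a, y) + y^a e^-y]/Gamma(a) | A > 0, tau0 > 0, 0 < alpha <= 1 | induced by a power-law friction kernel cut off at tau0; psi ~ t^alpha below tau0, diffusive above |
| Rouse monomer | 2t/N + mode sum | integer N >= 1 | first monomer of a free-end bead-spring chain, unit spring constant, noise variance 2 per coordinate |

The thermal prefactor of the viscoelastic MSD (2 k_B T tau0 / gamma_0) is kept
as the single amplitude A; temperature and friction are never separated
because only their combination is observable in tracking data.  The small-y
expansion of f is y^alpha / Gamma(1 + alpha) (1 + y(1 - alpha)/(1 + alpha) + ...),
which the unit tests pin against the regularized incomplete-gamma evaluation.

The Rouse monomer MSD is derived by normal-mode decomposition of
dx_i/dt = x_{i+1} - 2x_i + x_{i-1} + f_i with free ends (x_0 = x_1,
x_{N+1} = x_N): eigenvalues lambda_p = 4 sin^2(p pi / 2N), first-monomer
weights phi_p(1)^2 = (2/N) cos^2(p pi / 2N), center-of-mass diffusion 2t/N per
coordinate.  The derivation is validated against the exact normal-mode
simulator to 5% over three decades of lag.

## Splitting theory in 1D

Targets at 0 and L absorb on first touch; the walker starts at x0.  The key
objects are the post-first-passage mean trajectories mu_1(t), mu_2(t): the
average position a time t after the first contact, were the motion to
continue.  Two relations close the problem:

* partition identity: x0 = lim_t [pi_1 mu_1(t) + pi_2 mu_2(t)];
* a self-consistent integral equation expressing that the conditional mean of
  x(t + tau) given x(t) = x_i, averaged over t with Gaussian weights, can be
  partitioned over which target was hit first.  The conditional-mean weight is
  M(t, tau) = [psi(t+tau) + psi(t) - psi(tau)] / (2 psi(t)), and the post-hit
  path statistics are assumed Gaussian with the covariance of the free
  process.

This closure is an approximation (exact to first order in a weak-memory
expansion, and exact for Brownian motion where M = 1 gives pi_2 = x0/L and
mu_j pinned at the targets).  The package treats it as the theory to be
computed exactly, and quantifies its accuracy only through the Monte Carlo
cross-checks.

### Discretization

* mu_j is represented by its deviation nu_j = mu_j - x_j on a geometric lag
  grid spanning [1e-4 t_c(min(x0, L - x0)), 1e4 t_c(L)], 8 nodes/decade
  (minimum 64), where t_c(s) solves psi(t) = s^2.  Keying the lower end to the
  *near-target* time resolves the fast structure of mu_1 when x0 << L.
* The t-integral uses a trapezoidal rule in log t, 48 nodes/decade, padded two
  decades beyond the lag grid.  The integrand of the self-consistent equation
  decays only marginally (t^(-3H)) for small H; the truncated equations keep
  the exact cancellation between the p- and q-terms, and the reported
  `tail_estimate` bounds the neglected mass.  Grid-refinement studies (nodes
  per decade 8 -> 16, quadrature 48 -> 64/decade, padding 2 -> 3 decades) move
  pi2 for fBM H = 0.4 by less than 0.001.
* Between nodes nu_j is interpolated linearly in log t; above the last node it
  follows a power law refit from the last two decades each iteration (mu may
  diverge for superdiffusive models); below the first node it vanishes
  linearly.
* Iteration: start from the Markovian ansatz (nu = 0, pi2 = x0/L); freeze the
  Gaussian weights q_j, solve the linear system for the nu node values, relax
  with factor 0.8, re-estimate pi2 from the partition identity with the same
  relaxation, and repeat until max |d nu|/L and |d pi2| < 1e-6.  The 0.8
  relaxation was verified to reach the same fixed point as 0.5 (pi2 agreement
  ~1e-5) on every shipped family, in roughly half the iterations.  A trust
  region clips the pi2 odds update to a factor 3 per iteration; without it the
  alternation can shoot to pi2 = 0 or 1 for superdiffusive models at
  x0/L <= 0.04, with it those cases converge onto the small-x0 scaling law.
* Correctness is defined by the residual of the self-consistent equation,
  scaled to length units and reported relative to L (`residual_norm`,
  converged means <= 1e-4).  pi2 is extracted as the long-time limit of
  (x0 - mu1)/(mu2 - mu1), extrapolated linearly in log t over the last grid
  decade, with a drift diagnostic (warn above 1%); the limit exists even when
  mu_1 and mu_2 individually diverge.
* Degenerate starts within 1e-6 L of a target return pi deterministically with
  a warning instead of running the solver.

### Scaling law and weak memory

For the scale-invariant family, pi2 ~ A_H (x0/L)^(1/H - 1) as x0/L -> 0.
`scaling_prefactor` fits log pi2 against log(x0/L) over ratios <= 0.1 and
raises if the exponent misses 1/H - 1 by more than 10% (a solver-resolution
alarm, not a tunable).  `weak_memory_check` probes psi = 2Dt + eps psi_1:
the pi2 deviation is linear in eps with an O(eps^2) leftover; measured
curvature shows the linear regime holds for eps <= 0.05 for the
bidiffusive-type perturbation at x0/L = 0.3 (at eps ~ 0.4 the quadratic term
reaches tens of percent, so the doubling check is run in the small-eps
regime).

## Exact process sampling

All samplers are exact in distribution at the sample times; there is no
Euler bias anywhere.

* Stationary-increment models: circulant embedding of the increment
  autocovariance c(k) = [psi((k+1)dt) - 2 psi(k dt) + psi(|k-1| dt)]/2, FFT
  eigenvalues, complex white noise; real and imaginary parts give two
  independent paths.  Negative eigenvalues below -1e-8 of the maximum abort;
  tiny negatives are clipped.  For fractional Gaussian noise the embedding is
  provably nonnegative.
* Bidiffusive: exact Brownian + equilibrium Ornstein-Uhlenbeck updates
  (stationary initialization makes the monomer increments stationary).
* Rouse: exact OU step per normal mode, exact Brownian center of mass,
  equilibrium mode initialization.

First passage is detected on the discrete path with linear interpolation of
the crossing instant; no bridge correction is applied because none is well
defined for non-Markovian paths.  The residual effect is a positive bias of
the *counted* splitting probability that decays slowly for rough
(subdiffusive) paths — empirically like the RMS one-step displacement to a
power ~2 H_local — while the post-hit conditional mean curves are unbiased at
the same dt.  The dt-halving test quantifies this bias; the acceptance
comparisons run at the step sizes stated there, where the bias is within the
statistical tolerance.  Censored paths (no hit within the horizon) are
excluded from the estimate with a recorded fraction (warn above 1%, error
above 20%).

## Planar problems and the large-volume formula

In d > 1 the large-volume splitting probability reduces to time integrals
h_ij of propagator differences q_j(r_i, t) - p(r_i, t), where p is the free
Gaussian and q_j the density after the first passage to target j:
pi_1 = (h22 - h12)/(h22 + h11 - h21 - h12).  Memory enters through q_j.  Two
closures are offered and echoed in every output:

* markovian baseline — q_j recentered on the target, isotropic hit angles;
* semi-empirical — post-hit mean at c_j + (a + m_j(t)) u(theta), hit angle
  theta ~ exp(kappa cos(theta - theta0)) (von Mises), with m_j and the angle
  law calibrated from single-target simulations under the decoupling
  approximation.  theta is measured from the axis joining the hit target to
  the start; the target radius enters additively so m_j(0) = 0 places the
  post-hit mean on the target surface.  This parameterization is the simplest
  consistent reading of the closure; outputs always record which mode
  produced them.

The time integral runs on a log grid over [1e-4, 1e6] times the time to span
L, with an algebraic tail fitted over the last decade (error if the integrand
has not reached a decaying power law).  In d = 1 the h-route with the exact
post-hit means from the self-consistent solver agrees with the partition-
identity route to 1e-2 — the two routes are computed independently.

The confined Monte Carlo oracle reflects at radius R by folding the position
radially; the fold is applied to the memoryless component (Brownian mode /
center of mass), leaving relaxation-mode memory intact.  The confinement
prescription is a modeling choice; its justification is the measured
insensitivity of pi to R (R vs 2R within statistics).  The time step must
satisfy RMS 2D step <= a/3 (hard guard).

## Trajectory pipeline

From a (t, x) table: time-averaged MSD with overlapping windows (per-lag
variance via the (N - k)/k effective-sample count — a conservative standard
estimator), weighted log-log fit of the viscoelastic crossover model with
delta-method CIs and identifiability flags, Gaussianity check
(Kolmogorov-Smirnov on standardized non-overlapping increments at the memory
time and half of it, plus excess kurtosis), drift check (circular block
bootstrap, block >= 2x the memory time), and the empirical splitting
estimator: fictitious targets at p - x0 and p - x0 + L around each admitted
start, first crossing recorded, next start admitted >= one spacing (choose
>= 2 tau0) after the crossing; confidence intervals are twice the SD of the
mean.  Events that reuse a start across several x0 values are flagged
correlated.  A hard guard rejects trajectories whose median one-frame step
exceeds L/10, mirroring the frame-rate condition of the experimental design.

### Synthetic bead data and what the tests show

`gen_synthetic_bead_trajectory` emulates bead-in-polymer-solution tracking:
exact circulant sampling of the viscoelastic MSD (defaults: amplitude 1,
tau0 = 3 s, alpha = 0.5, i.e. a mid-concentration solution with a memory time
of a few seconds), unbiased, Gaussian, stationary increments, optional i.i.d.
localization noise adding a 2 sigma^2 plateau.  It reproduces exactly the
assumptions of the theory; what passing tests show is therefore the internal
consistency of theory, samplers and estimators — not that real bead data
satisfies those assumptions (real data adds tracking noise correlations,
drift, finite exposure blur, and possible non-Gaussianity, which only the
diagnostic checks would flag).

The end-to-end replication (generate -> fit MSD -> solve theory -> compare
empirical splitting and post-hit means) is run at the statistical scale of
the experiment it emulates: a memoryless "water" condition and viscoelastic
conditions with alpha = 0.75 (tau0 = 1.5 s) and alpha = 0.6 (tau0 = 3 s),
with tens to hundreds of recorded events per start offset and CIs of twice
the SD of the mean; since each offset is checked against a 95% interval, one
in ~20 may legitimately fall outside, and the test allows exactly that.
Post-hit mean curves are compared for a single start offset (the resolution
of the emulated mean-trajectory measurements) over lags in [tau0/2, 4 tau0].
Frame intervals are chosen so the median one-frame step is a few percent of
L; within those design constraints the crossing-miss bias of the empirical
estimator sits inside the stated CIs.  At much higher event counts the same
comparison would resolve both the residual frame-rate bias (it decays only
as a weak power of the frame interval for subdiffusive paths) and the
Gaussian-closure error of the theory itself; a deeper-memory condition
(alpha = 0.45, tau0 = 7 s, crossings within a few memory times) is therefore
checked qualitatively — near-target preference and post-hit recoil — because
there the closure measurably overestimates the recoil (theory mu plateau
0.64 vs simulation 0.43-0.51 at L = 2.8, x0 = 0.7) and a CI-level comparison
is not informative.

## Numerical edge cases

* Incomplete gamma through the scipy regularized routine (small-y series and
  large-y asymptotics internally); f(0) = 0 exactly.
* Tabulated MSDs: monotone PCHIP interpolation in log-log, declared (kappa, H)
  tail beyond the table, local power law below it.
* characteristic_time: geometric bracketing plus Brent in log t, bracket
  widened a factor 2 to survive log/exp roundoff at razor-thin brackets.
* Angle-distribution fits cap the concentration at 50 (beyond that the sample
  is indistinguishable from a point mass).
* All tolerances are keyword-configurable; defaults were validated on the
  Brownian closed form.

## Problem sizes

The shipped test suite and the acceptance script size their Monte Carlo at:
2e4 paths of 2e4 steps (H = 0.6) and 8e4 steps (H = 0.4; the finer step keeps
the crossing-miss bias of first-passage counting inside the statistical
window) for the fBM theory-vs-simulation comparisons; 4-5e3 paths x 1.6e5
steps for the bidiffusive post-passage curves; 4-5e3 paths for sampler
calibration; 4e2-9e2 paths for the planar runs (R = 90 and 200); and tens to
hundreds of events per start offset for the trajectory pipeline.  These sizes
make every stated tolerance a few standard errors wide.

## Known limitations

* The Gaussian stationary-covariance closure is approximate for strongly
  non-Markovian processes; the package quantifies the residual only through
  its own Monte Carlo (observed: ~1 SE agreement for fBM H = 0.6; a few
  percent relative offset in pi2 for strongly antipersistent models, partly
  degenerate with the simulators' own first-passage discretization bias).
* No smooth (finite-velocity) or biased processes, no aging, no more than two
  targets, no partially absorbing targets.
* d > 1 is large-volume only; the semi-empirical propagator is a calibrated
  approximation, not an exact closure, and is labeled as such in outputs.
* The empirical splitting estimator inherits the frame-rate bias discussed
  above; its guards (step <= L/10, start spacing >= 2 tau0) are necessary,
  not sufficient, for unbiasedness.
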