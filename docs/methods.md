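# Methods

## Model

`qsgrowth` models a bacterial population that can pay a growth-rate cost to
produce a shared public good (a secreted starch-degrading enzyme) in
exchange for a higher carrying capacity. The density N(t) (CFU/mL) follows
a logistic law whose two constants switch when production is activated:

    dN/dt = lambda(t) * N * (1 - N / kappa(t))

- Before activation: lambda = lambda0, kappa = kappa0.
- At the activation time t_a the rate switches instantaneously to
  lambda1 (<= lambda0: production is costly).
- The capacity does not jump: it ramps linearly from kappa0 to kappa1
  (>= kappa0: the enzyme releases extra nutrients) over a latency
  D(N(t_a)) that depends on the population density at activation. D is
  evaluated once, at activation, and frozen for the rest of the run.
- D(N) is a nondecreasing piecewise-linear function of activation density
  (`DelayFunction`), in practice a two-segment hinge: zero up to a
  breakpoint n_break (the "no-delay window") and linear above it. Below the
  first knot the function is constant; above the last knot it continues the
  final segment's slope.

Activation is driven by a `ControlSchedule`: `never`, `external` (induced
at a chosen time t_i), or `qs` — a quorum-sensing rule that fires the first
time N reaches a threshold alpha, abstracting autoinducer accumulation into
a density threshold. If N exceeds the current kappa(t) (possible right
after a switch) the logistic term is negative and the population declines
toward the capacity; densities are floored at 1 CFU/mL.

Units are hours and CFU/mL throughout; callers convert.

### Integrators

- `piecewise_closed_form` (default): exact logistic propagation on the
  constant-parameter segments, and an adaptive Runge-Kutta solve
  (rtol 1e-10) across the capacity ramp. QS crossing times are located by
  root-finding on the continuous pre-activation solution (xtol 1e-12), so
  activation does not depend on the output grid.
- `fine_rk`: fixed-step classical RK4 (default step 1e-3 h), written
  independently of the closed-form path and used as the reference oracle in
  tests; QS crossings are bisected inside the bracketing step, and steps
  are split at the switch time and ramp end so none straddles a kink.
- `euler`: forward Euler on the output grid, a deliberately crude
  comparator.
- `simulate_discrete`: the discrete-time approximation used for fitting.
  Within each step (lambda, kappa) are frozen and the state advances with
  the exact constant-parameter logistic update, which is exact whenever
  the parameters are constant across the step (any dt, never mode, and
  away from the ramp). During the ramp, kappa is frozen at the *step
  midpoint*: freezing at the step start lags the ramp by O(dt) and leaves
  ~11% error at dt = 1 h for a typical mid-experiment induction, while the
  midpoint value cancels the first-order term (measured max discrepancy
  7.8e-3 between dt = 1 h and dt = 0.01 h). Forward Euler is available for
  comparison and keeps the conventional start-of-step freeze.

## Calibration

The staged procedure mirrors how the model is calibrated to replicate
plate counts (triplicate hourly CFU/mL over 0-24 h, 25 samples):

1. **Replicate summary.** Per time point: mean, sample SD (n-1), and
   weight 1/SD. The SD is floored at 1e-3 times the mean — a zero sample
   SD is a finite-replicate artifact, and an unfloored weight would be
   infinite. A single replicate gets unit weights.
2. **Growth constants** (`fit_rate_capacity`). Weighted nonlinear least
   squares for (lambda, kappa) on a single-phase culture, with N(0)
   *fixed* to the mean of the first sample and the k = 0 residual dropped
   (it carries no information once N(0) is pinned). Fixing N(0) is what
   makes both constants estimable at once: counts span several decades, so
   a free N(0) lets the steady state dominate (good kappa, poor lambda)
   while a log-scale fit does the opposite. The uninduced culture yields
   (lambda0, kappa0), the t_i = 0 culture (lambda1, kappa1).
3. **Capacity-gain latency** (`fit_delay`). For each induced culture, a
   joint weighted fit of (N(0), D >= 0) with the four growth constants
   fixed; the model is the discrete-time switched logistic on the data's
   own grid.
4. **Delay function** (`fit_delay_function`). A least-squares hinge
   D(N) = s * max(0, N - n_break) through the per-arm (activation density,
   delay) pairs, with the breakpoint searched over the data range.
5. **QS threshold** (`fit_threshold`). A deterministic grid scan (default
   60 log-spaced candidates over 1e5..1e9 CFU/mL): for each alpha the QS
   model is simulated from the fixed N(0) and scored by the weighted SSR;
   ties break toward the smaller alpha. The scan uses the continuous-time
   integrator: with the discrete model whole intervals of alpha produce
   identical trajectories (the objective is a staircase), whereas the
   continuous activation time varies smoothly with alpha and noiseless
   data identify the generating grid point exactly.

Descriptive fits for comparing conditions are kept separate from the
calibration: `fit_logistic_rk` (unweighted logistic over (N(0), r, k) on
replicate means) and `fit_exponential_rate` (log-linear slope of the first
six samples).

### Weighting convention

"Weights are the inverse of the SD" admits two readings: a 1/SD multiplier
on the squared residual, or residuals normalized by the SD (an inverse-
variance multiplier). The package defaults to inverse variance
(`weight_mode="inv_var"`) — standard weighted least squares, under which
scaling a dataset's SDs by c scales its WSSR by 1/c² — and retains the
literal 1/SD multiplier as `weight_mode="inv_sd"`. Noiseless fits are
identical under both.

### Optimizer

Bounded trust-region least squares (`scipy.optimize.least_squares`, trf)
with seeded multistart (5 starts): lambda in [0.01, 3] 1/h, kappa in
[10 N(0), 1e11] CFU/mL (log-parametrized), D in [0, 24] h. The best
iterate is returned even when no start converges, flagged via
`converged=False`. All randomness flows from explicit integer seeds.

### Identifiability of the latency, and the safeguards around it

D only shapes the trajectory while the population is close enough to the
capacity for the ramp to bind. When activation happens at low density
(inside the no-delay window — e.g. induction at t = 0 from a 1e6 CFU/mL
inoculum) the trajectory changes by under 1% for D anywhere in [0, 6] h,
so the argmin of the objective is noise. Three safeguards:

- `fit_delay` collapses to D = 0 when a latency-free refit is within 2% of
  the optimal cost (a pure plateau), and always reports a linearized SE
  for D plus the re-optimized zero-latency cost ratio.
- `fit_delay_function` accepts per-point weights (the pipeline uses
  inverse-variance weights from the delay SEs) and anchors the breakpoint
  search at the largest observed zero-delay density: the hinge is zero at
  and below n_break, so a zero-delay observation is a lower bound for it,
  and without the anchor n_break is unidentified whenever the positive-
  delay arms are nearly collinear.
- In the end-to-end pipeline, the t_i = 0 arm enters the hinge with zero
  latency by construction — it is the very culture that calibrated
  (lambda1, kappa1) as a latency-free logistic, so a latency fitted to it
  can only absorb parameter error — and any other arm whose latency-free
  refit is not significantly worse (F(1, dof) at 5%, i.e. cost ratio below
  about 1 + 4.3/dof) also enters as zero.

Even so, the recovered n_break is only determined to within the spacing of
the neighbouring activation densities (with arms at roughly 1e6, 1.4e7,
5e7, 1.1e8 CFU/mL it can land anywhere between the last zero-latency arm
and the first latent one); treat it as an order-of-magnitude summary.

## Relative fitness

RF is the time-averaged pointwise ratio of an induced culture's density to
the uninduced reference. The default normalization divides the ratio sum
by the number of grid points so identical curves give RF = 1; the raw sum
is available (`normalization="sum"`, equal to T times the mean). The ratio
cancels the decade sweep of raw counts, so all time points contribute on a
comparable scale, and RF is invariant to rescaling both series together.
The k = 0 term is included (its ratio is ~1 by construction). Empirical
curves use replicate means on both sides; per-replicate RF is available as
a diagnostic. `model_fitness_scan` simulates one trajectory per induction
time against a never-activated trajectory from the same N(0). Ties in the
optimum break toward the earliest induction time.

## Synthetic data

The generator emulates a 24-h plate-count experiment: triplicate hourly
counts for a panel of conditions sharing one inoculum — cultures induced
at t in {0, 3, 5, 8, 12} h, an uninduced control, and optionally the
OFF/ON/QS strategy trio. Noise is multiplicative: each count is the
noiseless continuous-model trajectory times an independent lognormal
multiplier with median 1 and CV `noise_cv` (default 0.10), the standard
dispersion structure for serial-dilution plate counts spanning decades;
log counts then have constant variance across the 1e5..1e9 CFU/mL range.
Noise is independent across replicates and time points.

Default scenario constants — lambda0 = 0.9, lambda1 = 0.45 1/h,
kappa0 = 1.2e8, kappa1 = 8e8 CFU/mL, hinge delay breaking at 1e7 CFU/mL
with 5 h latency at 1e8, N(0) = 1e6, QS threshold 5e7 — are implementation
defaults chosen to exercise the dynamic range of real amylase-sharing
cultures; they are not measured values.

What the generator does **not** emulate: Poisson counting error at the
dilution-plate level, day/batch covariance between cultures, autocorrelated
deviations (e.g. a replicate running systematically warm), or any signal
transport/accumulation dynamics behind the threshold abstraction. Passing
recovery tests on this generator therefore demonstrates correctness of the
estimators under the stated noise model, not robustness to structured
experimental artifacts.

## Problem sizes and numerical choices

Tests and the acceptance script run at the experiment's native scale
(3 replicates x 25 hourly samples; 50-100 seeded datasets for Monte-Carlo
recovery; 60-point threshold grids), which keeps full runs in seconds to a
couple of minutes. Key tolerances: closed-form vs. grid agreement 1e-9
(never mode is exact); piecewise integrator vs. RK4 oracle < 1e-3
relative; noiseless round-trip recovery 1e-6. Degenerate inputs are
handled explicitly: saturated series flag r as unidentifiable in
`fit_logistic_rk`; all-zero delay points return the trivial zero
`DelayFunction`; thresholds below N(0) all reduce to ON dynamics and tie.

## Known limitations

- The QS abstraction is a sharp density threshold; graded promoter
  response and autoinducer transport are out of scope.
- No demographic stochasticity or spatial structure.
- Parameter uncertainties are linearized SEs, not bootstrap or posterior
  intervals.
- The latency estimator's spread at 10% count noise is ~0.3-1 h per arm
  (worse near the no-delay boundary); the hinge breakpoint inherits the
  arm spacing as its resolution.
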