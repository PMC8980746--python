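"""Staged calibration of the switched logistic model to replicate CFU counts.

The calibration mirrors how the model is fit to plate-count growth curves:

1. ``fit_rate_capacity`` — weighted nonlinear least squares for (lambda,
   kappa) on a single-phase culture (never-activated, or induced at t = 0),
   with the initial condition N(0) *fixed* to the mean of the first sample.
   Fixing N(0) balances the transient against the stationary regime: counts
   span several decades, so a free N(0) lets the steady state dominate the
   objective (good kappa, poor lambda), while fitting in log scale does the
   opposite.
2. ``fit_delay`` — for each externally induced culture, a joint fit of the
   initial condition N(0) and the capacity-gain latency D with the four
   growth constants held fixed.
3. ``fit_delay_function`` — a two-segment hinge summarizing latency as a
   function of activation density (zero below a breakpoint, linear above).
4. ``fit_threshold`` — a grid scan of the quorum-sensing threshold alpha
   against the QS culture's counts.

``fit_logistic_rk`` and ``fit_exponential_rate`` are the simpler summary
fits (plain logistic r/k on replicate means; log-linear early-phase rate)
used for descriptive comparisons between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .model import (
    ControlSchedule,
    DelayFunction,
    GrowthParams,
    _propagate_grid,
    logistic_closed_form,
    simulate,
)

__all__ = [
    "GrowthDataset",
    "FitResult",
    "ThresholdScan",
    "summarize_replicates",
    "weighted_ssr",
    "fit_rate_capacity",
    "fit_exponential_rate",
    "fit_logistic_rk",
    "fit_delay",
    "fit_threshold",
    "fit_delay_function",
    "default_alpha_grid",
]

#: Fraction of the replicate mean used to floor the SD before inverting it
#: into a weight; zero sample SD is a finite-replicate artifact and would
#: otherwise produce an infinite weight.
SD_FLOOR_FRAC = 1e-3

_LAMBDA_BOUNDS = (0.01, 3.0)
_KAPPA_MAX = 1e11
_DELAY_BOUNDS = (0.0, 24.0)


@dataclass
class GrowthDataset:
    """Replicate CFU/mL time series for one experimental condition.

    ``counts`` is a (replicates x times) matrix; all replicates share the
    time axis.  ``induction_time`` is None for never-induced cultures.
    """

    times: np.ndarray
    counts: np.ndarray
    label: str = ""
    induction_time: Optional[float] = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.atleast_2d(np.asarray(self.counts, dtype=float))
        if times.ndim != 1 or len(times) == 0:
            raise ValueError("times must be a nonempty 1-D array")
        if counts.shape[1] != len(times):
            raise ValueError(
                f"counts has {counts.shape[1]} columns but there are {len(times)} times"
            )
        if counts.shape[0] < 1:
            raise ValueError("at least one replicate is required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(counts)) or np.any(counts <= 0):
            raise ValueError("all counts must be positive and finite")
        self.times = times
        self.counts = counts

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def n_times(self) -> int:
        return self.counts.shape[1]

    def mean_series(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    def first_density(self) -> float:
        """Mean of the first sample across replicates (the fixed N(0))."""
        return float(self.counts[:, 0].mean())


@dataclass
class FitResult:
    """Outcome of one least-squares stage.

    ``estimates`` are the optimized quantities, ``fixed`` the values held
    constant; ``wssr`` is the weighted sum of squared residuals and
    ``residual_series`` the per-time weighted residuals entering it.
    """

    estimates: dict
    fixed: dict
    wssr: float
    n_points: int
    converged: bool
    residual_series: np.ndarray = field(default_factory=lambda: np.array([]))
    label: str = ""
    #: linearized standard errors for (a subset of) the estimates
    uncertainty: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.wssr < 0:
            raise ValueError("wssr must be nonnegative")
        overlap = set(self.estimates) & set(self.fixed)
        if overlap:
            raise ValueError(f"estimates and fixed overlap on {sorted(overlap)}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "wssr": float(self.wssr),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
        }


def summarize_replicates(
    dataset: GrowthDataset, sd_floor_frac: float = SD_FLOOR_FRAC
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-time replicate mean, sample SD (n-1 denominator) and weight 1/SD.

    The SD is floored at ``sd_floor_frac`` times the mean before inversion;
    with a single replicate the weights are all one (no dispersion
    information).
    """
    mean = dataset.counts.mean(axis=0)
    if dataset.n_replicates == 1:
        sd = np.zeros_like(mean)
        weights = np.ones_like(mean)
    else:
        sd = dataset.counts.std(axis=0, ddof=1)
        weights = 1.0 / np.maximum(sd, sd_floor_frac * mean)
    return mean, sd, weights


def _weight_multiplier(weights: np.ndarray, weight_mode: str) -> np.ndarray:
    """Multiplier on the *squared* residual for each weighting convention."""
    if weight_mode == "inv_var":
        return weights**2
    if weight_mode == "inv_sd":
        return weights
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def weighted_ssr(
    model_series: np.ndarray,
    dataset: GrowthDataset,
    weight_mode: str = "inv_var",
    skip_first: bool = True,
) -> float:
    """Weighted sum of squared residuals of a model series against the
    replicate means.  ``skip_first`` drops the k = 0 point, which carries no
    information once N(0) is pinned to it."""
    mean, _, weights = summarize_replicates(dataset)
    m = _weight_multiplier(weights, weight_mode)
    sl = slice(1, None) if skip_first else slice(None)
    r = np.asarray(model_series, dtype=float)[sl] - mean[sl]
    return float(np.sum(m[sl] * r**2))


def _weighted_residuals(model_series, mean, weights, weight_mode, skip_first=True):
    m = np.sqrt(_weight_multiplier(weights, weight_mode))
    sl = slice(1, None) if skip_first else slice(None)
    return m[sl] * (np.asarray(model_series, dtype=float)[sl] - mean[sl])


def _multistart_least_squares(residual_fn, starts, bounds):
    """Run bounded trust-region least squares from several starts and keep
    the best iterate (returned even when no start reports convergence)."""
    best = None
    converged = False
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            res = least_squares(residual_fn, x0, bounds=bounds, method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        converged = converged or bool(res.success)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best, converged


def fit_rate_capacity(
    dataset: GrowthDataset,
    model_mode: str = "single_phase_off",
    weight_mode: str = "inv_var",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Weighted NLS for (lambda, kappa) with N(0) fixed to the mean of the
    first sample.

    ``model_mode`` labels which phase the constants describe
    (``single_phase_off`` for a never-activated culture -> lambda0/kappa0;
    ``single_phase_on`` for a culture induced at t = 0 -> lambda1/kappa1);
    the fitted model is the constant-parameter discrete-time logistic either
    way, which coincides with the closed form at the sample times.
    """
    if model_mode not in ("single_phase_off", "single_phase_on"):
        raise ValueError(f"unknown model_mode {model_mode!r}")
    if dataset.n_times < 3:
        raise ValueError("need at least 3 time points to fit (lambda, kappa)")
    mean, _, weights = summarize_replicates(dataset)
    n0_fixed = dataset.first_density()
    times = dataset.times

    def residual(x):
        lam, ln_kap = x
        model = logistic_closed_form(n0_fixed, lam, np.exp(ln_kap), times)
        return _weighted_residuals(model, mean, weights, weight_mode)

    kap_lo = max(10.0 * n0_fixed, 1.0)
    bounds = (
        np.array([_LAMBDA_BOUNDS[0], np.log(kap_lo)]),
        np.array([_LAMBDA_BOUNDS[1], np.log(_KAPPA_MAX)]),
    )
    lam_guess = fit_exponential_rate(dataset, n_points=min(6, dataset.n_times))
    starts = [np.array([np.clip(lam_guess, *_LAMBDA_BOUNDS), np.log(max(mean.max(), kap_lo))])]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        lam0 = np.exp(rng.uniform(np.log(0.05), np.log(2.5)))
        kap0 = np.exp(rng.uniform(np.log(max(kap_lo, mean.max() / 10)), np.log(1e10)))
        starts.append(np.array([lam0, np.log(kap0)]))

    best, converged = _multistart_least_squares(residual, starts, bounds)
    lam_hat, kap_hat = best.x[0], float(np.exp(best.x[1]))
    res_series = residual(best.x)
    return FitResult(
        estimates={"lambda": float(lam_hat), "kappa": kap_hat},
        fixed={"n0": n0_fixed},
        wssr=float(np.sum(res_series**2)),
        n_points=len(res_series),
        converged=converged,
        residual_series=res_series,
        label=model_mode,
    )


def fit_exponential_rate(dataset: GrowthDataset, n_points: int = 6) -> float:
    """Early-phase exponential growth rate: OLS slope of ln(mean density)
    against time over the first ``n_points`` samples."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if dataset.n_times < n_points:
        raise ValueError(f"dataset has {dataset.n_times} points, need {n_points}")
    t = dataset.times[:n_points]
    y = np.log(dataset.mean_series()[:n_points])
    slope = np.polyfit(t, y, 1)[0]
    return float(slope)


def fit_logistic_rk(dataset: GrowthDataset, n_starts: int = 3, seed: int = 0) -> FitResult:
    """Unweighted NLS of the plain logistic closed form over (N(0), r, k)
    against the replicate-mean series — the descriptive convention for
    comparing growth rate and capacity between conditions, distinct from the
    weighted fixed-N(0) calibration.

    A series that sits at carrying capacity throughout leaves r
    unidentifiable; the fit then reports k at the data level with
    ``converged=False``.
    """
    if dataset.n_times < 4:
        raise ValueError("need at least 4 time points")
    mean = dataset.mean_series()
    level = mean.mean()
    if (mean.max() - mean.min()) < 1e-9 * level:
        return FitResult(
            estimates={"n0": float(mean[0]), "r": 0.0, "kappa": float(level)},
            fixed={},
            wssr=float(np.sum((mean - level) ** 2)),
            n_points=dataset.n_times,
            converged=False,
            residual_series=mean - level,
            label="logistic_rk",
        )

    times = dataset.times

    def residual(x):
        ln_n0, r, ln_k = x
        return logistic_closed_form(np.exp(ln_n0), r, np.exp(ln_k), times) - mean

    bounds = (
        np.array([np.log(mean.min() / 100.0), 1e-4, np.log(mean.min())]),
        np.array([np.log(mean.max() * 10.0), 5.0, np.log(1e12)]),
    )
    lam_guess = np.clip(fit_exponential_rate(dataset, min(6, dataset.n_times)), 1e-3, 4.9)
    starts = [np.array([np.log(mean[0]), lam_guess, np.log(mean.max())])]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.array(
                [
                    np.log(mean[0] * rng.uniform(0.3, 3.0)),
                    np.exp(rng.uniform(np.log(0.05), np.log(2.5))),
                    np.log(mean.max() * rng.uniform(0.8, 5.0)),
                ]
            )
        )
    best, converged = _multistart_least_squares(residual, starts, bounds)
    n0_hat, r_hat, k_hat = np.exp(best.x[0]), best.x[1], np.exp(best.x[2])
    res_series = residual(best.x)
    return FitResult(
        estimates={"n0": float(n0_hat), "r": float(r_hat), "kappa": float(k_hat)},
        fixed={},
        wssr=float(np.sum(res_series**2)),
        n_points=dataset.n_times,
        converged=converged,
        residual_series=res_series,
        label="logistic_rk",
    )


def _uniform_grid(times: np.ndarray) -> None:
    diffs = np.diff(times)
    if abs(times[0]) > 1e-9 or not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
        raise ValueError("discrete-time fitting requires a uniform time grid starting at 0")


def fit_delay(
    dataset: GrowthDataset,
    t_i: float,
    params: GrowthParams,
    weight_mode: str = "inv_var",
    n_starts: int = 5,
    seed: int = 0,
    flat_tol: float = 0.02,
) -> FitResult:
    """Joint weighted NLS over (N(0), D >= 0) for an externally induced
    culture, with the four growth constants held fixed.

    The model is the discrete-time switched logistic on the data's own grid;
    the joint optimization is well behaved here because the transient/
    stationary imbalance of the objective disappears once (lambda, kappa)
    are fixed.

    When activation happens at low density the trajectory is insensitive to
    D and the objective is a plateau rather than a minimum; two safeguards
    apply.  First, if removing the delay entirely (D = 0, N(0)
    re-optimized) changes the cost by less than ``flat_tol`` relative —
    i.e. the delay explains essentially nothing — D = 0 is reported.
    Second, the returned result carries a linearized standard error for the
    delay (``uncertainty["delay"]``) and the re-optimized cost ratio of the
    latency-free model (``uncertainty["zero_cost_ratio"]``); downstream
    summaries such as :func:`fit_delay_function` can use them to downweight
    or zero out arms whose latency is not statistically supported.
    """
    _uniform_grid(dataset.times)
    mean, _, weights = summarize_replicates(dataset)
    times = dataset.times
    schedule = ControlSchedule.external(t_i)
    first = dataset.first_density()

    def model_series(n0, delay):
        traj = _propagate_grid(params, schedule, DelayFunction.constant(delay), n0, times)
        return traj.density

    def residual(x):
        ln_n0, delay = x
        return _weighted_residuals(model_series(np.exp(ln_n0), delay), mean, weights, weight_mode)

    bounds = (
        np.array([np.log(first / 30.0), _DELAY_BOUNDS[0]]),
        np.array([np.log(first * 30.0), _DELAY_BOUNDS[1]]),
    )
    starts = [np.array([np.log(first), d]) for d in (0.1, 1.0, 3.0, 6.0, 12.0)][:n_starts]
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(
            np.array([np.log(first * rng.uniform(0.5, 2.0)), rng.uniform(*_DELAY_BOUNDS)])
        )
    best, converged = _multistart_least_squares(residual, starts, bounds)
    n0_hat, d_hat = float(np.exp(best.x[0])), float(best.x[1])

    # linearized SE of the delay from the Jacobian at the optimum; diverges
    # when the objective is flat in D
    delay_se = np.inf
    try:
        jtj = best.jac.T @ best.jac
        dof = max(1, len(best.fun) - 2)
        cov = (2.0 * best.cost / dof) * np.linalg.inv(jtj)
        if cov[1, 1] > 0:
            delay_se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        pass

    # zero-latency comparison (see docstring): re-optimized cost at D = 0
    zero_ratio = 1.0
    if d_hat > 0.0:
        best_cost = float(np.sum(residual(best.x) ** 2))
        res_d0 = least_squares(
            lambda z: residual(np.array([z[0], 0.0])),
            np.array([best.x[0]]),
            bounds=(bounds[0][:1], bounds[1][:1]),
            method="trf",
        )
        # least_squares cost is 0.5 * SSR
        zero_cost = 2.0 * res_d0.cost
        zero_ratio = float(zero_cost / best_cost) if best_cost > 0 else 1.0
        if zero_cost <= best_cost * (1.0 + flat_tol) + 1e-300:
            n0_hat, d_hat = float(np.exp(res_d0.x[0])), 0.0
            zero_ratio = 1.0

    res_series = residual(np.array([np.log(n0_hat), d_hat]))
    traj = _propagate_grid(params, schedule, DelayFunction.constant(d_hat), n0_hat, times)
    estimates = {"n0": n0_hat, "delay": d_hat}
    return FitResult(
        estimates=estimates,
        fixed={
            "lambda0": params.lambda0,
            "lambda1": params.lambda1,
            "kappa0": params.kappa0,
            "kappa1": params.kappa1,
            "t_induction": float(t_i),
            "activation_density": float(traj.activation_density),
        },
        wssr=float(np.sum(res_series**2)),
        n_points=len(res_series),
        converged=converged,
        residual_series=res_series,
        label=f"delay_t{t_i:g}",
        uncertainty={"delay": delay_se, "zero_cost_ratio": zero_ratio},
    )


@dataclass(frozen=True)
class ThresholdScan:
    """Result of the quorum-sensing threshold grid scan."""

    alpha_star: float
    alpha_grid: np.ndarray
    wssr_curve: np.ndarray

    def __iter__(self):
        # allows ``alpha_star, wssr_curve = scan`` unpacking
        yield self.alpha_star
        yield self.wssr_curve


def default_alpha_grid(num: int = 60, lo: float = 1e5, hi: float = 1e9) -> np.ndarray:
    """Deterministic log-spaced threshold grid (CFU/mL)."""
    return np.geomspace(lo, hi, num)


def fit_threshold(
    qs_dataset: GrowthDataset,
    params: GrowthParams,
    delay_fn: DelayFunction,
    alpha_grid,
    weight_mode: str = "inv_var",
) -> ThresholdScan:
    """Grid scan of the activation threshold alpha against a QS culture.

    For each candidate alpha the QS model is simulated from the fixed N(0)
    (mean of the first sample) with the continuous-time integrator — the
    activation time varies continuously with alpha, so the weighted SSR
    discriminates between neighboring candidates even on noiseless data.
    Ties are broken toward the smaller alpha.  Pass
    ``DelayFunction.zero()`` to scan the no-latency indicator model.
    """
    grid = np.asarray(alpha_grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValueError("alpha_grid must be a nonempty 1-D array")
    if np.any(grid <= 0):
        raise ValueError("alpha_grid must be positive")
    if np.any(np.diff(grid) < 0):
        raise ValueError("alpha_grid must be sorted ascending")
    n0 = qs_dataset.first_density()
    times = qs_dataset.times
    wssr_curve = np.empty(len(grid))
    for i, alpha in enumerate(grid):
        traj = simulate(params, ControlSchedule.qs(alpha), delay_fn, n0, times)
        wssr_curve[i] = weighted_ssr(traj.density, qs_dataset, weight_mode)
    idx = int(np.argmin(wssr_curve))  # first minimum = smallest alpha on ties
    return ThresholdScan(float(grid[idx]), grid, wssr_curve)


def fit_delay_function(
    points: Sequence[tuple[float, float]],
    weights: Optional[Sequence[float]] = None,
) -> DelayFunction:
    """Least-squares fit of a two-segment hinge D(N) = s * max(0, N - b) to
    (activation density, delay) pairs; the breakpoint b is searched over the
    data's density range and the slope s is constrained nonnegative.

    ``weights`` (optional, one per point) weight the squared errors — e.g.
    inverse-variance weights from the per-arm delay standard errors, so that
    arms where the latency was unidentifiable do not distort the hinge.

    Observed zero delays anchor the breakpoint: since the hinge is zero at
    and below b, the search range for b starts at the largest density whose
    observed delay is exactly zero (the boundary of the no-delay window).
    Without that anchor b is weakly identified whenever the positive-delay
    points are nearly collinear.

    With all delays zero the trivial zero function is returned, with its
    breakpoint at the largest observed density.
    """
    pts = [(float(d), float(h)) for d, h in points]
    if len(pts) < 2:
        raise ValueError("need at least two (density, delay) points")
    dens = np.array([d for d, _ in pts])
    dels = np.array([h for _, h in pts])
    if np.any(dens <= 0):
        raise ValueError("densities must be positive")
    if np.any(dels < 0):
        raise ValueError("delays must be nonnegative")
    if weights is None:
        wts = np.ones_like(dels)
    else:
        wts = np.asarray(weights, dtype=float)
        if wts.shape != dels.shape or np.any(wts < 0) or not np.any(wts > 0):
            raise ValueError("weights must be nonnegative, one per point, not all zero")
    if np.all(dels[wts > 0] == 0.0) or np.all(dels == 0.0):
        return DelayFunction(((float(dens.max()), 0.0),))

    def slope_for(b):
        x = np.maximum(0.0, dens - b)
        sxx = np.sum(wts * x * x)
        if sxx == 0.0:
            return 0.0
        return max(0.0, float(np.sum(wts * x * dels) / sxx))

    def ssr(b):
        s = slope_for(b)
        return float(np.sum(wts * (s * np.maximum(0.0, dens - b) - dels) ** 2))

    hi = float(dens.max())
    anchored = dens[(dels == 0.0) & (wts > 0) & (dens < hi)]
    lo = float(anchored.max()) if len(anchored) else float(dens.min())
    candidates = np.unique(np.concatenate([np.geomspace(lo, hi, 512), dens[dens >= lo]]))
    ssr_values = np.array([ssr(b) for b in candidates])
    k = int(np.argmin(ssr_values))
    b_lo = candidates[max(0, k - 1)]
    b_hi = candidates[min(len(candidates) - 1, k + 1)]
    if b_hi > b_lo:
        res = minimize_scalar(ssr, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-9 * hi})
        b_star = float(res.x) if res.fun <= ssr_values[k] else float(candidates[k])
    else:
        b_star = float(candidates[k])
    s_star = slope_for(b_star)
    if s_star == 0.0 or b_star >= hi:
        return DelayFunction(((hi, 0.0),))
    return DelayFunction(((b_star, 0.0), (hi, s_star * (hi - b_star))))
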