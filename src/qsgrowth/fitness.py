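"""Relative fitness of induced versus uninduced cultures.

Relative fitness (RF) is the ratio of the induced culture's density to the
uninduced reference, accumulated over the experiment:

    RF = sum_k N(t_k) / N_off(t_k)        (normalization="sum")
    RF = (1/T) * sum_k N(t_k)/N_off(t_k)  (normalization="mean", default)

The pointwise ratio cancels the orders-of-magnitude sweep of the raw
counts, so every time point contributes on a comparable scale.  With mean
normalization identical curves give RF = 1.  Scanning RF over the induction
time locates the optimum moment to start paying the public-good cost: too
early sacrifices growth rate before the extra capacity is needed, too late
incurs the capacity-gain latency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .model import ControlSchedule, DelayFunction, GrowthParams, simulate
from .fitting import GrowthDataset

__all__ = [
    "FitnessCurve",
    "relative_fitness",
    "replicate_fitness",
    "empirical_fitness_scan",
    "model_fitness_scan",
    "optimal_induction",
]


@dataclass(frozen=True)
class FitnessCurve:
    """Relative fitness as a function of induction time."""

    induction_times: np.ndarray
    rf_values: np.ndarray
    normalization: str = "mean"

    def __post_init__(self) -> None:
        times = np.asarray(self.induction_times, dtype=float)
        rf = np.asarray(self.rf_values, dtype=float)
        if len(times) != len(rf):
            raise ValueError("induction_times and rf_values must have equal length")
        if len(times) == 0:
            raise ValueError("curve must be nonempty")
        if np.any(rf <= 0):
            raise ValueError("rf_values must be positive")
        object.__setattr__(self, "induction_times", times)
        object.__setattr__(self, "rf_values", rf)

    @property
    def t_opt(self) -> float:
        """Induction time maximizing RF; ties go to the earliest time."""
        order = np.argsort(self.induction_times, kind="stable")
        rf = self.rf_values[order]
        return float(self.induction_times[order][int(np.argmax(rf))])


def _check_series(induced, reference):
    induced = np.asarray(induced, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if induced.shape != reference.shape or induced.ndim != 1:
        raise ValueError("induced and reference must be equal-length 1-D series")
    if np.any(reference <= 0):
        raise ValueError("reference densities must be positive")
    if np.any(induced <= 0):
        raise ValueError("induced densities must be positive")
    return induced, reference


def relative_fitness(induced, reference, normalization: str = "mean") -> float:
    """Accumulated density ratio of an induced series over a reference
    series sharing its time grid.  Scale-invariant: rescaling both series by
    a common factor leaves RF unchanged."""
    induced, reference = _check_series(induced, reference)
    total = float(np.sum(induced / reference))
    if normalization == "mean":
        return total / len(induced)
    if normalization == "sum":
        return total
    raise ValueError(f"unknown normalization {normalization!r}")


def replicate_fitness(
    dataset: GrowthDataset, reference: GrowthDataset, normalization: str = "mean"
) -> np.ndarray:
    """Diagnostic: RF of each replicate against the reference's replicate
    mean (the headline RF uses replicate means on both sides)."""
    ref = reference.mean_series()
    return np.array(
        [relative_fitness(row, ref, normalization) for row in dataset.counts]
    )


def empirical_fitness_scan(
    datasets: Mapping[float, GrowthDataset],
    reference: GrowthDataset,
    normalization: str = "mean",
) -> FitnessCurve:
    """RF of each induced culture's replicate-mean series against the
    uninduced reference, one value per induction time."""
    if len(datasets) == 0:
        raise ValueError("datasets must be nonempty")
    ref_mean = reference.mean_series()
    times = sorted(float(t) for t in datasets)
    rf = []
    for t_i in times:
        ds = datasets[t_i]
        if ds.n_times != reference.n_times or not np.allclose(ds.times, reference.times):
            raise ValueError(f"dataset at t_i={t_i} does not share the reference time grid")
        rf.append(relative_fitness(ds.mean_series(), ref_mean, normalization))
    return FitnessCurve(np.array(times), np.array(rf), normalization)


def model_fitness_scan(
    params: GrowthParams,
    delay_fn: DelayFunction,
    n0: float,
    induction_times,
    horizon: float = 24.0,
    dt: float = 1.0,
    normalization: str = "mean",
    method: str = "piecewise_closed_form",
) -> FitnessCurve:
    """Theoretical fitness curve from the calibrated model: one simulated
    trajectory per induction time against a never-activated trajectory, all
    from the same N(0).  Deterministic for fixed inputs."""
    induction_times = np.asarray(induction_times, dtype=float)
    if len(induction_times) == 0:
        raise ValueError("induction_times must be nonempty")
    if horizon <= induction_times.max():
        raise ValueError("horizon must exceed the largest induction time")
    grid = np.arange(int(round(horizon / dt)) + 1) * dt
    ref = simulate(params, ControlSchedule.never(), delay_fn, n0, grid, method)
    rf = []
    for t_i in induction_times:
        traj = simulate(params, ControlSchedule.external(t_i), delay_fn, n0, grid, method)
        rf.append(relative_fitness(traj.density, ref.density, normalization))
    order = np.argsort(induction_times)
    return FitnessCurve(induction_times[order], np.array(rf)[order], normalization)


def optimal_induction(curve: FitnessCurve) -> float:
    """The induction time maximizing relative fitness (earliest on ties)."""
    return curve.t_opt
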