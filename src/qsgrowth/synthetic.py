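"""Synthetic replicate growth experiments with plate-count noise structure.

The generator emulates the design of a 24-h induction-time experiment:
triplicate hourly CFU/mL counts (25 samples, 0..24 h) for a panel of
conditions — never induced, externally induced at a set of times, and a
quorum-sensing strain — all sharing one inoculum.  Counts span ~1e5 to
~1e9 CFU/mL, so measurement error is modeled as multiplicative: each count
is the noiseless model trajectory times an independent lognormal multiplier
with median 1 and a chosen coefficient of variation, the standard
dispersion structure of serial-dilution plate counts.

Default scenario constants (growth rates 0.9/0.45 1/h, capacities
1.2e8/8e8 CFU/mL, a hinge latency breaking at 1e7 CFU/mL, inoculum 1e6,
CV 0.10) are implementation defaults chosen to exercise the same dynamic
range as real amylase-sharing cultures; they are defaults, not measured
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fitting import GrowthDataset
from .model import ControlSchedule, DelayFunction, GrowthParams, simulate

__all__ = [
    "ExperimentScenario",
    "default_scenario",
    "fig_style_induction_conditions",
    "off_on_qs_conditions",
    "generate_dataset",
    "generate_experiment",
]

#: Default hinge: no latency up to 1e7 CFU/mL, rising to 5 h at 1e8 CFU/mL.
DEFAULT_DELAY_FN = DelayFunction.hinge(1e7, 5.0 / 9e7)

DEFAULT_PARAMS = GrowthParams(lambda0=0.9, lambda1=0.45, kappa0=1.2e8, kappa1=8e8)

#: Default QS threshold for synthetic quorum-sensing conditions (CFU/mL).
DEFAULT_QS_ALPHA = 5e7


def fig_style_induction_conditions(
    induction_times=(0.0, 3.0, 5.0, 8.0, 12.0),
) -> tuple[tuple[str, ControlSchedule], ...]:
    """Externally induced cultures at each induction time plus an uninduced
    control — the induction-time experimental design."""
    conds = tuple(
        (f"induced_{t_i:g}h", ControlSchedule.external(t_i)) for t_i in induction_times
    )
    return conds + (("uninduced", ControlSchedule.never()),)


def off_on_qs_conditions(alpha: float = DEFAULT_QS_ALPHA) -> tuple[tuple[str, ControlSchedule], ...]:
    """The three regulatory strategies: OFF (never produces), ON (induced at
    t = 0) and QS (density-triggered at ``alpha``)."""
    return (
        ("OFF", ControlSchedule.never()),
        ("ON", ControlSchedule.external(0.0)),
        ("QS", ControlSchedule.qs(alpha)),
    )


@dataclass(frozen=True)
class ExperimentScenario:
    """Everything needed to generate one synthetic experiment."""

    params: GrowthParams = DEFAULT_PARAMS
    delay_fn: DelayFunction = DEFAULT_DELAY_FN
    n0: float = 1e6
    times: np.ndarray = field(default_factory=lambda: np.arange(25.0))
    n_replicates: int = 3
    noise_cv: float = 0.10
    conditions: tuple = field(default_factory=fig_style_induction_conditions)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")


def default_scenario(seed: int = 0, **overrides) -> ExperimentScenario:
    return ExperimentScenario(seed=seed, **overrides)


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Median-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_dataset(
    scenario: ExperimentScenario,
    schedule: ControlSchedule,
    label: str = "",
    rng: Optional[np.random.Generator] = None,
) -> GrowthDataset:
    """One condition's replicate counts: the noiseless continuous-model
    trajectory times independent lognormal multipliers per replicate and
    time point.  Reproducible: with ``rng=None`` the stream is seeded from
    ``scenario.seed``."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    traj = simulate(scenario.params, schedule, scenario.delay_fn, scenario.n0, scenario.times)
    mult = _lognormal_multipliers(
        rng, scenario.noise_cv, (scenario.n_replicates, len(scenario.times))
    )
    counts = traj.density[None, :] * mult
    induction_time = schedule.t_induction if schedule.mode == "external" else None
    return GrowthDataset(
        times=scenario.times, counts=counts, label=label, induction_time=induction_time
    )


def generate_experiment(scenario: ExperimentScenario) -> dict[str, GrowthDataset]:
    """One dataset per scenario condition, all sharing the inoculum and the
    time grid, with independent noise drawn from a single seeded stream."""
    if len(scenario.conditions) == 0:
        raise ValueError("scenario.conditions must be nonempty")
    labels = [label for label, _ in scenario.conditions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    rng = np.random.default_rng(scenario.seed)
    return {
        label: generate_dataset(scenario, schedule, label=label, rng=rng)
        for label, schedule in scenario.conditions
    }
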