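import numpy as np
import pytest

from qsgrowth import DelayFunction, GrowthParams


@pytest.fixture
def params():
    """Default switched constants: costly activation, higher capacity."""
    return GrowthParams(lambda0=0.9, lambda1=0.45, kappa0=1.2e8, kappa1=8e8)


@pytest.fixture
def hinge_delay():
    """No latency up to 1e7 CFU/mL, ~5 h latency at 1e8 CFU/mL."""
    return DelayFunction.hinge(1e7, 5.0 / 9e7)


@pytest.fixture
def zero_delay():
    return DelayFunction.zero()


@pytest.fixture
def hourly():
    """Hourly sampling over 24 h (25 samples)."""
    return np.arange(25.0)


def random_scenario(rng):
    """A random switched-growth scenario in the plate-count regime."""
    from qsgrowth import ControlSchedule

    lam0 = rng.uniform(0.3, 1.5)
    lam1 = rng.uniform(0.1, lam0)
    kap0 = np.exp(rng.uniform(np.log(1e7), np.log(5e8)))
    kap1 = kap0 * rng.uniform(1.5, 8.0)
    p = GrowthParams(lam0, lam1, kap0, kap1)
    n0 = np.exp(rng.uniform(np.log(1e4), np.log(1e6)))
    n_break = np.exp(rng.uniform(np.log(5e6), np.log(5e7)))
    slope = rng.uniform(0.0, 8.0) / kap0
    delay_fn = DelayFunction.hinge(n_break, slope)
    mode = rng.choice(["never", "external", "qs"])
    if mode == "external":
        schedule = ControlSchedule.external(rng.uniform(0.0, 12.0))
    elif mode == "qs":
        schedule = ControlSchedule.qs(np.exp(rng.uniform(np.log(1e6), np.log(2e8))))
    else:
        schedule = ControlSchedule.never()
    return p, schedule, delay_fn, n0
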