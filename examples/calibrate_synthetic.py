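"""Staged calibration on a synthetic induction-time experiment.

Generates noisy triplicate growth curves (cultures induced at 0, 3, 5, 8
and 12 h plus an uninduced control), then runs the staged fits: (lambda,
kappa) on the uninduced and t = 0 cultures with N(0) fixed to the first
sample, and a joint (N(0), D) fit of the capacity-gain latency for each
later induction time.  Prints estimates next to the generating values.
"""

from qsgrowth import (
    GrowthParams,
    default_scenario,
    fit_delay,
    fit_rate_capacity,
    generate_experiment,
)
from qsgrowth.synthetic import DEFAULT_DELAY_FN

scenario = default_scenario(seed=42)
datasets = generate_experiment(scenario)
truth = scenario.params

off = fit_rate_capacity(datasets["uninduced"], "single_phase_off")
on = fit_rate_capacity(datasets["induced_0h"], "single_phase_on", seed=1)
print("growth constants (estimate | generating value):")
print(f"  lambda0 {off.estimates['lambda']:.3f} 1/h | {truth.lambda0}")
print(f"  kappa0  {off.estimates['kappa']:.3g} CFU/mL | {truth.kappa0:.3g}")
print(f"  lambda1 {on.estimates['lambda']:.3f} 1/h | {truth.lambda1}")
print(f"  kappa1  {on.estimates['kappa']:.3g} CFU/mL | {truth.kappa1:.3g}")

params_hat = GrowthParams(
    off.estimates["lambda"], on.estimates["lambda"],
    off.estimates["kappa"], on.estimates["kappa"],
)
print("\ncapacity-gain latency per induction time (estimate | generating):")
for t_i in (3.0, 5.0, 8.0, 12.0):
    fit = fit_delay(datasets[f"induced_{t_i:g}h"], t_i, params_hat, seed=int(t_i))
    true_d = DEFAULT_DELAY_FN(fit.fixed["activation_density"])
    print(
        f"  t_i = {t_i:>4} h: D = {fit.estimates['delay']:.2f} h"
        f" (se {fit.uncertainty['delay']:.2f}) | {true_d:.2f} h"
        f"  [activation at {fit.fixed['activation_density']:.3g} CFU/mL]"
    )

print(
    "\nLater induction means activation at higher density, hence a longer"
    "\nwait before the higher carrying capacity is realized.  At low"
    "\nactivation densities (t_i = 3 h here) the trajectory barely depends on"
    "\nD, so that estimate is noise — compare its standard error and the"
    "\nzero-latency cost ratio in FitResult.uncertainty before trusting it."
)
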