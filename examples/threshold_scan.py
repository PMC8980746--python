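"""Estimate the quorum-sensing activation threshold from a QS growth curve.

Generates a noisy QS culture (activation when the density crosses
5e7 CFU/mL), then scans candidate thresholds alpha over a log-spaced grid,
simulating the QS model for each and scoring it by the weighted sum of
squared residuals against the data.  The minimizer is the estimated
threshold.
"""

import numpy as np

from qsgrowth import (
    ControlSchedule,
    default_alpha_grid,
    default_scenario,
    fit_threshold,
    generate_dataset,
)

scenario = default_scenario(seed=7)
alpha_true = 5e7
dataset = generate_dataset(scenario, ControlSchedule.qs(alpha_true), label="QS")

grid = default_alpha_grid()  # 60 log-spaced points, 1e5..1e9 CFU/mL
scan = fit_threshold(dataset, scenario.params, scenario.delay_fn, grid)

print(f"true threshold      : {alpha_true:.3g} CFU/mL")
print(f"estimated threshold : {scan.alpha_star:.3g} CFU/mL")
print(f"WSSR at the optimum : {scan.wssr_curve.min():.3g}")
k = int(np.argmin(scan.wssr_curve))
lo, hi = max(0, k - 2), min(len(grid), k + 3)
print("residual curve near the optimum (alpha, WSSR):")
for a, w in zip(scan.alpha_grid[lo:hi], scan.wssr_curve[lo:hi]):
    print(f"  {a:10.3g}  {w:10.3g}")

print(
    "\nCandidate thresholds that fire too early or too late mistime the"
    "\ngrowth-rate switch and miss the observed curve; at 10% count noise the"
    "\ndip is shallow, so neighboring grid points trade places between"
    "\nreplicate experiments (the scan is typically within a grid step or two"
    "\nof the generating threshold)."
)
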