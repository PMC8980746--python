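# qsgrowth

Switched-parameter logistic growth under quorum-sensing control: simulate,
calibrate, and find the optimal time to start producing a costly public
good.

## The problem

Many bacteria secrete "public goods" — e.g. an α-amylase that digests
extracellular starch into sugars every cell can use. Production is
beneficial (more accessible nutrients ⇒ a higher carrying capacity) but
costly (a lower intrinsic growth rate), and the benefit is not immediate:
if production starts when the population is already large, there is a
latency before the extra capacity is realized. Quorum sensing — switching
production on when the cell density crosses a threshold — is a policy for
timing this investment. This package is for quantitative microbiologists
and modelers who want to fit that trade-off to plate-count growth curves
(CFU/mL vs. time) and locate the induction time / density that maximizes
population fitness.

## The model

Density N(t) follows a logistic law whose constants switch on activation
of public-good production:

    dN/dt = λ(t) N (1 − N/κ(t))

    λ(t) = λ₀ before activation, λ₁ after          (λ₁ ≤ λ₀: cost)
    κ(t) = κ₀                      t < tᵢ
         = κ₀ + (κ₁−κ₀)(t−tᵢ)/D    tᵢ ≤ t ≤ tᵢ+D   (linear ramp)
         = κ₁                      t > tᵢ+D        (κ₁ ≥ κ₀: benefit)

where tᵢ is the activation time and the latency D = D(N(tᵢ)) is a
nondecreasing piecewise-linear (hinge) function of the density at
activation — zero below a breakpoint (the "no-delay window"). Activation
is `never`, `external` at a chosen tᵢ, or quorum-sensing: the first time
N ≥ α. Calibration is staged weighted least squares: (λ, κ) per phase with
N(0) fixed to the first sample's mean, then per-induction-time (N(0), D)
fits, a hinge fit of D(N), and a grid scan for α. Fitness of a timing
policy is the relative fitness

    RF = (1/T) Σₖ N(tₖ) / N_off(tₖ)

— the time-averaged density ratio of induced to uninduced cultures; the
optimal induction time maximizes RF. See `docs/methods.md` for details.

## Worked example

`examples/fitness_scan.py` generates a noisy synthetic induction-time
experiment (triplicate hourly counts, cultures induced at 0, 3, 5, 8 and
12 h plus an uninduced control) and scans relative fitness:

```
induction time (h) | empirical RF | model RF
                 0 |         2.59 |     2.69
                 3 |         3.45 |     3.52
                 5 |         3.77 |     3.78
                 8 |         3.17 |     3.24
                12 |         2.30 |     2.34

optimal induction time: empirical 5 h, model 5 h
```

Every induced culture beats the control (RF > 1) because the enzyme
raises the carrying capacity ~6.7-fold, but the curve is unimodal:
inducing at t = 0 pays the growth-rate cost long before the extra
capacity is needed, while inducing at 12 h activates a dense culture and
incurs a multi-hour capacity latency. The optimum (5 h, RF ≈ 3.8) falls
where the activation density still sits inside the no-delay window.

The other examples cover the remaining capabilities: simulating the
OFF/ON/QS strategies (`simulate_strategies.py`), the staged calibration
(`calibrate_synthetic.py`) and the quorum-threshold scan
(`threshold_scan.py`). A thin CLI wraps the same pipeline
(`qsgrowth synth|simulate|fit-growth|fit-delays|fit-threshold|fitness|run-all`);
see `qsgrowth --help`.

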