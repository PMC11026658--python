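# blt-learning

Rescorla–Wagner modelling of continuous and binary prediction data from the
Breathing Learning Task (BLT), a probabilistic interoceptive
reversal-learning paradigm.

## The problem

In the BLT, one of two visual cues is shown on each of 80 trials and an
inspiratory breathing resistance either follows (probability 0.8 for one
cue, 0.2 for the other) or does not.  The cue–resistance pairing reverses
four times during the session (after trial 30, then every 12–13 trials).
Participants rate, on a continuous slider from "definitely no resistance"
(0.0) to "definitely resistance" (1.0), how strongly they expect the
resistance — so each response carries both a prediction and the
participant's certainty in it.

This package implements the complete modelling framework for such data, for
researchers in computational psychiatry and interoception who want to
estimate individual learning rates from bounded continuous (or binarised)
prediction trajectories and validate those estimates by simulation:

- **Task module** — generation and encoding of the trial schedule, including
  the "contingency space" recoding that maps both cues onto a single
  outcome axis `o_t` (1 iff cue 1 → resistance or cue 2 → no resistance).
- **Learning model** — Rescorla–Wagner belief updating,
  `v_{t+1} = v_t + α δ_t` with `δ_t = o_t − v_t` and `v_0 = 0.5`, plus a
  dual-learning-rate variant that uses `α_p` on no-resistance
  (positive-valence) trials and `α_n` on resistance (negative-valence)
  trials.
- **Observation models** — a softmax
  `p(y_t=1) = e^{βv_t} / (e^{βv_t} + e^{β(1−v_t)})` for binarised
  responses, and a beta likelihood in the mean–dispersion parameterisation
  `y_t ~ Beta(μ_t φ, (1−μ_t) φ)` with `μ_t = v_t` for continuous responses,
  where the dispersion φ is a single group-level parameter (higher φ =
  less response noise).
- **Inference** — maximum a posteriori estimation (single-start L-BFGS-B)
  under Gaussian priors in native space (α: mean 0.34, variance 0.88,
  bounded [0, 1]; β: mean 4.21, variance 1.75), no-learning null models
  (α = 0, `v_t ≡ 0.5`), and model comparison via
  `BIC/AIC = −2 ln L̂ + cκ` and Bayes factors.
- **Validation** — simulation and parameter-recovery experiments (truncated
  normal learning rates, softmax decision noise or clipped Gaussian
  response noise, Fisher-z-averaged recovery correlations), plus behavioural
  analyses: per-trial proportion correct, certainty scores, group-trajectory
  validation and exploratory Spearman correlation matrices against
  questionnaire scores.
- **Synthetic data** — a generator for complete synthetic studies
  (responses on the raw 0–10 slider scale, questionnaire-like scores with
  controllable rank correlation to behaviour, ground-truth records), so the
  whole pipeline runs end to end without any empirical data.

## Worked example

```python
import numpy as np
from blt import (build_schedule, draw_alpha, simulate_continuous,
                 fit_continuous, fit_null, bayes_factor)

schedule = build_schedule()            # 80 trials, 80/20, four reversals
alpha = draw_alpha(16, seed=7)         # truncated-normal learning rates
y = simulate_continuous(alpha, sigma=0.1, schedule=schedule, seed=7)

fit = fit_continuous(y, schedule)      # joint MAP: 16 alphas + shared phi
null = fit_null(y, schedule, "continuous")
print("recovery r  :", np.corrcoef(alpha, fit.estimates["alpha"])[0, 1])
print("phi         :", fit.estimates["phi"])
print("BIC fit/null:", fit.bic, null.bic)
print("Bayes factor:", bayes_factor(null.bic, fit.bic))
```

prints

```
recovery r  : 0.9883858012021237
phi         : 6.943906632949908
BIC fit/null: -2801.1928931574084 -1108.823592716354
Bayes factor: inf
```

The learning rates recover almost perfectly at this noise level (r ≈ 0.99).
The fitted group dispersion φ ≈ 6.9 reflects both the injected σ = 0.1
noise and the boundary pile-up from the fast learners in this particular
draw (several simulated α above 0.8 push predictions — and hence clipped
noisy responses — against 0 and 1, which a beta likelihood accommodates by
lowering φ).  The learning model beats the no-learning null by ~1700 BIC
points, a Bayes factor beyond float range (reported as `inf`).

The same operations are available from a thin CLI:

```bash
blt simulate-schedule --seed 1 --out schedule.csv
blt synth --seed 1 --out study/
blt fit --model continuous --responses study/responses.csv \
        --schedule study/schedule.csv --out fits.json
blt recover --model binary --noise 8,4,2,1 --runs 10 --subjects 500 \
        --seed 1 --out recovery.json
```

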