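# Methods

## Task model and contingency space

The task is an 80-trial probabilistic cue–outcome learning session with
coupled contingencies: cue A predicts the inspiratory-resistance stimulus
with probability `p_high = 0.8` exactly when cue B predicts it with
`1 − p_high`, and the pairing reverses between blocks.  The default block
partition is 30 / 13 / 12 / 13 / 12 trials (four reversals); this is the
only partition consistent with an initial 30-trial association phase
followed by reversals every 12–13 trials over the remaining 50.  Because
the contingencies are coupled (and participants are told so), every trial
is recoded onto a single axis: `o_t = 1` iff cue 1 was followed by
resistance or cue 2 by no resistance.  The coding is label-symmetric —
swapping cue labels and complementing `o` (and reflecting predictions
`y → 1 − y`) leaves every likelihood unchanged, which the test suite
verifies.

Two schedule realizations are offered.  `exact_proportion` (default) fixes
the number of contingency-consistent outcomes in each block at
`round(p · block length)`, so simulated studies share identical outcome
frequencies across seeds; `bernoulli` draws each trial independently.  Cue
order is balanced within block and uniformly shuffled; cue order and the
counterbalancing of initial pairings are metadata only — the models consume
`o_t` (and the valence `s_t` = resistance indicator) exclusively.

## Learning and observation models

Beliefs update by the Rescorla–Wagner rule `v_{t+1} = v_t + α δ_t`,
`δ_t = o_t − v_t`, `v_0 = 0.5` (fixed: complete initial uncertainty).  The
dual-rate variant applies `α_p` when `s_t = 0` (no resistance, positive
valence) and `α_n` when `s_t = 1`; with `α_p = α_n` it is identical to the
single-rate model, giving a proper nesting.

Binarised responses are modelled with a softmax of the belief,
`p = logistic(β(2v − 1))`, computed in log-space (`log_expit`) so β up to
10³ cannot overflow.  Continuous slider responses are modelled as beta
distributed around the belief in the mean–dispersion parameterisation
`a = μφ`, `b = (1 − μ)φ` (mean μ = `v_t`, concentration `a + b = φ`).  φ is
a single scalar shared by all subjects and trials — a group noise
parameter; per-subject dispersions would be straightforward but are not
implemented.

**Boundary policy.**  The beta density is degenerate at 0 and 1, so both
responses and means are clipped to `[ε, 1 − ε]` with ε = 1e−4 before
evaluation (configurable).  Alternatives were examined: treating boundary
responses as missing destroys learning-rate recovery at high noise
(boundary observations are the most informative ones there), and the
Smithson–Verkuilen squeeze performs slightly worse than clipping; larger ε
(1e−2, 5e−2) also degrades recovery.  Responses at exactly 0.5 stay in the
continuous likelihood but become missed trials when binarised (they encode
complete indecision, which the binary model cannot represent).

**Missing trials.**  A missed response drops out of the likelihood, but the
outcome still updates the belief — the stimulus was experienced whether or
not a rating was logged.  A missing *outcome* (not part of the standard
task) carries the belief forward unchanged.

## MAP estimation

Parameters are estimated by maximum a posteriori with Gaussian priors in
native space: α (and each of α_p, α_n) ~ N(0.34, var 0.88) hard-bounded to
[0, 1]; β ~ N(4.21, var 1.75) bounded below by 0.  These prior moments come
from maximum-likelihood fits to a separate eight-participant pilot cohort
of the binary task.  The truncation constant of the bounded Gaussian does
not depend on the parameter and is dropped.  φ has no stated prior; it
carries an improper flat prior on (0, 500], so its estimate is
likelihood-driven, with start value 10 (the single-start-at-prior-mean rule
applies to the parameters that have prior means).

Optimisation is single-start L-BFGS-B from the prior means with analytic
gradients.  Belief-trajectory sensitivities propagate alongside the state
(`dv_{t+1}/dα = (1 − α) dv_t/dα + δ_t`), the softmax gradient is the usual
logistic-residual form, and the beta-likelihood gradients use digamma
functions.  Tolerances: `ftol` 1e−10 (relative), projected-gradient norm
1e−6, which realises roughly 1e−6 absolute accuracy on objectives of
magnitude 10²–10³.  Tests verify the analytic gradients against finite
differences and the optima against dense grid-search oracles.

Per-subject binary fits are block-separable, so all subjects are solved as
one batched L-BFGS-B problem (identical optima, far faster than a Python
loop of scalar solves; the projected-gradient criterion is a max-norm, so
each subject's gradient is individually driven to tolerance).  The
continuous model is a genuinely joint fit: S subject learning rates plus
the shared φ in one (S+1)-dimensional solve (2S+1 for the dual variant).

**Bookkeeping for model comparison.**  `BIC = −2 ln L̂ + κ ln n`,
`AIC = −2 ln L̂ + 2κ`, with n the number of non-missing modelled responses
and κ the free-parameter count: 2 per subject for the binary model (α, β;
3 dual), S + 1 for the continuous group fit (2S + 1 dual).  Null models
clamp α = 0 (`v_t ≡ 0.5`): the binary null's likelihood is exactly
`n ln 0.5` (β drops out of the likelihood; it is counted as the one
formally free parameter per subject and its MAP estimate is the prior
mean), while the continuous null still fits φ by 1-D bounded optimisation
(κ = 1).  Group scores pool summed log-likelihoods, summed κ and pooled n.
Bayes factors are `exp(Δscore/2)`.

## Simulation and parameter recovery

Recovery experiments draw learning rates i.i.d. from
N(0.34, var 0.88) truncated to [0, 1], simulate responses on a shared
standard task schedule, refit with the matching model under the default priors, and
correlate simulated with recovered rates.  Ten runs of 500 subjects are
used per noise level, and per-run Pearson r values are averaged via the
Fisher z-transform.  Binary responses are Bernoulli draws from the softmax
at β ∈ {8, 4, 2, 1}; continuous responses add N(0, σ²) noise at
σ ∈ {0.05, 0.1, 0.2, 0.4} and are clipped to [0, 1].  Clipping (rather
than truncated resampling or reflection) implements the bounding of noisy
responses; the alternatives were tested and collapse recovery entirely
(r ≤ 0.2 at σ = 0.4), because they delete the information carried by
pile-ups at the response boundaries.

**One shared schedule per experiment.**  All runs and noise levels within
an experiment share a single schedule realization (derived from the
experiment seed unless a schedule is passed explicitly), mirroring the task
itself, where one fixed outcome sequence is common to all participants.
The realization matters quantitatively in the high-noise regimes: at
σ = 0.4 the recovery correlation varies by roughly ±0.04 across random
schedule realizations of the same block structure (~0.77–0.88), and the
β = 1 binary correlation by a similar margin, because recovery under heavy
noise leans on exactly where the minority outcomes fall.  The original
task's own outcome sequence is not publicly deposited, so no realization
here is *the* schedule; reference recovery values for this design
(0.90 single-rate and 0.84/0.88 dual at σ = 0.4) sit near the top of the
realization range, and values measured on random realizations run a few
hundredths lower at high noise.  At low-to-moderate noise the realization
is immaterial.

Known recovery phenomena reproduced here: the ceiling effect for recovered
α above ≈0.6 at low decision noise (β = 8), the downward bias of recovered
α at σ = 0.4, and the monotone decrease of the recovered group φ as σ
grows.

Seed management: one master seed spawns an independent
`(seed, noise-index, run)` stream per run, so any run is reproducible in
isolation.  For dual-rate recovery, α_p and α_n are drawn independently
from the same truncated normal.

## Synthetic studies

`generate_study` produces a complete cohort: responses written on the raw
0–10 slider scale in cue-referenced space (so preprocessing genuinely
exercises the contingency mapping), optional uniform missingness, a report
phase echoing the true stimulus with a configurable lapse rate, and
questionnaire-like scores.  Questionnaires are Gaussian with configurable
marginals (defaults are rough healthy-cohort values) and an optional target
Spearman correlation to the subject's true learning rate or realised
certainty, implemented with a Gaussian copula: the latent Pearson
correlation is `2 sin(π ρ_s / 6)`, the learning-rate latent is its
truncated-normal probability transform, and the certainty latent uses
rank-based normal scores.

What the generator does *not* emulate: item-level questionnaire structure,
slider discretisation and motor noise, reaction times, trial timing,
physiological traces, and any systematic response styles (anchoring,
drift).  Passing tests therefore demonstrate correctness of the estimators
under the stated generative assumptions, not robustness to real-world
response artefacts.

## Other numerical and design choices

- Spearman p-values use the t-approximation at all sample sizes (scipy's
  default); exact small-sample enumeration is not implemented.  At the
  cohort sizes this package targets (n ≥ 14) the approximation error is
  negligible relative to the exploratory, uncorrected use of these
  p-values.
- Degenerate group-trajectory validation (a zero-variance modelled series,
  e.g. from a null model) reports r = 0 with a `degenerate` flag rather
  than NaN.
- `fisher_mean_r` nudges |r| = 1 off the pole before `arctanh`.
- Problem sizes in the test suite: unit and property tests run on single
  subjects or cohorts of ≤ 120; the acceptance-style recovery tests run the
  full reference design (10 × 500 per noise level), which completes in a
  few minutes on one CPU thanks to the batched analytic-gradient fits.

## Known limitations

- No hierarchical shrinkage or full posterior uncertainty: MAP point
  estimates only, matching the framework this package implements.
- φ is group-level by design; strong between-subject differences in
  response consistency will be absorbed into the learning-rate estimates.
- The binary model cannot represent indecision; trials at exactly 0.5 are
  lost to it (they remain in the continuous model).
- Empirical cohort-level values (mean learning rates, fitted φ, cohort
  BICs) depend on data that are not publicly deposited and are therefore
  validated only through self-consistency on synthetic cohorts.
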