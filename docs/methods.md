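# Methods

## Task model

Each of six symbols (A–F) yields its pair's *salient* outcome with
probability 0.8 or 0.2 and NOTHING otherwise. Rewards are coded in
dimensionless units: GAIN = +1, LOSE = −1, LOOK = NOTHING = 0 (one unit is
one 20p coin; LOOK shows the coin without awarding it). Expected values are
therefore A: +0.8, B: +0.2, C/D: 0, E: −0.2, F: −0.8.

Outcome sampling is i.i.d. Bernoulli per trial; an `exact_mix_outcomes`
helper provides a fixed 80/20 shuffled outcome list per block for designs
that hold the realised mix exact. Left/right screen position is uniformly
random each trial and has no effect on contingencies; display timing and
response deadlines are not modelled.

**Optimal-response coding** is the strict rank order A > B > C > D > E > F,
evaluated on the symbols shown, never on the realised outcome. Using the
rank order rather than raw expected values encodes two conventions of this
task: Gain symbols beat Look symbols, Look symbols beat Loss symbols, and
within the equal-EV Look pair the 80%-LOOK symbol C counts as the better
choice. Schedules are exact-count: each learning block contains exactly
`trials_per_pair` of each pair, each transfer phase exactly `reps` of each
of the 15 pairings, shuffled per block.

## Reinforcement-learning models

**Q-learning (4 free parameters: α⁺, α⁻, β, β-day2).** All Q start at 0.
On a learning trial with reward r, δ = r − Q(chosen) and Q(chosen) increases
by α⁺δ if δ > 0, else α⁻δ. Choice between the two shown symbols is softmax
over β·Q, with β for day-1 trials and β-day2 for the 24-hour phase. With
rewards in {−1, 0, +1} and α ∈ [0, 1], Q stays in [−1, 1].

**OpAL (6 free parameters: α_G, α_N, β_G, β_N, β_G-day2, β_N-day2).**
Critic: V(chosen) += α_c·δ with δ = r − V(chosen). Actors (initialised at
1): G(chosen) += α_G·G·δ and N(chosen) += α_N·N·(−δ), floored at 1e-6 so the
multiplicative Hebbian update cannot cross zero when |α·δ| > 1. Choice is
softmax over the combined strength β_G·G − β_N·N with phase-appropriate
gains. The critic rate α_c is not counted as a free parameter: it is tied to
(α_G + α_N)/2 by default and configurable to a constant. This keeps the
model at the stated two learning rates + two choice gains (per day) while
retaining a functioning critic; it is a modelling choice the data cannot
strongly constrain at these trial counts.

**Likelihood.** Feedback-free choice trials never update values; values
freeze at the end of learning. By default the likelihood covers day-1
learning trials (180) and the 24-hour phase (90) — the phases the
day-1/day-2 parameter split refers to — for 270 modelled trials per
subject-condition. The 0-min and 30-min phases can optionally be scored
under the day-1 temperature (`include_early_phases`). Practice trials use
distinct stimuli and a throwaway state, and are never scored. The per-trial
scored probability is a two-option softmax computed as a stable logistic of
the strength difference; the optimiser runs on a compiled flat-array version
of this likelihood that the test suite pins to the trial-level reference
implementation (1e-10 on enumerable sequences).

## Fitting and model comparison

Per subject-condition multi-start MLE (default 10 starts) with L-BFGS-B on
transformed coordinates: logit for learning rates (|logit| ≤ 8), log for
inverse temperatures/gains, capped at 100 to keep likelihoods finite and
fits identifiable. Starts are uniform on a moderate box of the transformed
space (α roughly 0.02–0.92, β roughly 0.1–12); the best of all starts is
returned and results are bit-reproducible given the generator seed.
BIC = 2·NLL + k·ln(n_modelled_trials); cohort comparison uses the **mean**
of per-unit BICs (configurable to a sum), and exact ties are reported as
ties rather than silently broken.

The validation harness (`gainloss.validation`) draws generating parameters
from wide identifiable ranges — rates uniform on [0.05, 0.95], choice
parameters log-uniform on [0.5, 8] — because recovery characterises the
estimator over the plausible space, not one population. It uses 16 restarts
rather than the fitting default: near-flat likelihood plateaus make the
selected optimum jittery, and validation wants estimator quality, not
speed. Typical results at the study's trial counts (31 agents, 180 + 90
trials): Spearman true-vs-recovered ≈ 0.65–0.9 for all four Q-learning
parameters, and a diagonally dominant model-recovery confusion matrix
(Q-learning essentially never misattributed; OpAL-generated agents
occasionally won by Q-learning when their gains are nearly symmetric, which
makes OpAL mimic a single-temperature model at a 2-parameter BIC penalty).

## Behavioural metrics

Accuracy is the percentage of optimal responses in a phase. Choose-X is
100 × (times X chosen)/(times X seen); in a 6-repetition transfer phase each
symbol is seen 30 times. Avoid-X = 100 − Choose-X. Missing phases yield
missing values, never zeros, and propagate to complete-case statistics.
Learner thresholding keeps subject-conditions whose learning accuracy
*strictly exceeds* 60% under a rule: overall, Gain pair, Loss pair, or the
final 10 presentations of either pair ("final 10" pooled across blocks, the
simpler reading), with "any" the union of the five. Weight-adjusted dose is
dose (default 150 mg) divided by body weight in kg.

## Inference statistics

Paired t-tests on complete cases report t, df = n−1, two-sided p, Cohen's
d = t/√n, and the 95% CI of the mean difference from t quantiles. Zero
variance of the differences is a degenerate input and raises rather than
returning t = 0: 0/0 has no defensible value and silent zeros would hide
data errors.

The **JZS Bayes factor** places a Cauchy(0, r) prior (default r = 0.707) on
the standardised effect δ under H1 and computes
BF10 = ∫ f(t | ν, δ√n) dCauchy(δ) / f(t | ν, 0) by adaptive quadrature
(relative tolerance 1e-8), reported as BF01 = 1/BF10. The posterior of δ is
normalised on a grid over [−6, 6] with 10,001 points; median and central 95%
interval are read off the cumulative. The noncentral-t density falls back to
a log-space chi-mixture quadrature where the library implementation
overflows (large ν × noncentrality), so prior-washout behaviour at large n
remains computable. Against published values derivable from printed (t, n):
BF01(0.906, 31) = 3.582, BF01(1.771, 31) = 1.301, posterior median 0.147 —
agreeing with an independent closed-form implementation (pingouin) to
better than 0.01%.

Repeated-measures ANOVA (via pingouin) reports F, dfs, p and partial η² per
effect; Mauchly's test runs for within factors with ≥3 levels and the
Greenhouse–Geisser correction replaces the p-value when Mauchly p < 0.05
(ε = 1 trivially for 2-level factors). Subjects missing any design cell are
dropped listwise. No multiple-testing correction is applied anywhere, and
report footers say so: the analysis mirrors a battery of individually
reported uncorrected tests.

The exact two-sided binomial test defaults to the "minlike" convention
(sum of all outcomes no more likely than observed) with a tail-doubling
flag. Note a known discrepancy: for 17 correct guesses of 29 both standard
conventions give p ≈ 0.458, not the 0.720 sometimes quoted for this design;
this package reports its own exact value. Dose-response uses OLS polynomial
regression (degree 1 or 2) reporting r² and the overall F-test p; a constant
outcome returns r² = 0 with an undefined p.

## Synthetic cohorts

`generate_cohort` builds the full crossover study: per-subject parameters
drawn normal on the logit scale (rates) and log scale (temperatures), both
conditions sharing the same draw, with the drug condition's day-2 choice
parameter(s) shifted additively on the log scale (default shift 0 — an
exact within-subject null). Condition order alternates across subjects;
age/MoCA/weight are drawn from distributions typical of a healthy
older-adult cohort (age ≈ 71 ± 7, MoCA ≈ 26 ± 3, weight ≈ 75 ± 13 kg); an
optional missingness rate drops whole subject-phase blocks, flagged absent
rather than zero-filled. All randomness descends from one master seed via
named `SeedSequence` substreams.

Default population values (α⁺ ≈ 0.30, α⁻ ≈ 0.20 on the logit scale with SD
0.6; day-1 β ≈ 0.67, day-2 β ≈ 1.65 on the log scale with SD 0.4) were
chosen once so the cohort reproduces the qualitative pattern of older-adult
data on this task — learning accuracy near 55% with 24-hour transfer around
65–75% — and then frozen; measured means over three 31-subject cohorts were
55.6% and 71.5%.

A vectorised batch simulator (`batch_accuracy_24h`) implements the same
Q-learning updates across thousands of agents at once for calibration
studies; a unit test holds it to the trial-level simulator in expectation.
Null cohorts give a paired-accuracy-test rejection rate statistically
compatible with the nominal 5% over 500 replicates, and power rises
monotonically with the day-2 log-β shift.

**What the generator does not emulate:** reaction times, sequential/
perseverative choice dependencies, fatigue or session-order effects,
questionnaire item responses, and any true drug effect on learning rates.
Passing tests therefore show that the pipeline is correct and calibrated
under its own generative assumptions, not that those assumptions exhaust
real behaviour.

## Problem sizes

The test suite uses 6-subject cohorts for integration tests and the full
31-subject design for distributional checks; the recovery suite runs 31
agents (parameter recovery), 20 replicates × 2 generating models (model
recovery, 6 restarts) and 500 replicate cohorts (type-I calibration).
These sizes give stable pass/fail behaviour under the fixed seeds while
keeping a full run in a few minutes on one CPU.

## Known limitations

- Only the two models in the study are implemented; no perseveration
  kernels, forgetting, or Pavlovian terms.
- MLE + BIC only — no hierarchical estimation or random-effects model
  comparison.
- The OpAL critic treatment (tied α_c) is one defensible convention among
  several; with 270 trials per unit the data cannot adjudicate.
- β estimates hit the [0, 100] bound when a unit's choices are nearly
  deterministic; recovery tables show the resulting heavy-tailed RMSE even
  where rank correlations are high.
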