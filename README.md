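# gainloss

Simulation and analysis of the **GainLoss task** — a probabilistic selection
task used to ask whether a dopaminergic drug (levodopa) changes how people
*express* reinforcement-learned values when choosing, separately from how
they *learn* them.

The package is aimed at behavioural-pharmacology and computational-psychiatry
researchers who want a fully testable version of this analysis: a task
simulator, trial-level reinforcement-learning models with exact likelihoods,
maximum-likelihood fitting with BIC model comparison, the behavioural choice
metrics, and the frequentist + Bayesian statistics of a within-subject
crossover design — all runnable end-to-end on synthetic cohorts, with no
access to any participant data required.

## The task and models

Six symbols form three pairs: a Gain pair (A: 80% chance of +1, B: 20%), a
Look pair (C/D: valueless outcomes) and a Loss pair (F: 80% chance of −1,
E: 20%). After two 90-trial learning blocks with probabilistic feedback,
choice expression is measured on feedback-free phases presenting all 15
symbol pairings six times (90 trials), immediately, at 30 minutes, and at
24 hours — the last one under drug or placebo.

Two generative models provide choice likelihoods:

* **Dual-learning-rate Q-learning** — per-symbol values updated by the
  reward prediction error δ = r − Q(c), with separate rates α⁺ (δ > 0) and
  α⁻ (δ < 0); softmax choice with inverse temperature β on day 1 and a
  separate β-day2 on the 24-hour phase.
* **OpAL** (opponent actor learning) — critic V plus Hebbian Go/NoGo actors
  G and N, combined as β_G·G − β_N·N with day-1 and day-2 gain pairs.

Fits are per subject-condition by multi-start bounded MLE; models are
compared by mean per-unit BIC = 2·NLL + k·ln(n). Inference uses paired
t-tests (Cohen's d = t/√n), JZS Bayes factors (Cauchy prior, width 0.707,
reported null-favouring as BF01), and time × drug repeated-measures ANOVAs
with Mauchly's test and the Greenhouse–Geisser correction.

## Worked example

```bash
python analysis/01_generate_cohort.py
python analysis/03_fit_models.py
python analysis/04_inference_stats.py
```

generates a 31-subject null-effect crossover cohort (no true drug effect),
fits both models and runs the statistics. Output from one run:

```
cohort: 31 subjects, 29760 trials (seed 2026)
mean learning accuracy 55.7% | mean 24-h transfer accuracy 71.1%

mean BIC qlearning: 360.5644
mean BIC opal: 370.3441
winning model by mean BIC: qlearning

24-h paired t-tests (drug vs placebo):
  accuracy   t=-1.176 p=0.249 d=-0.211 BF01=2.782
  choose_A   t=-0.282 p=0.780 d=-0.051 BF01=5.031
  ...
7/7 contrasts favour the null (BF01 > 1)
```

Read: learning stays near chance while 24-hour transfer is clearly above it;
the simpler Q-learning model wins the BIC comparison; and on a cohort with
no built-in drug effect every drug-vs-placebo contrast is non-significant
with BF01 > 1, i.e. the Bayesian tests correctly favour the null.
`analysis/02_behavioural_metrics.py` adds choose/avoid percentages and the
\>60% learner thresholds; `analysis/05_recovery_and_calibration.py` checks
parameter/model recovery and the type-I calibration of the paired accuracy
test. The same pipeline is available as a CLI (`gainloss run-all --seed 1`).

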