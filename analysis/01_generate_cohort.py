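"""Generate the synthetic crossover cohort every later step analyses.

31 subjects x 2 conditions (drug/placebo, counterbalanced), each with a
30-trial practice block, two 90-trial learning blocks and three 90-trial
feedback-free choice phases.  The default drug effect is zero: a null cohort,
matching the hypothesis the statistics are designed to test.

Writes results/cohort/{trials.csv,metadata.csv,ground_truth.json}.
"""

from gainloss.cohort import CohortConfig, generate_cohort, write_cohort
from gainloss.metrics import choice_summary

SEED = 2026

cfg = CohortConfig(seed=SEED)
dataset = generate_cohort(cfg)
write_cohort(dataset, "results/cohort")

cs = choice_summary(dataset.trials)
learn = cs[cs.phase == "learning"].accuracy.mean()
transfer = cs[cs.phase == "choice24h"].accuracy.mean()
print(f"cohort: {dataset.meta.shape[0]} subjects, {len(dataset.trials)} trials (seed {SEED})")
print(f"mean learning accuracy {learn:.1f}% | mean 24-h transfer accuracy {transfer:.1f}%")
print("wrote results/cohort/")
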