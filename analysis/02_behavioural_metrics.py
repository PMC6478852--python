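"""Behavioural summaries of the generated cohort.

Computes per subject x condition x phase accuracy and choose/avoid
percentages, and applies the >60% learner thresholds.  Writes
results/choice_summary.csv and results/learners.csv.
"""

import pandas as pd

from gainloss.cohort import read_cohort
from gainloss.metrics import choice_summary, threshold_learners
from gainloss.task import SYMBOLS

dataset = read_cohort("results/cohort")
cs = choice_summary(dataset.trials)
cs.round(4).to_csv("results/choice_summary.csv", index=False)

t24 = cs[cs.phase == "choice24h"]
print("mean 24-h choose% by symbol (pooled over conditions):")
print("  " + "  ".join(f"{s}: {t24[f'choose_{s}'].mean():5.1f}" for s in SYMBOLS))

learners = threshold_learners(dataset.trials, "any")
pd.DataFrame(learners, columns=["subject", "condition"]).to_csv(
    "results/learners.csv", index=False)
per_cond = pd.DataFrame(learners, columns=["subject", "condition"]).condition.value_counts()
print(f"units exceeding 60% learning accuracy under any rule: {len(learners)}/62 "
      f"({per_cond.to_dict()})")
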