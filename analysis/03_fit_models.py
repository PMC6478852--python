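"""Fit the dual-learning-rate Q-learning and OpAL models to every
subject-condition and compare them by mean per-unit BIC.

Writes results/fits.csv and results/model_comparison.csv.
"""

import pandas as pd

from gainloss.cohort import read_cohort
from gainloss.fitting import compare_models
from gainloss.pipeline import fit_cohort

SEED = 2026

dataset = read_cohort("results/cohort")
fits = fit_cohort(dataset, ("qlearning", "opal"), n_starts=10, seed=SEED)
rows = [{"unit": u, **fr.to_row()} for m in fits for u, fr in fits[m].items()]
pd.DataFrame(rows).round(4).to_csv("results/fits.csv", index=False)

comparison = compare_models(fits)
comparison.to_frame().round(4).to_csv("results/model_comparison.csv", index=False)
for m, b in comparison.mean_bic.items():
    print(f"mean BIC {m}: {b:.4f}")
print(f"winning model by mean BIC: {comparison.winner}")
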