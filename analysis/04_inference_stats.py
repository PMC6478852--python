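"""The study's statistical battery on the generated cohort.

Paired t-tests with Cohen's d and JZS Bayes factors (BF01, Cauchy width
0.707) on the 24-hour choice phase; time x drug repeated-measures ANOVAs
across the three choice phases; weight-adjusted dose regressions on the
drug-minus-placebo differences.  On the default null cohort the expectation
is no significant drug effects and BF01 > 1 for most contrasts.

Writes the report bundle under results/stats/.
"""

from gainloss.pipeline import PipelineConfig, run_pipeline

SEED = 2026

cfg = PipelineConfig(out_dir="results/stats", seed=SEED, input_dir="results/cohort",
                     models=())  # fits were produced by 03_fit_models.py
result = run_pipeline(cfg)

tt = result["ttests"].set_index("measure")
print("24-h paired t-tests (drug vs placebo):")
for measure, row in tt.iterrows():
    print(f"  {measure:10s} t={row['t']:+.3f} p={row['p']:.3f} d={row['d']:+.3f} "
          f"BF01={row['BF01']:.3f}")
n_null = (tt["BF01"] > 1).sum()
print(f"{n_null}/{len(tt)} contrasts favour the null (BF01 > 1)")
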