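"""End-to-end orchestration: generate (or ingest) -> behavioural metrics ->
model fitting and comparison -> inference statistics -> report tables.

All randomness descends from one master seed via named ``SeedSequence``
substreams; running the same config and seed twice produces byte-identical
reports.  Report values are written with 4 decimals.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CONDITIONS,
    CohortConfig,
    CohortDataset,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .fitting import FitResult, compare_models, fit_unit
from .metrics import choice_summary, threshold_learners, weight_adjusted_dose, SubjectMeta
from .stats import BayesConfig, DegenerateInputError, dose_response, paired_t, rm_anova
from .task import CHOICE_PHASES, SYMBOLS

log = logging.getLogger("gainloss")


@dataclass
class PipelineConfig:
    out_dir: str = "results/run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_dir: str | None = None          # read an existing cohort instead of generating
    models: tuple[str, ...] = ("qlearning", "opal")
    n_starts: int = 10
    include_early_phases: bool = False    # score choice0/choice30 under day-1 beta
    bf_prior_scale: float = 0.707
    threshold_rule: str = "any"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        if "models" in d:
            d["models"] = tuple(d["models"])
        return cls(**d)


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(4)


def _write(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        _fmt(df).to_csv(fh, index=False)


def fit_cohort(
    dataset: CohortDataset, models, n_starts: int, seed: int, modelled_phases=None,
) -> dict[str, dict[str, FitResult]]:
    """Fit every subject-condition unit under each model; deterministic per seed."""
    from .models import MODELLED_PHASES_DEFAULT

    phases = MODELLED_PHASES_DEFAULT if modelled_phases is None else modelled_phases
    units = sorted(
        dataset.trials.groupby(["subject", "condition"]).groups
    )
    fits: dict[str, dict[str, FitResult]] = {m: {} for m in models}
    root = np.random.SeedSequence(seed)
    for (subject, condition), unit_seq in zip(units, root.spawn(len(units))):
        trials = dataset.unit_trials(subject, condition)
        for model, m_seq in zip(models, unit_seq.spawn(len(models))):
            rng = np.random.default_rng(m_seq)
            try:
                fits[model][f"{subject}/{condition}"] = fit_unit(
                    model, trials, n_starts=n_starts, rng=rng, modelled_phases=phases
                )
            except Exception as exc:  # noqa: BLE001 - surfaced in the run log
                log.warning("fit failed for %s/%s under %s: %s", subject, condition, model, exc)
    return fits


def _paired_table(summary: pd.DataFrame, phase: str, measures: list[str], bayes: BayesConfig) -> pd.DataFrame:
    wide = summary[summary.phase == phase].pivot(index="subject", columns="condition")
    rows = []
    for measure in measures:
        try:
            res = paired_t(wide[(measure, "drug")], wide[(measure, "placebo")], bayes)
            rows.append({"measure": measure, **res.to_row()})
        except (DegenerateInputError, KeyError) as exc:
            rows.append({"measure": measure, "error": str(exc)})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the key results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [f"gainloss {__version__}", f"seed {config.seed}"]
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(name)s: %(message)s")

    stage = "generate"
    try:
        if config.input_dir:
            dataset = read_cohort(config.input_dir)
        else:
            cohort_cfg = CohortConfig(**{**asdict(config.cohort), "seed": config.seed})
            dataset = generate_cohort(cohort_cfg)
            write_cohort(dataset, out / "cohort")
        log.info("cohort: %d subjects, %d trials", dataset.meta.shape[0], len(dataset.trials))

        stage = "metrics"
        summary = choice_summary(dataset.trials)
        _write(summary, out / "choice_summary.csv", header)
        learners = threshold_learners(dataset.trials, config.threshold_rule)
        pd.DataFrame(learners, columns=["subject", "condition"]).to_csv(
            out / "learners.csv", index=False)

        stage = "fit"
        fits = fit_cohort(dataset, config.models, config.n_starts, config.seed,
                          modelled_phases=("learning", "choice0", "choice30", "choice24h")
                          if config.include_early_phases else None)
        fit_rows = [{"unit": u, **fr.to_row()} for m in fits for u, fr in fits[m].items()]
        _write(pd.DataFrame(fit_rows), out / "fits.csv", header)
        comparison = None
        complete = {m: f for m, f in fits.items() if f}
        if len(complete) >= 2 and len({frozenset(f) for f in complete.values()}) == 1:
            comparison = compare_models(complete)
            _write(comparison.to_frame(), out / "model_comparison.csv", header)

        stage = "stats"
        bayes = BayesConfig(prior_scale=config.bf_prior_scale)
        measures = ["accuracy"] + [f"choose_{s}" for s in SYMBOLS]
        ttests = _paired_table(summary, "choice24h", measures, bayes)
        _write(ttests, out / "ttests_24h.csv",
               header + ["paired t-tests, drug vs placebo, 24-hour choice phase",
                         "no multiple-testing correction applied"])

        anova_rows = []
        long = summary[summary.phase.isin(CHOICE_PHASES)]
        for measure in measures:
            sub = long.rename(columns={measure: "y"})[["subject", "condition", "phase", "y"]].dropna()
            try:
                res = rm_anova(sub, dv="y", within=["phase", "condition"], subject="subject")
                for eff in res.effects:
                    anova_rows.append({"measure": measure, **vars(eff)})
            except ValueError as exc:
                anova_rows.append({"measure": measure, "error": str(exc)})
        _write(pd.DataFrame(anova_rows), out / "anova_time_drug.csv", header)

        # parameter comparisons, Table-4 style, for the winning model
        param_tables = {}
        for model, unit_fits in complete.items():
            rows = []
            per_cond = {c: {} for c in CONDITIONS}
            for unit, fr in unit_fits.items():
                subject, condition = unit.split("/")
                per_cond[condition][subject] = fr.params.to_dict()
            shared = sorted(set(per_cond["drug"]) & set(per_cond["placebo"]))
            if shared:
                pnames = [k for k, v in next(iter(per_cond["drug"].values())).items() if v is not None]
                for pname in pnames:
                    x = [per_cond["drug"][s][pname] for s in shared]
                    y = [per_cond["placebo"][s][pname] for s in shared]
                    try:
                        res = paired_t(x, y, bayes)
                        rows.append({"parameter": pname, **res.to_row()})
                    except DegenerateInputError as exc:
                        rows.append({"parameter": pname, "error": str(exc)})
            param_tables[model] = pd.DataFrame(rows)
            _write(param_tables[model], out / f"params_{model}.csv", header)

        # weight-adjusted dose regressions on drug-minus-placebo differences
        dose_rows = []
        meta = dataset.meta.set_index("subject")
        wide = summary[summary.phase == "choice24h"].pivot(index="subject", columns="condition")
        doses = [weight_adjusted_dose(SubjectMeta(s, "", meta.loc[s, "weight_kg"],
                                                  meta.loc[s, "dose_mg"]))
                 for s in wide.index]
        for measure in measures:
            try:
                diff = wide[(measure, "drug")] - wide[(measure, "placebo")]
                for degree in (1, 2):
                    reg = dose_response(doses, diff, degree=degree)
                    dose_rows.append({"measure": measure, "degree": degree,
                                      "r_squared": reg.r_squared, "p": reg.p})
            except (ValueError, KeyError) as exc:
                dose_rows.append({"measure": measure, "error": str(exc)})
        _write(pd.DataFrame(dose_rows), out / "dose_response.csv", header)

        run_info = {
            "seed": config.seed, "version": __version__,
            "n_subjects": int(dataset.meta.shape[0]),
            "models": list(config.models),
            "winner": comparison.winner if comparison else None,
            "mean_bic": comparison.mean_bic if comparison else None,
        }
        with open(out / "run.json", "w") as fh:
            json.dump(run_info, fh, indent=1)
    except Exception as exc:
        (out / "INCOMPLETE").write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"dataset": dataset, "summary": summary, "fits": fits,
            "comparison": comparison, "ttests": ttests, "run_info": run_info}
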