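"""Recovery harnesses: can the fitting machinery get back what generated the
data?

Parameter recovery simulates agents on the standard schedule (two 90-trial
learning blocks + a 90-trial 24-hour transfer phase), refits them, and
summarises bias, RMSE and true-vs-recovered rank correlation.  Model
recovery simulates agents from each model, fits both, and tabulates which
wins by BIC — the confusion matrix whose diagonal says the comparison can
tell the models apart at this trial count.

Generating parameters are drawn from wide, deliberately identifiable ranges
(learning rates uniform on [0.05, 0.95], choice parameters log-uniform on
[0.5, 8]): recovery characterises the estimator over the plausible parameter
space, not any one population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import task
from .fitting import FitResult, fit_unit, recovery_report
from .models import OpALParams, QLearningParams, get_model, simulate_agent
from .task import make_symbol_set

RATE_RANGE = (0.05, 0.95)
CHOICE_RANGE = (0.5, 8.0)


def _draw_params(model_name: str, rng: np.random.Generator):
    def rate():
        return float(rng.uniform(*RATE_RANGE))

    def gain():
        lo, hi = np.log(CHOICE_RANGE)
        return float(np.exp(rng.uniform(lo, hi)))

    if model_name == "qlearning":
        return QLearningParams(rate(), rate(), gain(), gain())
    return OpALParams(rate(), rate(), gain(), gain(), gain(), gain())


def _standard_schedule(rng: np.random.Generator):
    ss = make_symbol_set("placebo")
    sched = task.build_learning_schedule(2, 30, rng)
    sched += task.build_choice_schedule(ss, 6, rng)
    return sched, ss


def simulate_and_fit(
    model_name: str, params, rng: np.random.Generator,
    fit_models: tuple[str, ...] | None = None, n_starts: int = 10,
) -> dict[str, FitResult]:
    """One agent on the standard schedule, fitted under each requested model."""
    gen = get_model(model_name)
    sched, ss = _standard_schedule(rng)
    trials = simulate_agent(gen, params, sched, ss, rng)
    out = {}
    for m in fit_models or (model_name,):
        out[m] = fit_unit(m, trials, n_starts=n_starts, rng=rng)
    return out


def parameter_recovery(
    model_name: str, n_agents: int, rng: np.random.Generator, n_starts: int = 16,
) -> tuple[pd.DataFrame, list, list[FitResult]]:
    """Recovery table over ``n_agents`` independently drawn agents.

    Uses more optimisation restarts than the fitting default: near-flat
    likelihood plateaus make the selected optimum jittery, and validation
    wants estimator quality, not speed.
    """
    if n_agents == 0:
        return recovery_report([], []), [], []
    true_params, fits = [], []
    for _ in range(n_agents):
        p = _draw_params(model_name, rng)
        fr = simulate_and_fit(model_name, p, rng, n_starts=n_starts)[model_name]
        true_params.append(p)
        fits.append(fr)
    return recovery_report(true_params, fits), true_params, fits


def model_recovery_confusion(
    n_reps: int, rng: np.random.Generator,
    models: tuple[str, ...] = ("qlearning", "opal"), n_starts: int = 10,
) -> pd.DataFrame:
    """Replicate-count confusion matrix: rows = generating model, columns =
    BIC-winning model."""
    counts = pd.DataFrame(0, index=list(models), columns=list(models))
    for _ in range(n_reps):
        for gen_name in models:
            p = _draw_params(gen_name, rng)
            fits = simulate_and_fit(gen_name, p, rng, fit_models=models, n_starts=n_starts)
            winner = min(fits, key=lambda m: fits[m].bic)
            counts.loc[gen_name, winner] += 1
    return counts
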