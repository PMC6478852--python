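"""Maximum-likelihood fitting, BIC model comparison and recovery harnesses.

Each subject-condition is fitted separately (the study compares parameters
between drug and placebo with paired tests).  Optimisation is multi-start
L-BFGS-B on transformed coordinates — logit for learning rates, log for
inverse temperatures (capped at 100) — so every start respects the bounds and
the optimum maps back to the open parameter space.

The optimiser runs on a "compiled" flat-array view of the trial sequence for
speed; :func:`gainloss.models.negative_log_likelihood` is the reference
implementation and the two are held equal by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .models import (
    MODELLED_PHASES_DEFAULT,
    OpALParams,
    QLearningParams,
    _GN_FLOOR,
    _SYM_INDEX,
    get_model,
)
from .task import TrialRecord

BETA_MAX = 100.0  # keeps likelihoods finite and fits identifiable
_LOGIT_BOUND = 8.0  # |logit(alpha)| cap; alpha within ~3e-4 of the boundary


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    model: str
    params: object
    nll: float
    n_trials: int
    k_params: int
    bic: float
    n_starts: int
    best_start: int
    converged: bool
    start_nlls: list[float] = field(default_factory=list, repr=False)

    def to_row(self) -> dict:
        row = {"model": self.model, "nll": self.nll, "bic": self.bic,
               "n_trials": self.n_trials, "k_params": self.k_params,
               "converged": self.converged}
        row.update(self.params.to_dict())
        return row


def bic(nll: float, k_params: int, n_trials: int) -> float:
    """Bayesian Information Criterion, 2*NLL + k*ln(n); lower is better."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return 2.0 * nll + k_params * math.log(n_trials)


# ---------------------------------------------------------------------------
# Compiled likelihood

@dataclass
class CompiledTrials:
    """Flat-array view of one subject-condition's modelled trial sequence."""

    left: np.ndarray      # symbol indices
    right: np.ndarray
    chosen_is_left: np.ndarray  # bool
    reward: np.ndarray    # nan on feedback-free trials
    is_learning: np.ndarray     # bool: update values after scoring
    scored: np.ndarray    # bool: contributes a likelihood term
    is_day2: np.ndarray   # bool: use day-2 choice parameters
    n_scored: int


def compile_trials(
    trials: Sequence[TrialRecord],
    modelled_phases: Sequence[str] = MODELLED_PHASES_DEFAULT,
) -> CompiledTrials:
    rows = [t for t in trials if t.chosen is not None and t.phase != "practice"]
    left = np.array([_SYM_INDEX[t.left] for t in rows], dtype=np.intp)
    right = np.array([_SYM_INDEX[t.right] for t in rows], dtype=np.intp)
    chosen_is_left = np.array([t.chosen == t.left for t in rows])
    reward = np.array([np.nan if t.reward is None else t.reward for t in rows])
    is_learning = np.array([t.phase == "learning" for t in rows])
    scored = np.array([t.phase in modelled_phases for t in rows])
    is_day2 = np.array([t.phase == "choice24h" for t in rows])
    return CompiledTrials(left, right, chosen_is_left, reward, is_learning,
                          scored, is_day2, int(scored.sum()))


def _nll_qlearning(theta: np.ndarray, ct: CompiledTrials) -> float:
    a_pos, a_neg, beta, beta2 = theta
    q = [0.0] * 6
    nll = 0.0
    for i in range(len(ct.left)):
        li, ri = ct.left[i], ct.right[i]
        ci = li if ct.chosen_is_left[i] else ri
        if ct.scored[i]:
            b = beta2 if ct.is_day2[i] else beta
            d = b * (q[ci] - (q[ri] if ci == li else q[li]))
            # -log sigmoid(d), stable in both tails
            nll += math.log1p(math.exp(-abs(d))) + max(-d, 0.0)
        if ct.is_learning[i]:
            delta = ct.reward[i] - q[ci]
            q[ci] += (a_pos if delta > 0 else a_neg) * delta
    return nll


def _nll_opal(theta: np.ndarray, ct: CompiledTrials) -> float:
    a_g, a_n, b_g, b_n, b_g2, b_n2, a_c = theta
    v = [0.0] * 6
    g = [1.0] * 6
    n = [1.0] * 6
    nll = 0.0
    for i in range(len(ct.left)):
        li, ri = ct.left[i], ct.right[i]
        ci = li if ct.chosen_is_left[i] else ri
        oi = ri if ci == li else li
        if ct.scored[i]:
            bg, bn = (b_g2, b_n2) if ct.is_day2[i] else (b_g, b_n)
            d = (bg * g[ci] - bn * n[ci]) - (bg * g[oi] - bn * n[oi])
            nll += math.log1p(math.exp(-abs(d))) + max(-d, 0.0)
        if ct.is_learning[i]:
            delta = ct.reward[i] - v[ci]
            v[ci] += a_c * delta
            g[ci] = max(g[ci] + a_g * g[ci] * delta, _GN_FLOOR)
            n[ci] = max(n[ci] - a_n * n[ci] * delta, _GN_FLOOR)
    return nll


# transformed coordinates: logit for rates, log for temperatures/gains

def _q_from_x(x: np.ndarray) -> np.ndarray:
    return np.array([expit(x[0]), expit(x[1]), math.exp(x[2]), math.exp(x[3])])


def _opal_from_x(x: np.ndarray) -> np.ndarray:
    a_g, a_n = expit(x[0]), expit(x[1])
    return np.array([a_g, a_n, *np.exp(x[2:6]), 0.5 * (a_g + a_n)])


_SPECS = {
    "qlearning": dict(
        n_x=4, from_x=_q_from_x, nll=_nll_qlearning,
        bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)] * 2 + [(-10.0, math.log(BETA_MAX))] * 2,
    ),
    "opal": dict(
        n_x=6, from_x=_opal_from_x, nll=_nll_opal,
        bounds=[(-_LOGIT_BOUND, _LOGIT_BOUND)] * 2 + [(-10.0, math.log(BETA_MAX))] * 4,
    ),
}


def _params_from_theta(model_name: str, theta: np.ndarray):
    if model_name == "qlearning":
        return QLearningParams(*[float(t) for t in theta])
    return OpALParams(*[float(t) for t in theta[:6]], alpha_c=None)


def fit_unit(
    model_name: str,
    trials: Sequence[TrialRecord],
    n_starts: int = 10,
    rng: np.random.Generator | None = None,
    modelled_phases: Sequence[str] = MODELLED_PHASES_DEFAULT,
) -> FitResult:
    """Fit one subject-condition by multi-start bounded MLE.

    Deterministic given the generator state; the best of ``n_starts`` local
    optimisations (uniform starts on the transformed space) is returned.
    """
    if not trials:
        raise FitError("empty trial set")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    model = get_model(model_name)
    spec = _SPECS[model_name]
    ct = compile_trials(trials, modelled_phases)
    if ct.n_scored == 0:
        raise FitError("no trials in the modelled phases")

    def objective(x):
        return spec["nll"](spec["from_x"](x), ct)

    lo = np.array([b[0] for b in spec["bounds"]])
    hi = np.array([b[1] for b in spec["bounds"]])
    best = None
    start_nlls = []
    any_converged = False
    for s in range(n_starts):
        # moderate start box: alphas spread over (0.02, 0.98), betas over (~0.1, ~12)
        x0 = rng.uniform(np.maximum(lo, -4.0), np.minimum(hi, 2.5))
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=spec["bounds"],
                                options={"ftol": 1e-9, "gtol": 1e-7})
        start_nlls.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), s)
    if best is None or not np.isfinite(best[0]):
        raise FitError(f"all {n_starts} starts failed; last diagnostics: {res.message}")
    nll_opt, x_opt, s_opt = best
    params = _params_from_theta(model_name, spec["from_x"](x_opt))
    k = model.n_free_params
    return FitResult(
        model=model_name, params=params, nll=nll_opt, n_trials=ct.n_scored,
        k_params=k, bic=bic(nll_opt, k, ct.n_scored), n_starts=n_starts,
        best_start=s_opt, converged=any_converged, start_nlls=start_nlls,
    )


# ---------------------------------------------------------------------------
# Model comparison

@dataclass
class ModelComparison:
    mean_bic: dict[str, float]
    winner: str | None          # None on an exact tie
    bic_table: pd.DataFrame     # unit x model per-unit BICs

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"model": list(self.mean_bic), "mean_bic": list(self.mean_bic.values())})
        df["winner"] = df["model"] == self.winner
        return df


def compare_models(fits_by_model: dict[str, dict[str, FitResult]]) -> ModelComparison:
    """Cohort-level comparison by mean per-unit BIC; ties reported, not broken."""
    unit_sets = {m: set(f) for m, f in fits_by_model.items()}
    ref = next(iter(unit_sets.values()))
    if any(u != ref for u in unit_sets.values()):
        raise ValueError("models were fitted on different unit sets")
    table = pd.DataFrame({m: {u: fr.bic for u, fr in fits.items()}
                          for m, fits in fits_by_model.items()}).sort_index()
    mean_bic = {m: float(table[m].mean()) for m in table.columns}
    best = min(mean_bic.values())
    winners = [m for m, v in mean_bic.items() if v == best]
    return ModelComparison(mean_bic=mean_bic,
                           winner=winners[0] if len(winners) == 1 else None,
                           bic_table=table)


# ---------------------------------------------------------------------------
# Recovery

def recovery_report(
    true_params: Sequence[object],
    fitted: Sequence[FitResult],
) -> pd.DataFrame:
    """Per-parameter bias, RMSE and Spearman true-vs-recovered correlation."""
    if not fitted:
        return pd.DataFrame(columns=["parameter", "bias", "rmse", "spearman_r"])
    names = [k for k, v in true_params[0].to_dict().items() if v is not None]
    rows = []
    for name in names:
        t = np.array([p.to_dict()[name] for p in true_params], dtype=float)
        r = np.array([f.params.to_dict()[name] for f in fitted], dtype=float)
        rho = stats.spearmanr(t, r).statistic if len(t) > 2 and np.std(t) > 0 else np.nan
        rows.append({"parameter": name, "bias": float(np.mean(r - t)),
                     "rmse": float(np.sqrt(np.mean((r - t) ** 2))),
                     "spearman_r": float(rho) if rho == rho else np.nan})
    return pd.DataFrame(rows)
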