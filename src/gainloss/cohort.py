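"""Synthetic crossover cohorts for the GainLoss study design.

Generates complete studies with the structure the analysis assumes: 31
subjects, each completing a drug and a placebo condition (order
counterbalanced), with a 30-trial practice block, two 90-trial learning
blocks (30 per pair, 80/20 contingencies) and three 90-trial feedback-free
choice phases (0 min, 30 min, 24 h).  Choices come from model agents whose
parameters are drawn per subject from population distributions — normal on
the logit scale for learning rates and on the log scale for inverse
temperatures.  A configurable drug effect shifts the day-2 choice
parameter(s) additively on the log scale, coupled within subject (drug
parameters = placebo parameters + shift), so a zero effect gives an exact
within-subject null.

Default population values place learning-phase accuracy near 55% and
24-hour transfer accuracy in the 65-75% band — near-chance incremental
learning with clearly above-chance expression, the qualitative pattern seen
in older adults on this task.  Subject metadata (age, MoCA, weight) are drawn
to match the cohort demographics of such studies (age ~ 71 +/- 7 years,
MoCA ~ 26 +/- 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy import stats

from . import task
from .metrics import SubjectMeta
from .models import QLearningParams, OpALParams, get_model, simulate_agent
from .task import COLUMNS, TrialRecord, make_symbol_set, trials_to_frame, frame_to_trials

CONDITIONS = ("drug", "placebo")


@dataclass
class CohortConfig:
    n_subjects: int = 31
    model: str = "qlearning"
    # population means/dispersions on transformed scales
    mu_logit_alpha_pos: float = -0.85   # alpha+ ~ 0.30
    mu_logit_alpha_neg: float = -1.40   # alpha- ~ 0.20
    sd_logit_alpha: float = 0.6
    mu_log_beta: float = -0.4           # day-1 beta ~ 0.67
    mu_log_beta_day2: float = 0.5       # day-2 beta ~ 1.65
    sd_log_beta: float = 0.4
    # drug effect: additive shift on log day-2 choice parameter(s)
    drug_shift_log_beta_day2: float = 0.0
    drug_shift_log_beta_g_day2: float = 0.0  # OpAL approach gain (Frank-style asymmetry)
    drug_shift_log_beta_n_day2: float = 0.0  # OpAL avoidance gain
    missingness: float = 0.0            # per subject-phase block drop probability
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 13.0
    age_mean: float = 71.2
    age_sd: float = 7.4
    moca_mean: float = 26.2
    moca_sd: float = 3.1
    dose_mg: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.sd_logit_alpha < 0 or self.sd_log_beta < 0:
            raise ValueError("dispersions must be non-negative")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")
        if self.model not in ("qlearning", "opal"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class CohortDataset:
    trials: pd.DataFrame                       # observed tidy table
    meta: pd.DataFrame                         # subject, order, weight_kg, age, moca, dose_mg
    ground_truth: dict[str, dict]              # "subject/condition" -> generating params
    config: CohortConfig

    def unit_trials(self, subject: str, condition: str) -> list[TrialRecord]:
        sub = self.trials[(self.trials.subject == subject) & (self.trials.condition == condition)]
        return frame_to_trials(sub.sort_values(["phase", "block", "trial_index"], key=_phase_key))


def _phase_key(col: pd.Series) -> pd.Series:
    if col.name == "phase":
        order = {p: i for i, p in enumerate(task.PHASES)}
        return col.map(order)
    return col


def draw_subject_params(config: CohortConfig, rng: np.random.Generator):
    """Per-subject (placebo, drug) parameter pairs.

    Placebo parameters are population draws; drug parameters are the same
    draws with the configured day-2 log-scale shift applied, so any drug
    effect is purely within-subject.
    """
    config.validate()
    out = []
    for _ in range(config.n_subjects):
        la_p = rng.normal(config.mu_logit_alpha_pos, config.sd_logit_alpha)
        la_n = rng.normal(config.mu_logit_alpha_neg, config.sd_logit_alpha)
        lb1 = rng.normal(config.mu_log_beta, config.sd_log_beta)
        lb2 = rng.normal(config.mu_log_beta_day2, config.sd_log_beta)
        if config.model == "qlearning":
            placebo = QLearningParams(expit(la_p), expit(la_n), np.exp(lb1), np.exp(lb2))
            drug = QLearningParams(
                placebo.alpha_pos, placebo.alpha_neg, placebo.beta,
                float(np.exp(lb2 + config.drug_shift_log_beta_day2)),
            )
        else:
            placebo = OpALParams(expit(la_p), expit(la_n),
                                 np.exp(lb1), np.exp(lb1), np.exp(lb2), np.exp(lb2))
            drug = OpALParams(
                placebo.alpha_g, placebo.alpha_n, placebo.beta_g, placebo.beta_n,
                float(np.exp(lb2 + config.drug_shift_log_beta_g_day2)),
                float(np.exp(lb2 + config.drug_shift_log_beta_n_day2)),
            )
        out.append({"placebo": placebo, "drug": drug})
    return out


def _subject_schedule(rng: np.random.Generator) -> list[TrialRecord]:
    sched = task.build_learning_schedule(1, 10, rng, phase="practice")
    sched += task.build_learning_schedule(2, 30, rng, phase="learning")
    ss = make_symbol_set("placebo")
    for phase in task.CHOICE_PHASES:
        sched += task.build_choice_schedule(ss, 6, rng, phase=phase)
    return sched


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Simulate the full crossover study; bit-reproducible from ``config.seed``."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    params_rng = np.random.default_rng(root.spawn(1)[0])
    all_params = draw_subject_params(config, params_rng)
    model = get_model(config.model)

    frames, meta_rows, truth = [], [], {}
    for i, subj_params in enumerate(all_params):
        subject = f"S{i + 1:02d}"
        s_seq = root.spawn(1)[0]
        srng = np.random.default_rng(s_seq)
        order = "drug_first" if i % 2 == 0 else "placebo_first"  # counterbalanced
        weight = float(np.clip(srng.normal(config.weight_mean_kg, config.weight_sd_kg), 45, 140))
        age = float(np.clip(srng.normal(config.age_mean, config.age_sd), 65, 95))
        moca = int(np.clip(round(srng.normal(config.moca_mean, config.moca_sd)), 15, 30))
        meta_rows.append({"subject": subject, "order": order, "weight_kg": round(weight, 1),
                          "age": round(age, 1), "moca": moca, "dose_mg": config.dose_mg})
        for condition in CONDITIONS:
            params = subj_params[condition]
            symbol_set = make_symbol_set(condition)
            sched = _subject_schedule(srng)
            records = simulate_agent(model, params, sched, symbol_set, srng)
            if config.missingness > 0:
                drop = {ph for ph in task.PHASES if srng.random() < config.missingness}
                records = [r for r in records if r.phase not in drop]
            frames.append(trials_to_frame(records, subject=subject, condition=condition))
            truth[f"{subject}/{condition}"] = params.to_dict()

    frames = [f for f in frames if not f.empty]
    trials = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=COLUMNS)
    return CohortDataset(trials=trials, meta=pd.DataFrame(meta_rows),
                         ground_truth=truth, config=config)


def write_cohort(dataset: CohortDataset, path: str | Path) -> None:
    """Observed tables as CSV; generating parameters segregated into JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.trials.to_csv(path / "trials.csv", index=False)
    dataset.meta.to_csv(path / "metadata.csv", index=False)
    with open(path / "ground_truth.json", "w") as fh:
        json.dump({"config": asdict(dataset.config), "params": dataset.ground_truth}, fh, indent=1)


def read_cohort(path: str | Path) -> CohortDataset:
    path = Path(path)
    trials = pd.read_csv(path / "trials.csv", dtype={"subject": str, "condition": str})
    bad = ~(trials["left_symbol"].isin(task.SYMBOLS) & trials["right_symbol"].isin(task.SYMBOLS))
    if bad.any():
        row = trials.index[bad][0]
        raise ValueError(f"unknown symbol in trials.csv at row {row}: "
                         f"{trials.loc[row, ['left_symbol', 'right_symbol']].tolist()}")
    meta = pd.read_csv(path / "metadata.csv", dtype={"subject": str})
    gt_file = path / "ground_truth.json"
    truth, config = {}, CohortConfig()
    if gt_file.exists():
        with open(gt_file) as fh:
            payload = json.load(fh)
        truth = payload.get("params", {})
        config = CohortConfig(**payload.get("config", {}))
    return CohortDataset(trials=trials, meta=meta, ground_truth=truth, config=config)


def subject_meta(dataset: CohortDataset) -> list[SubjectMeta]:
    return [
        SubjectMeta(subject=r.subject, order=r.order, weight_kg=r.weight_kg,
                    dose_mg=r.dose_mg, age=r.age, moca=r.moca)
        for r in dataset.meta.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Vectorised Q-learning batch simulator (for calibration studies that need
# thousands of agents: type-I error rates, power curves)

def _batch_shuffled(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently shuffle each row of a (n_agents, n_trials) index array."""
    keys = rng.random(rows.shape)
    return np.take_along_axis(rows, np.argsort(keys, axis=1), axis=1)


_PAIR_MEMBERS = np.array([[0, 1], [2, 3], [4, 5]])           # learning pairs
_ALL_PAIRS = np.array([(i, j) for i in range(6) for j in range(i + 1, 6)])
_P_SALIENT_VEC = np.array([task.make_symbol_set("placebo")[s].p_salient for s in task.SYMBOLS])
_SALIENT_VALUE_VEC = np.array([task.make_symbol_set("placebo")[s].salient_value for s in task.SYMBOLS])


def batch_accuracy_24h(
    alpha_pos: np.ndarray, alpha_neg: np.ndarray, beta: np.ndarray, beta_day2: np.ndarray,
    rng: np.random.Generator, trials_per_pair: int = 30, n_blocks: int = 2, choice_reps: int = 6,
) -> np.ndarray:
    """24-hour choice accuracy for a batch of Q-learning agents, one per
    parameter-vector entry, each playing an independently shuffled standard
    schedule.  Same update and choice rules as the trial-level simulator,
    vectorised across agents."""
    n = len(alpha_pos)
    q = np.zeros((n, 6))
    rows = np.arange(n)
    # learning: per-block shuffled pair order per agent
    for _ in range(n_blocks):
        pair_idx = _batch_shuffled(np.tile(np.repeat(np.arange(3), trials_per_pair), (n, 1)), rng)
        for t in range(pair_idx.shape[1]):
            a, b = _PAIR_MEMBERS[pair_idx[:, t]].T
            p_a = 1.0 / (1.0 + np.exp(-beta * (q[rows, a] - q[rows, b])))
            pick_a = rng.random(n) < p_a
            chosen = np.where(pick_a, a, b)
            reward = np.where(rng.random(n) < _P_SALIENT_VEC[chosen],
                              _SALIENT_VALUE_VEC[chosen], 0.0)
            delta = reward - q[rows, chosen]
            lr = np.where(delta > 0, alpha_pos, alpha_neg)
            q[rows, chosen] += lr * delta
    # 24-h transfer: all 15 pairs x reps, no updates
    pair_idx = _batch_shuffled(np.tile(np.repeat(np.arange(15), choice_reps), (n, 1)), rng)
    n_choice = pair_idx.shape[1]
    optimal = np.zeros(n)
    for t in range(n_choice):
        a, b = _ALL_PAIRS[pair_idx[:, t]].T  # a always the higher-ranked symbol
        p_a = 1.0 / (1.0 + np.exp(-beta_day2 * (q[rows, a] - q[rows, b])))
        optimal += rng.random(n) < p_a
    return 100.0 * optimal / n_choice


def null_rejection_rate(
    config: CohortConfig, n_reps: int, rng: np.random.Generator, alpha_level: float = 0.05,
) -> float:
    """Fraction of null-effect replicate cohorts in which the paired t-test on
    24-hour accuracy (drug vs placebo) rejects at ``alpha_level``.

    A type-I calibration: each replicate draws ``config.n_subjects`` subjects,
    plays both conditions with identical generating parameters and paired-t
    tests the accuracy difference.
    """
    n_sub = config.n_subjects
    m = n_reps * n_sub
    la_p = rng.normal(config.mu_logit_alpha_pos, config.sd_logit_alpha, m)
    la_n = rng.normal(config.mu_logit_alpha_neg, config.sd_logit_alpha, m)
    b1 = np.exp(rng.normal(config.mu_log_beta, config.sd_log_beta, m))
    b2 = np.exp(rng.normal(config.mu_log_beta_day2, config.sd_log_beta, m))
    acc = {c: batch_accuracy_24h(expit(la_p), expit(la_n), b1, b2, rng) for c in CONDITIONS}
    diff = (acc["drug"] - acc["placebo"]).reshape(n_reps, n_sub)
    tstat, pval = stats.ttest_rel(diff, np.zeros_like(diff), axis=1)
    # ttest against zero on the paired differences == paired t on the two conditions
    return float(np.mean(pval < alpha_level))


def drug_effect_power(
    config: CohortConfig, shift_log_beta_day2: float, n_reps: int,
    rng: np.random.Generator, alpha_level: float = 0.05,
) -> float:
    """Rejection rate of the paired accuracy t-test when the drug condition's
    day-2 inverse temperature is shifted by ``shift_log_beta_day2`` log units."""
    n_sub = config.n_subjects
    m = n_reps * n_sub
    la_p = rng.normal(config.mu_logit_alpha_pos, config.sd_logit_alpha, m)
    la_n = rng.normal(config.mu_logit_alpha_neg, config.sd_logit_alpha, m)
    b1 = np.exp(rng.normal(config.mu_log_beta, config.sd_log_beta, m))
    lb2 = rng.normal(config.mu_log_beta_day2, config.sd_log_beta, m)
    acc_d = batch_accuracy_24h(expit(la_p), expit(la_n), b1, np.exp(lb2 + shift_log_beta_day2), rng)
    acc_p = batch_accuracy_24h(expit(la_p), expit(la_n), b1, np.exp(lb2), rng)
    diff = (acc_d - acc_p).reshape(n_reps, n_sub)
    _, pval = stats.ttest_rel(diff, np.zeros_like(diff), axis=1)
    return float(np.mean(pval < alpha_level))
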