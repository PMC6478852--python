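"""Behavioural summaries: accuracy, choose/avoid percentages, learner
thresholds and weight-adjusted dose.

Accuracy is the percentage of optimal responses (higher-ranked symbol chosen,
regardless of the realised outcome).  Choose-X is the percentage of the
presentations of symbol X on which it was selected — in a 6-repetition
transfer phase each symbol appears in 5 pairings, so 30 presentations —
and Avoid-X is its complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import LEARNING_PAIRS, PAIR_OF, SYMBOLS

THRESHOLD_RULES = ("overall", "gain_pair", "loss_pair", "last10_gain", "last10_loss", "any")
LEARNER_CUTOFF_PCT = 60.0  # strict: accuracy must exceed this


@dataclass(frozen=True)
class SubjectMeta:
    subject: str
    order: str            # "drug_first" | "placebo_first"
    weight_kg: float
    dose_mg: float = 150.0
    age: float | None = None
    moca: float | None = None

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be positive")
        if self.dose_mg < 0:
            raise ValueError("dose must be non-negative")


def weight_adjusted_dose(meta: SubjectMeta) -> float:
    """Administered dose divided by body weight, in mg/kg."""
    return meta.dose_mg / meta.weight_kg


def accuracy_pct(trials: pd.DataFrame, phase: str) -> float:
    """Percent optimal responses in ``phase``; NaN when the phase is absent."""
    sub = trials[(trials["phase"] == phase) & trials["chosen"].notna()]
    if sub.empty:
        return float("nan")
    return 100.0 * sub["optimal"].mean()


def choose_pct(trials: pd.DataFrame, symbol: str, phase: str) -> float:
    """100 * times chosen / times seen for ``symbol`` in ``phase``; NaN if never shown."""
    sub = trials[(trials["phase"] == phase) & trials["chosen"].notna()]
    seen = sub[(sub["left_symbol"] == symbol) | (sub["right_symbol"] == symbol)]
    if seen.empty:
        return float("nan")
    return 100.0 * (seen["chosen"] == symbol).mean()


def avoid_pct(trials: pd.DataFrame, symbol: str, phase: str) -> float:
    return 100.0 - choose_pct(trials, symbol, phase)


def choice_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy per subject x condition x phase table of accuracy and per-symbol
    choose%/avoid%.  Phases a subject is missing are simply absent rows."""
    rows = []
    for (subject, condition, phase), grp in trials.groupby(
        ["subject", "condition", "phase"], sort=True
    ):
        row = {"subject": subject, "condition": condition, "phase": phase,
               "accuracy": accuracy_pct(grp, phase)}
        for s in SYMBOLS:
            c = choose_pct(grp, s, phase)
            row[f"choose_{s}"] = c
            row[f"avoid_{s}"] = 100.0 - c
        rows.append(row)
    return pd.DataFrame(rows)


def _pair_accuracy(learning: pd.DataFrame, pair: tuple[str, str], last_n: int | None = None) -> float:
    mask = learning["left_symbol"].isin(pair) & learning["right_symbol"].isin(pair)
    sub = learning[mask]
    if last_n is not None:
        sub = sub.tail(last_n)  # final presentations pooled across blocks
    if sub.empty:
        return float("nan")
    return 100.0 * sub["optimal"].mean()


def learning_accuracy(trials: pd.DataFrame, rule: str) -> float:
    """Learning-phase accuracy under one thresholding rule for a single
    subject-condition table."""
    learning = trials[(trials["phase"] == "learning") & trials["chosen"].notna()]
    learning = learning.sort_values(["block", "trial_index"])  # "last 10" needs trial order
    gain, _, loss = LEARNING_PAIRS
    if rule == "overall":
        return 100.0 * learning["optimal"].mean() if len(learning) else float("nan")
    if rule == "gain_pair":
        return _pair_accuracy(learning, gain)
    if rule == "loss_pair":
        return _pair_accuracy(learning, loss)
    if rule == "last10_gain":
        return _pair_accuracy(learning, gain, last_n=10)
    if rule == "last10_loss":
        return _pair_accuracy(learning, loss, last_n=10)
    raise ValueError(f"unknown rule {rule!r}")


def threshold_learners(trials: pd.DataFrame, rule: str = "any") -> list[tuple[str, str]]:
    """Subject-condition units whose learning accuracy strictly exceeds 60%
    under ``rule``; "any" accepts units passing at least one of the five rules."""
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown rule {rule!r}; valid: {THRESHOLD_RULES}")
    rules = THRESHOLD_RULES[:-1] if rule == "any" else (rule,)
    keep = []
    for (subject, condition), grp in trials.groupby(["subject", "condition"], sort=True):
        accs = [learning_accuracy(grp, r) for r in rules]
        if any(np.isfinite(a) and a > LEARNER_CUTOFF_PCT for a in accs):
            keep.append((subject, condition))
    return keep
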