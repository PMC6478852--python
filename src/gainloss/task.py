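"""The GainLoss instrumental learning task.

Six symbols (A-F) are arranged in three fixed pairs: a Gain pair (A, B), a
Look pair (C, D) and a Loss pair (E, F).  Each symbol yields its pair's
salient outcome (GAIN +1, LOOK 0, LOSE -1) with probability 0.8 or 0.2 and
NOTHING (0) otherwise.  Learning trials present a pair, the agent picks a
symbol and sees a probabilistic outcome; feedback-free choice phases present
all 15 pairings of the six symbols with no outcome shown.

Rewards are coded in dimensionless units {-1, 0, +1} (one unit = one 20p
coin); LOOK carries no monetary value and is coded 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

SYMBOLS = ("A", "B", "C", "D", "E", "F")
PAIR_OF = {"A": "Gain", "B": "Gain", "C": "Look", "D": "Look", "E": "Loss", "F": "Loss"}
LEARNING_PAIRS = (("A", "B"), ("C", "D"), ("E", "F"))

# Strict preference order used for optimal-response coding.  Within each pair
# the 80%-salient member of Gain/Look wins and the 80%-loss member of Loss
# loses; across pairs Gain beats Look beats Loss.  The Look-pair ranking
# (C over D) is a convention, not an expected-value difference.
OPTIMALITY_RANK = {s: i for i, s in enumerate(SYMBOLS)}

PHASES = ("practice", "learning", "choice0", "choice30", "choice24h")
CHOICE_PHASES = ("choice0", "choice30", "choice24h")

_SALIENT = {"Gain": ("GAIN", 1), "Look": ("LOOK", 0), "Loss": ("LOSE", -1)}
# 80%-salient symbols: A (GAIN), C (LOOK), F (LOSE); their pair-mates get 20%.
_P_SALIENT = {"A": 0.8, "B": 0.2, "C": 0.8, "D": 0.2, "E": 0.2, "F": 0.8}


class ConfigurationError(ValueError):
    """Raised for unknown condition tags or malformed task configuration."""


@dataclass(frozen=True)
class Contingency:
    """Outcome law for one symbol: salient outcome with ``p_salient``, else NOTHING."""

    symbol_id: str
    pair_id: str
    p_salient: float
    salient_outcome: str
    salient_value: int

    def __post_init__(self) -> None:
        if self.p_salient not in (0.8, 0.2):
            raise ConfigurationError(f"p_salient must be 0.8 or 0.2, got {self.p_salient}")
        expected = {"GAIN": 1, "LOOK": 0, "LOSE": -1}[self.salient_outcome]
        if self.salient_value != expected:
            raise ConfigurationError(
                f"salient_value {self.salient_value} inconsistent with {self.salient_outcome}"
            )


@dataclass(frozen=True)
class SymbolSet:
    """The six contingencies for one condition (distinct stimuli per condition)."""

    condition: str
    contingencies: dict[str, Contingency] = field(repr=False)

    def __getitem__(self, symbol: str) -> Contingency:
        return self.contingencies[symbol]


def make_symbol_set(condition_tag: str, known_conditions: Iterable[str] = ("drug", "placebo")) -> SymbolSet:
    """Build the standard six-symbol contingency set for one condition.

    The contingencies are identical across conditions; the tag records which
    (physically distinct) stimulus set a condition used.
    """
    if condition_tag not in tuple(known_conditions):
        raise ConfigurationError(f"unknown condition tag {condition_tag!r}")
    cont = {}
    for s in SYMBOLS:
        pair = PAIR_OF[s]
        outcome, value = _SALIENT[pair]
        cont[s] = Contingency(s, pair, _P_SALIENT[s], outcome, value)
    return SymbolSet(condition_tag, cont)


@dataclass
class TrialRecord:
    """One trial: schedule slot plus (once played) choice, outcome and coding."""

    phase: str
    block: int
    trial_index: int
    left: str
    right: str
    chosen: str | None = None
    outcome: str | None = None  # None on feedback-free choice phases
    reward: float | None = None
    optimal: bool | None = None

    @property
    def pair(self) -> tuple[str, str]:
        return (self.left, self.right)


def _shuffled_pairs(pairs: list[tuple[str, str]], rng: np.random.Generator) -> list[tuple[str, str]]:
    order = rng.permutation(len(pairs))
    out = []
    for i in order:
        a, b = pairs[i]
        out.append((a, b) if rng.random() < 0.5 else (b, a))  # left/right randomised
    return out


def build_learning_schedule(
    n_blocks: int, trials_per_pair: int, rng: np.random.Generator, phase: str = "learning"
) -> list[TrialRecord]:
    """Blocked learning schedule: each block holds ``trials_per_pair`` of each
    learning pair (AB, CD, EF) in shuffled order with random left/right placement.
    """
    if n_blocks < 1 or trials_per_pair < 1:
        raise ValueError("n_blocks and trials_per_pair must be positive")
    trials = []
    idx = 0
    for b in range(n_blocks):
        pairs = [p for p in LEARNING_PAIRS for _ in range(trials_per_pair)]
        for left, right in _shuffled_pairs(pairs, rng):
            trials.append(TrialRecord(phase, b, idx, left, right))
            idx += 1
    return trials


def build_choice_schedule(
    symbol_set: SymbolSet, reps: int, rng: np.random.Generator, phase: str = "choice24h"
) -> list[TrialRecord]:
    """Feedback-free choice schedule: every unordered pair of distinct symbols
    exactly ``reps`` times (15 pairs, so reps=6 gives 90 trials)."""
    if reps < 1:
        raise ValueError("reps must be positive")
    pairs = [p for p in combinations(SYMBOLS, 2) for _ in range(reps)]
    return [
        TrialRecord(phase, 0, i, left, right)
        for i, (left, right) in enumerate(_shuffled_pairs(pairs, rng))
    ]


def sample_outcome(contingency: Contingency, rng: np.random.Generator) -> tuple[str, int]:
    """Draw one probabilistic outcome: salient with p_salient, else NOTHING (0)."""
    if rng.random() < contingency.p_salient:
        return contingency.salient_outcome, contingency.salient_value
    return "NOTHING", 0


def exact_mix_outcomes(
    contingency: Contingency, n: int, rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Shuffled outcome list with the salient/NOTHING ratio exact in ``n`` draws.

    Alternative to i.i.d. :func:`sample_outcome` for schedules that hold the
    realised outcome mix fixed within a block.
    """
    n_salient = int(round(contingency.p_salient * n))
    outcomes = [(contingency.salient_outcome, contingency.salient_value)] * n_salient
    outcomes += [("NOTHING", 0)] * (n - n_salient)
    return [outcomes[i] for i in rng.permutation(n)]


def expected_value(contingency: Contingency) -> float:
    """Probability-weighted outcome value; the complement NOTHING is worth 0."""
    return contingency.p_salient * contingency.salient_value


def is_optimal(pair: tuple[str, str], chosen: str) -> bool:
    """Whether ``chosen`` is the preferred member of ``pair`` under the task's
    strict order A > B > C > D > E > F.

    The coding depends only on the symbols shown, never on the realised
    outcome.  Look symbols rank above Loss and below Gain symbols; within the
    Look pair the 80%-LOOK symbol C is treated as preferable to D.
    """
    if chosen not in pair:
        raise ValueError(f"chosen symbol {chosen!r} not in pair {pair}")
    other = pair[0] if chosen == pair[1] else pair[1]
    return OPTIMALITY_RANK[chosen] < OPTIMALITY_RANK[other]


# ---------------------------------------------------------------------------
# Tidy-table serialisation

COLUMNS = [
    "subject", "condition", "phase", "block", "trial_index",
    "left_symbol", "right_symbol", "chosen", "outcome", "reward", "optimal",
]


def trials_to_frame(trials: list[TrialRecord], subject: str = "", condition: str = "") -> pd.DataFrame:
    rows = [
        {
            "subject": subject,
            "condition": condition,
            "phase": t.phase,
            "block": t.block,
            "trial_index": t.trial_index,
            "left_symbol": t.left,
            "right_symbol": t.right,
            "chosen": t.chosen,
            "outcome": t.outcome,
            "reward": t.reward,
            "optimal": t.optimal,
        }
        for t in trials
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    """Inverse of :func:`trials_to_frame` for one subject-condition table."""
    trials = []
    for row in df.itertuples(index=False):
        for sym in (row.left_symbol, row.right_symbol):
            if sym not in SYMBOLS:
                raise ValueError(f"unknown symbol {sym!r} at trial_index {row.trial_index}")
        chosen = None if pd.isna(row.chosen) else row.chosen
        trials.append(
            TrialRecord(
                phase=row.phase,
                block=int(row.block),
                trial_index=int(row.trial_index),
                left=row.left_symbol,
                right=row.right_symbol,
                chosen=chosen,
                outcome=None if pd.isna(row.outcome) else row.outcome,
                reward=None if pd.isna(row.reward) else float(row.reward),
                optimal=None if chosen is None else is_optimal((row.left_symbol, row.right_symbol), chosen),
            )
        )
    return trials
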