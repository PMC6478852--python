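"""Trial-level reinforcement-learning models for the GainLoss task.

Two generative models are provided, each exposing simulation and an exact
choice log-likelihood:

* **Dual-learning-rate Q-learning.**  Per-symbol action values Q start at 0
  and update from the reward prediction error delta = r - Q(chosen), with a
  separate learning rate for positive (alpha_pos) and negative (alpha_neg)
  errors.  Choices are softmax over beta * Q of the two symbols shown, with a
  day-1 inverse temperature (beta) for learning trials and a separate day-2
  temperature (beta_day2) for the 24-hour feedback-free phase.

* **OpAL** (opponent actor-learning).  A critic V tracks value; two Hebbian
  actors accumulate evidence for approach (G) and avoidance (N):
  V += alpha_c * delta, G += alpha_g * G * delta, N += alpha_n * N * (-delta).
  Choice combines the actors as beta_g * G - beta_n * N with day-1 and day-2
  gain pairs.

Feedback-free choice trials never update values; values are frozen at the end
of learning.  By default the likelihood covers day-1 learning trials and the
24-hour choice phase only (the phases the day-1 / day-2 parameter split is
fit to); the 0-minute and 30-minute phases can optionally be scored under the
day-1 temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from typing import Sequence

import numpy as np

from .task import (
    SYMBOLS,
    SymbolSet,
    TrialRecord,
    is_optimal,
    sample_outcome,
)

_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
_GN_FLOOR = 1e-6  # keeps the Hebbian actor weights positive

MODELLED_PHASES_DEFAULT = ("learning", "choice24h")


def softmax_probs(values: Sequence[float], inverse_temperature: float) -> np.ndarray:
    """Softmax choice probabilities, numerically stabilised by max-subtraction."""
    if inverse_temperature < 0:
        raise ValueError("inverse temperature must be non-negative")
    z = inverse_temperature * np.asarray(values, dtype=float)
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


@dataclass
class QLearningParams:
    alpha_pos: float = 0.3  # learning rate, positive prediction errors
    alpha_neg: float = 0.3  # learning rate, negative prediction errors
    beta: float = 2.0       # day-1 softmax inverse temperature
    beta_day2: float = 2.0  # 24-hour choice-phase inverse temperature

    def validate(self) -> None:
        for a in (self.alpha_pos, self.alpha_neg):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"learning rates must be in [0, 1], got {a}")
        for b in (self.beta, self.beta_day2):
            if not (np.isfinite(b) and b >= 0):
                raise ValueError(f"inverse temperatures must be finite and >= 0, got {b}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QLearningParams":
        return cls(**{f.name: d[f.name] for f in fields(cls)})


@dataclass
class OpALParams:
    alpha_g: float = 0.3       # Go-actor learning rate
    alpha_n: float = 0.3       # NoGo-actor learning rate
    beta_g: float = 1.0        # day-1 approach gain
    beta_n: float = 1.0        # day-1 avoidance gain
    beta_g_day2: float = 1.0   # day-2 approach gain
    beta_n_day2: float = 1.0   # day-2 avoidance gain
    alpha_c: float | None = None  # critic rate; None ties it to (alpha_g + alpha_n)/2

    @property
    def critic_rate(self) -> float:
        return 0.5 * (self.alpha_g + self.alpha_n) if self.alpha_c is None else self.alpha_c

    def validate(self) -> None:
        for a in (self.alpha_g, self.alpha_n, self.critic_rate):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"learning rates must be in [0, 1], got {a}")
        for b in (self.beta_g, self.beta_n, self.beta_g_day2, self.beta_n_day2):
            if not (np.isfinite(b) and b >= 0):
                raise ValueError(f"choice gains must be finite and >= 0, got {b}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "OpALParams":
        return cls(**{f.name: d[f.name] for f in fields(cls)})


@dataclass
class ModelState:
    """Latent values: Q for Q-learning; V plus actor weights G, N for OpAL."""

    q: np.ndarray | None = None
    v: np.ndarray | None = None
    g: np.ndarray | None = None
    n: np.ndarray | None = None
    last_delta: float = 0.0


class QLearningModel:
    """Dual-learning-rate delta-rule model with per-phase inverse temperatures."""

    name = "qlearning"
    params_cls = QLearningParams
    n_free_params = 4

    def init_state(self) -> ModelState:
        return ModelState(q=np.zeros(len(SYMBOLS)))

    def update(self, state: ModelState, chosen: str, reward: float, params: QLearningParams) -> ModelState:
        i = _SYM_INDEX[chosen]
        delta = reward - state.q[i]
        alpha = params.alpha_pos if delta > 0 else params.alpha_neg
        state.q[i] += alpha * delta
        state.last_delta = delta
        return state

    def action_strength(self, state: ModelState, symbol: str, params: QLearningParams, phase: str) -> float:
        return self._phase_beta(params, phase) * state.q[_SYM_INDEX[symbol]]

    @staticmethod
    def _phase_beta(params: QLearningParams, phase: str) -> float:
        if phase == "choice24h":
            return params.beta_day2
        if phase in ("practice", "learning", "choice0", "choice30"):
            return params.beta
        raise ValueError(f"unknown phase {phase!r}")

    def choice_probs(self, state: ModelState, pair: tuple[str, str], params: QLearningParams, phase: str) -> np.ndarray:
        beta = self._phase_beta(params, phase)
        vals = [state.q[_SYM_INDEX[s]] for s in pair]
        return softmax_probs(vals, beta)


class OpALModel:
    """Opponent actor-learning: critic V plus Go/NoGo actors with separate gains."""

    name = "opal"
    params_cls = OpALParams
    n_free_params = 6

    def init_state(self) -> ModelState:
        k = len(SYMBOLS)
        return ModelState(v=np.zeros(k), g=np.ones(k), n=np.ones(k))

    def update(self, state: ModelState, chosen: str, reward: float, params: OpALParams) -> ModelState:
        i = _SYM_INDEX[chosen]
        delta = reward - state.v[i]
        state.v[i] += params.critic_rate * delta
        state.g[i] = max(state.g[i] + params.alpha_g * state.g[i] * delta, _GN_FLOOR)
        state.n[i] = max(state.n[i] + params.alpha_n * state.n[i] * (-delta), _GN_FLOOR)
        state.last_delta = delta
        return state

    @staticmethod
    def _phase_gains(params: OpALParams, phase: str) -> tuple[float, float]:
        if phase == "choice24h":
            return params.beta_g_day2, params.beta_n_day2
        if phase in ("practice", "learning", "choice0", "choice30"):
            return params.beta_g, params.beta_n
        raise ValueError(f"unknown phase {phase!r}")

    def action_strength(self, state: ModelState, symbol: str, params: OpALParams, phase: str) -> float:
        bg, bn = self._phase_gains(params, phase)
        i = _SYM_INDEX[symbol]
        return bg * state.g[i] - bn * state.n[i]

    def choice_probs(self, state: ModelState, pair: tuple[str, str], params: OpALParams, phase: str) -> np.ndarray:
        acts = [self.action_strength(state, s, params, phase) for s in pair]
        return softmax_probs(acts, 1.0)  # gains already scale the actors


MODELS = {m.name: m for m in (QLearningModel(), OpALModel())}


def get_model(name: str):
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; registered: {sorted(MODELS)}") from None


# ---------------------------------------------------------------------------
# Likelihood


class TrialDataError(ValueError):
    """Raised when a trial sequence is unordered or references unknown symbols."""


def _check_order(trials: Sequence[TrialRecord]) -> None:
    phase_rank = {"practice": 0, "learning": 1, "choice0": 2, "choice30": 3, "choice24h": 4}
    last = -1
    for t in trials:
        if t.phase not in phase_rank:
            raise TrialDataError(f"unknown phase {t.phase!r}")
        r = phase_rank[t.phase]
        if r < last:
            raise TrialDataError("trials are not in chronological phase order")
        last = r
        for s in (t.left, t.right):
            if s not in _SYM_INDEX:
                raise TrialDataError(f"unknown symbol {s!r}")


def negative_log_likelihood(
    model,
    params,
    trials: Sequence[TrialRecord],
    modelled_phases: Sequence[str] = MODELLED_PHASES_DEFAULT,
) -> float:
    """Exact -sum log P(chosen_t | state_t) over the modelled phases.

    Values update only on learning-phase trials (feedback shown); choice-phase
    trials are scored with values frozen at the end of learning.  Trials whose
    phase is outside ``modelled_phases`` contribute no likelihood term, but
    learning trials always update values.
    """
    _check_order(trials)
    state = model.init_state()
    nll = 0.0
    for t in trials:
        if t.chosen is None:
            continue
        if t.phase in modelled_phases:
            p = model.choice_probs(state, t.pair, params, t.phase)
            p_chosen = p[0] if t.chosen == t.left else p[1]
            nll -= np.log(max(p_chosen, 1e-300))
        if t.phase == "learning" and t.reward is not None:
            model.update(state, t.chosen, t.reward, params)
    return float(nll)


def simulate_agent(
    model,
    params,
    schedules: Sequence[TrialRecord],
    symbol_set: SymbolSet,
    rng: np.random.Generator,
) -> list[TrialRecord]:
    """Play the given schedule with softmax choices; sample outcomes and update
    values on practice/learning trials only.  Returns completed records.

    Practice trials use a throwaway state (distinct practice stimuli) so they
    do not seed the learning-block values.
    """
    state = model.init_state()
    practice_state = model.init_state()
    out = []
    for t in schedules:
        st = practice_state if t.phase == "practice" else state
        p = model.choice_probs(st, t.pair, params, t.phase)
        chosen = t.left if rng.random() < p[0] else t.right
        rec = TrialRecord(t.phase, t.block, t.trial_index, t.left, t.right, chosen=chosen)
        rec.optimal = is_optimal(rec.pair, chosen)
        if t.phase in ("practice", "learning"):
            outcome, reward = sample_outcome(symbol_set[chosen], rng)
            rec.outcome, rec.reward = outcome, float(reward)
            model.update(st, chosen, reward, params)
        out.append(rec)
    return out
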