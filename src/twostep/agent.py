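"""Seven-parameter hybrid model-based / model-free agent.

First-stage choices combine two valuation systems. The model-free system
caches values ``Q_mf`` for the two rockets and updates the chosen one with
two prediction errors, both computed before any update on the trial:

    Q_mf <- Q_mf + alpha1 * (Q_s2_chosen - Q_mf) + alpha21 * (r - Q_s2_chosen)

alpha1 scales the state-transition error (value of the reached second-stage
option minus the cached first-stage value); alpha21 scales the contribution
of the second-stage reward prediction error to the first stage (an
eligibility-trace term, equivalent to alpha1*lambda in the classic
parameterization). The model-based system evaluates each rocket
prospectively through the known transition structure:

    Q_mb(rocket 1) = p_common * max(Q3, Q4) + (1 - p_common) * max(Q5, Q6)

(and symmetrically for rocket 2); transition probabilities are fixed, not
learned. The systems are combined additively, Q_hybrid = beta_mb * Q_mb +
beta_mf * Q_mf, and the first-stage choice is a logistic in the hybrid value
difference plus a perseveration term pi * C, where C is +1 / -1 toward
repeating the previous rocket (0 before the first completed trial). Second
stage: Q values update by a plain delta rule with rate alpha2, and choices
are logistic with inverse temperature beta2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import task as task_mod
from ._likelihood import loglik_core
from .task import PAIR_OF_STATE, RewardWalk, SessionData, TaskConfig, TrialRecord

__all__ = [
    "PARAM_NAMES",
    "AgentParams",
    "AgentState",
    "compute_mb_values",
    "first_stage_choice_prob",
    "second_stage_choice_prob",
    "update_after_trial",
    "simulate_session",
    "session_loglik",
    "Q_INIT_DEFAULT",
]

PARAM_NAMES = ("alpha1", "alpha21", "alpha2", "beta_mb", "beta_mf", "beta2", "pi")

#: initial Q value for all stimuli: midpoint of the reward-probability range
Q_INIT_DEFAULT = 0.5


class LikelihoodError(FloatingPointError):
    """Raised when a likelihood evaluates to a non-finite value."""


@dataclass(frozen=True)
class AgentParams:
    """The seven free parameters of the hybrid agent.

    alpha1, alpha21, alpha2 are learning rates in [0, 1]; beta_mb, beta_mf
    and beta2 are non-negative weights / inverse temperature; pi (choice
    perseveration) is an unbounded real.
    """

    alpha1: float
    alpha21: float
    alpha2: float
    beta_mb: float
    beta_mf: float
    beta2: float
    pi: float

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha21", "alpha2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("beta_mb", "beta_mf", "beta2"):
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not math.isfinite(self.pi):
            raise ValueError(f"pi must be finite, got {self.pi}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "AgentParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (7,):
            raise ValueError(f"expected 7 values, got shape {values.shape}")
        return cls(**dict(zip(PARAM_NAMES, values)))


@dataclass
class AgentState:
    """Evolving learning state: cached MF values, second-stage values, and
    the last completed first-stage choice (None before the first)."""

    q_mf: np.ndarray = field(default_factory=lambda: np.full(2, Q_INIT_DEFAULT))
    q_s2: np.ndarray = field(default_factory=lambda: np.full(4, Q_INIT_DEFAULT))
    prev_choice1: Optional[int] = None

    def copy(self) -> "AgentState":
        return AgentState(self.q_mf.copy(), self.q_s2.copy(), self.prev_choice1)


def compute_mb_values(q_s2: Sequence[float], p_common: float) -> Tuple[float, float]:
    """Prospective values of the two rockets given four second-stage values.

    Pure function: Q1 = p * max(Q3, Q4) + (1-p) * max(Q5, Q6) and Q2 with
    the transition weights swapped.
    """
    q3, q4, q5, q6 = (float(v) for v in q_s2)
    m_a = max(q3, q4)
    m_b = max(q5, q6)
    return (p_common * m_a + (1.0 - p_common) * m_b, (1.0 - p_common) * m_a + p_common * m_b)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def first_stage_choice_prob(state: AgentState, params: AgentParams, p_common: float = 0.70) -> float:
    """Probability of choosing rocket 1, combining both systems plus
    perseveration; strictly inside (0, 1)."""
    q_mb1, q_mb2 = compute_mb_values(state.q_s2, p_common)
    q_h1 = params.beta_mb * q_mb1 + params.beta_mf * float(state.q_mf[0])
    q_h2 = params.beta_mb * q_mb2 + params.beta_mf * float(state.q_mf[1])
    if state.prev_choice1 is None:
        c = 0.0
    else:
        c = 1.0 if state.prev_choice1 == 1 else -1.0
    return _sigmoid((q_h1 - q_h2) + params.pi * c)


def second_stage_choice_prob(q_pair: Sequence[float], beta2: float) -> float:
    """Probability of choosing the lower-indexed stimulus of the visited pair."""
    q_left, q_right = (float(v) for v in q_pair)
    return _sigmoid(beta2 * (q_left - q_right))


def update_after_trial(state: AgentState, trial: TrialRecord, params: AgentParams) -> AgentState:
    """Return the post-trial learning state.

    Missed trials are a no-op: no value update, and the perseveration
    reference stays on the last completed trial. Otherwise only the chosen
    first-stage and chosen second-stage values change, both prediction
    errors using the pre-update chosen second-stage value.
    """
    new = state.copy()
    if trial.missed:
        return new
    i1 = trial.choice1 - 1
    i2 = trial.choice2 - 3
    q_c2 = float(state.q_s2[i2])
    r = float(trial.reward)
    new.q_mf[i1] += params.alpha1 * (q_c2 - new.q_mf[i1]) + params.alpha21 * (r - q_c2)
    new.q_s2[i2] += params.alpha2 * (r - q_c2)
    new.prev_choice1 = trial.choice1
    return new


def simulate_session(
    params: AgentParams,
    walk: RewardWalk,
    config: TaskConfig,
    seed: int,
    subject_id: str = "sim",
    condition: str = "sim",
    missed: Optional[np.ndarray] = None,
    q_init: float = Q_INIT_DEFAULT,
) -> SessionData:
    """Simulate one session of the agent playing the task.

    Choices are sampled from the two softmax rules, transitions from the
    p_common structure, and rewards as Bernoulli draws with the walk's
    probability of the chosen second-stage stimulus. ``missed`` optionally
    marks trials as aborted; on those trials nothing is sampled and no
    learning occurs. Deterministic for a fixed seed.
    """
    if walk.n_trials < config.n_trials:
        raise ValueError(f"walk has {walk.n_trials} trials, need {config.n_trials}")
    rng = np.random.default_rng(seed)
    if missed is None:
        missed = np.zeros(config.n_trials, dtype=bool)
    missed = np.asarray(missed, dtype=bool)
    state = AgentState(np.full(2, q_init), np.full(4, q_init), None)

    rows: list = []
    for t in range(config.n_trials):
        if missed[t]:
            rows.append((t + 1, pd.NA, pd.NA, pd.NA, pd.NA, pd.NA, True))
            continue
        p1 = first_stage_choice_prob(state, params, config.p_common)
        choice1 = 1 if rng.random() < p1 else 2
        state2 = task_mod.sample_transition(choice1, config, rng)
        pair = PAIR_OF_STATE[state2]
        i_left = pair[0] - 3
        p_left = second_stage_choice_prob((state.q_s2[i_left], state.q_s2[i_left + 1]), params.beta2)
        choice2 = pair[0] if rng.random() < p_left else pair[1]
        reward = int(rng.random() < walk.prob(t, choice2))
        rec = TrialRecord(
            index=t + 1,
            choice1=choice1,
            state2=state2,
            choice2=choice2,
            transition=task_mod.transition_label(choice1, state2),
            reward=reward,
            missed=False,
        )
        rows.append((t + 1, choice1, state2, choice2, rec.transition, reward, False))
        state = update_after_trial(state, rec, params)
    trials = pd.DataFrame(rows, columns=task_mod.SESSION_COLUMNS)
    trials["choice1"] = trials["choice1"].astype("Int64")
    trials["choice2"] = trials["choice2"].astype("Int64")
    trials["reward"] = trials["reward"].astype("Int64")
    trials["state2"] = trials["state2"].astype("string")
    trials["transition"] = trials["transition"].astype("string")
    trials["missed"] = trials["missed"].astype(bool)
    return SessionData(subject_id=subject_id, condition=condition, trials=trials, config=config)


def session_loglik(
    params: AgentParams, session: SessionData, q_init: float = Q_INIT_DEFAULT
) -> float:
    """Log-likelihood of all completed choices in a session.

    Sums log P(choice1) + log P(choice2) over non-missed trials under the
    sequential learning recursion; missed trials contribute zero. Raises
    :class:`LikelihoodError` on a non-finite result.
    """
    arrays = session.to_arrays()
    ll = loglik_core(
        params.alpha1,
        params.alpha21,
        params.alpha2,
        params.beta_mb,
        params.beta_mf,
        params.beta2,
        params.pi,
        arrays["choice1"],
        arrays["state2"],
        arrays["choice2"],
        arrays["reward"],
        arrays["missed"],
        session.config.p_common,
        q_init,
    )
    if not math.isfinite(ll):
        raise LikelihoodError(f"non-finite log-likelihood for params {params}")
    return float(ll)
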