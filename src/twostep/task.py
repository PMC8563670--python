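"""Generative model of the two-step task environment.

The task has two first-stage stimuli ("rockets", coded 1 and 2). Each rocket
leads predominantly (probability ``p_common``) to one of two second-stage
states ("planets" A and B); rocket 1's dominant destination is state A,
rocket 2's is state B. Each second-stage state offers a choice between two
stimuli ("aliens"): state A holds stimuli {3, 4}, state B holds {5, 6}. Each
alien pays one point with a probability that drifts across trials as a
Gaussian random walk reflected into ``[walk_low, walk_high]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, NamedTuple, Optional

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "RewardWalk",
    "TrialRecord",
    "SessionData",
    "STATE_LABELS",
    "STATE_OF_CHOICE2",
    "PAIR_OF_STATE",
    "simulate_reward_walk",
    "sample_transition",
    "sample_transitions",
    "transition_label",
    "label_transitions",
]

STATE_LABELS = ("A", "B")
#: second-stage stimulus pair held by each state
PAIR_OF_STATE = {"A": (3, 4), "B": (5, 6)}
STATE_OF_CHOICE2 = {3: "A", 4: "A", 5: "B", 6: "B"}
#: dominant destination of each first-stage stimulus (fixed convention)
DOMINANT_STATE = {1: "A", 2: "B"}

SESSION_COLUMNS = ["trial", "choice1", "state2", "choice2", "transition", "reward", "missed"]


class InvalidConfigError(ValueError):
    """Raised when a TaskConfig violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Generative constants of the two-step environment.

    Parameters
    ----------
    n_trials
        Trials per session (default 201 = 3 blocks of 67).
    n_blocks, block_length
        Block structure; breaks carry no computational consequence (the
        reward walk and all learning state continue across blocks).
    p_common
        Probability of the common (dominant) transition.
    walk_low, walk_high
        Hard bounds of the reward-probability random walk.
    walk_sd
        Per-trial standard deviation of the Gaussian walk step.
    reward_value
        Points credited per rewarded trial.
    """

    n_trials: int = 201
    n_blocks: int = 3
    block_length: int = 67
    p_common: float = 0.70
    walk_low: float = 0.25
    walk_high: float = 0.75
    walk_sd: float = 0.025
    reward_value: int = 1

    def __post_init__(self) -> None:
        if self.n_blocks * self.block_length != self.n_trials:
            raise InvalidConfigError(
                f"n_blocks * block_length = {self.n_blocks * self.block_length} "
                f"!= n_trials = {self.n_trials}"
            )
        if not 0.5 < self.p_common < 1:
            raise InvalidConfigError(f"p_common must be in (0.5, 1), got {self.p_common}")
        if not 0 <= self.walk_low <= self.walk_high <= 1:
            raise InvalidConfigError(
                f"require 0 <= walk_low <= walk_high <= 1, got [{self.walk_low}, {self.walk_high}]"
            )
        if self.walk_sd < 0:
            raise InvalidConfigError(f"walk_sd must be >= 0, got {self.walk_sd}")


@dataclass(frozen=True)
class RewardWalk:
    """Per-trial reward probabilities of the four second-stage stimuli.

    ``probabilities`` has shape (n_trials, 4); column j holds the reward
    probability of stimulus 3 + j.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError(f"expected (n_trials, 4) array, got shape {p.shape}")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_trials(self) -> int:
        return self.probabilities.shape[0]

    def prob(self, trial_index: int, choice2: int) -> float:
        """Reward probability of ``choice2`` (3..6) on 0-based ``trial_index``."""
        return float(self.probabilities[trial_index, choice2 - 3])


class TrialRecord(NamedTuple):
    """One trial of behavior; fields are None on missed trials."""

    index: int
    choice1: Optional[int]
    state2: Optional[str]
    choice2: Optional[int]
    transition: Optional[str]
    reward: Optional[int]
    missed: bool


@dataclass
class SessionData:
    """One subject-session of trial-level behavior.

    ``trials`` is a DataFrame with columns trial (1-based), choice1 (1/2),
    state2 ('A'/'B'), choice2 (3..6), transition ('common'/'rare'), reward
    (0/1) and missed (bool); choice/state/reward cells are missing (NA) on
    missed trials.
    """

    subject_id: str
    condition: str
    trials: pd.DataFrame
    config: TaskConfig = field(default_factory=TaskConfig)

    def __post_init__(self) -> None:
        if len(self.trials) != self.config.n_trials:
            raise ValueError(
                f"session has {len(self.trials)} trials, config expects {self.config.n_trials}"
            )
        missing = [c for c in SESSION_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trials table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_completed(self) -> int:
        return int((~self.trials["missed"].astype(bool)).sum())

    def iter_trials(self) -> Iterator[TrialRecord]:
        for row in self.trials.itertuples(index=False):
            missed = bool(row.missed)
            yield TrialRecord(
                index=int(row.trial),
                choice1=None if missed else int(row.choice1),
                state2=None if missed else str(row.state2),
                choice2=None if missed else int(row.choice2),
                transition=None if missed or pd.isna(row.transition) else str(row.transition),
                reward=None if missed else int(row.reward),
                missed=missed,
            )

    def to_arrays(self) -> dict:
        """Integer-coded arrays for the fast likelihood kernel.

        choice1 in {0,1}, state2 in {0,1}, choice2 in {0..3} (stimulus - 3),
        reward in {0,1}; entries on missed trials are zero placeholders and
        must be ignored via the ``missed`` mask.
        """
        t = self.trials
        missed = t["missed"].to_numpy(dtype=bool)
        n = len(t)
        choice1 = np.zeros(n, dtype=np.int64)
        state2 = np.zeros(n, dtype=np.int64)
        choice2 = np.zeros(n, dtype=np.int64)
        reward = np.zeros(n, dtype=np.int64)
        ok = ~missed
        choice1[ok] = t.loc[ok, "choice1"].to_numpy(dtype=np.int64) - 1
        state2[ok] = (t.loc[ok, "state2"] == "B").to_numpy(dtype=np.int64)
        choice2[ok] = t.loc[ok, "choice2"].to_numpy(dtype=np.int64) - 3
        reward[ok] = t.loc[ok, "reward"].to_numpy(dtype=np.int64)
        return {
            "choice1": choice1,
            "state2": state2,
            "choice2": choice2,
            "reward": reward,
            "missed": missed,
        }


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by repeated reflection at both bounds."""
    width = hi - lo
    if width == 0:
        return np.full_like(x, lo)
    y = np.mod(x - lo, 2.0 * width)
    return lo + np.minimum(y, 2.0 * width - y)


def simulate_reward_walk(config: TaskConfig, seed: int, n_trials: Optional[int] = None) -> RewardWalk:
    """Simulate the reflected Gaussian random walk of reward probabilities.

    Each stimulus starts at an independent uniform draw within the bounds and
    evolves by zero-mean Gaussian steps of scale ``walk_sd``, reflected at
    ``walk_low`` and ``walk_high``. Deterministic for a fixed seed.
    """
    if config.walk_sd < 0:  # defensive; TaskConfig already validates
        raise InvalidConfigError("walk_sd must be >= 0")
    n = config.n_trials if n_trials is None else int(n_trials)
    rng = np.random.default_rng(seed)
    start = rng.uniform(config.walk_low, config.walk_high, size=4)
    steps = rng.normal(0.0, config.walk_sd, size=(n - 1, 4)) if n > 1 else np.zeros((0, 4))
    free = start + np.concatenate([np.zeros((1, 4)), np.cumsum(steps, axis=0)], axis=0)
    return RewardWalk(_fold(free, config.walk_low, config.walk_high))


def sample_transition(choice1: int, config: TaskConfig, rng: np.random.Generator) -> str:
    """Sample the second-stage state reached by ``choice1`` (1 or 2)."""
    if choice1 not in (1, 2):
        raise ValueError(f"choice1 must be 1 or 2, got {choice1}")
    dominant = DOMINANT_STATE[choice1]
    other = "B" if dominant == "A" else "A"
    return dominant if rng.random() < config.p_common else other


def sample_transitions(choices1: np.ndarray, config: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Vectorized transition sampling; returns an array of 'A'/'B' labels."""
    choices1 = np.asarray(choices1)
    common = rng.random(choices1.shape) < config.p_common
    dominant = np.where(choices1 == 1, "A", "B")
    other = np.where(choices1 == 1, "B", "A")
    return np.where(common, dominant, other)


def transition_label(choice1: int, state2: str) -> str:
    """'common' if state2 is the dominant destination of choice1, else 'rare'."""
    if state2 not in STATE_LABELS:
        raise ValueError(f"unknown state code {state2!r}")
    return "common" if DOMINANT_STATE[choice1] == state2 else "rare"


def label_transitions(session: SessionData) -> SessionData:
    """Return a copy of the session with the transition column filled in.

    Missed trials keep a missing transition.
    """
    trials = session.trials.copy()
    labels: list = []
    for row in trials.itertuples(index=False):
        if bool(row.missed):
            labels.append(pd.NA)
            continue
        state2 = str(row.state2)
        if state2 not in STATE_LABELS:
            raise ValueError(f"unknown state code {state2!r} at trial {row.trial}")
        labels.append(transition_label(int(row.choice1), state2))
    trials["transition"] = labels
    return replace(session, trials=trials)


def empty_trials(n_trials: int) -> pd.DataFrame:
    """All-missed trial table scaffold used by the simulators."""
    return pd.DataFrame(
        {
            "trial": np.arange(1, n_trials + 1),
            "choice1": pd.array([pd.NA] * n_trials, dtype="Int64"),
            "state2": pd.array([pd.NA] * n_trials, dtype="string"),
            "choice2": pd.array([pd.NA] * n_trials, dtype="Int64"),
            "transition": pd.array([pd.NA] * n_trials, dtype="string"),
            "reward": pd.array([pd.NA] * n_trials, dtype="Int64"),
            "missed": np.ones(n_trials, dtype=bool),
        }
    )
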