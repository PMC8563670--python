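"""Synthetic paired-design cohorts emulating the study's structure.

Each subject is tested in two conditions (default sated vs hungry), one
201-trial session per condition with an independent reward walk. Subject
parameters are drawn from Gaussians on the transformed scale; the second
condition adds a mean shift on selected parameters, expressed as a paired
Cohen's d. By default the hungry condition raises the first-stage learning
rate (d = 0.76 on alpha1's transform) and the eligibility contribution of
second-stage prediction errors (d = 0.52 on alpha21's transform). A small
fraction of trials (2.3 per 201 on average) is marked missed.

Variance decomposition: the declared population SD per parameter is split
between a stable subject-level component and a condition-level component,
controlled by ``condition_var_frac`` (default 0.5, i.e. each sd^2/2). The
marginal SD in either condition always equals the declared SD; the SD of
within-subject differences is sqrt(2 * frac) * sd, and the second
condition's mean shift of d * sqrt(2 * frac) * sd yields a paired Cohen's d
of exactly d in expectation. ``condition_var_frac = 0`` gives identical
parameters in both conditions (a strict null, only valid with zero
effects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .agent import PARAM_NAMES, AgentParams, simulate_session
from .recovery import DEFAULT_GENERATING, _child_seeds
from .task import SessionData, TaskConfig, simulate_reward_walk
from .transforms import from_gaussian_scale

__all__ = ["CohortSpec", "draw_cohort_parameters", "generate_cohort"]

#: per-parameter condition effects (paired Cohen's d on the transformed scale)
DEFAULT_EFFECT_D = np.array([0.76, 0.52, 0.0, 0.0, 0.0, 0.0, 0.0])


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic paired two-condition cohort."""

    n_subjects: int = 32
    conditions: Tuple[str, str] = ("sated", "hungry")
    baseline_mean: np.ndarray = field(default_factory=lambda: DEFAULT_GENERATING.mean.copy())
    baseline_sd: np.ndarray = field(default_factory=lambda: DEFAULT_GENERATING.sd.copy())
    effect_d: np.ndarray = field(default_factory=lambda: DEFAULT_EFFECT_D.copy())
    condition_var_frac: float = 0.5
    missed_rate: float = 2.3 / 201
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        for name in ("baseline_mean", "baseline_sd", "effect_d"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (7,):
                raise ValueError(f"{name} must hold 7 values")
            object.__setattr__(self, name, arr)
        if np.any(self.baseline_sd <= 0):
            raise ValueError("baseline_sd must be positive")
        if not 0 <= self.missed_rate < 1:
            raise ValueError("missed_rate must be in [0, 1)")
        if not 0 <= self.condition_var_frac <= 1:
            raise ValueError("condition_var_frac must be in [0, 1]")
        if self.condition_var_frac == 0 and np.any(self.effect_d != 0):
            raise ValueError(
                "a paired effect size is undefined without condition-level variance"
            )


def draw_cohort_parameters(spec: CohortSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Ground-truth parameter table: one row per subject-condition.

    The second condition's transformed means are shifted by
    ``effect_d * baseline_sd`` relative to the first (baseline) condition.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frac = spec.condition_var_frac
    sd_subject = spec.baseline_sd * np.sqrt(1.0 - frac)
    sd_cond = spec.baseline_sd * np.sqrt(frac)
    shift = spec.effect_d * np.sqrt(2.0 * frac) * spec.baseline_sd
    rows = []
    for i in range(spec.n_subjects):
        sid = f"S{i:03d}"
        subject_level = spec.baseline_mean + sd_subject * rng.standard_normal(7)
        for j, cond in enumerate(spec.conditions):
            theta = subject_level + (shift if j == 1 else 0.0) + sd_cond * rng.standard_normal(7)
            native = from_gaussian_scale(theta)
            row = {"subject_id": sid, "condition": cond}
            row.update({f"theta_{n}": theta[k] for k, n in enumerate(PARAM_NAMES)})
            row.update({n: getattr(native, n) for n in PARAM_NAMES})
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(
    spec: CohortSpec, config: Optional[TaskConfig] = None
) -> Tuple[List[SessionData], pd.DataFrame]:
    """Simulate the full paired cohort.

    Returns one session per subject-condition (independent reward walks,
    missed trials injected uniformly at ``missed_rate``) together with the
    ground-truth parameter table. Bit-for-bit reproducible from the spec's
    master seed.
    """
    config = config or TaskConfig()
    seeds = _child_seeds(spec.seed, 1 + 3 * spec.n_subjects * 2)
    truth = draw_cohort_parameters(spec, seeds[0])
    sessions: List[SessionData] = []
    k = 1
    for row in truth.itertuples(index=False):
        params = AgentParams(
            **{n: getattr(row, n) for n in PARAM_NAMES}
        )
        walk = simulate_reward_walk(config, seeds[k])
        miss_rng = np.random.default_rng(seeds[k + 1])
        missed = miss_rng.random(config.n_trials) < spec.missed_rate
        sessions.append(
            simulate_session(
                params,
                walk,
                config,
                seeds[k + 2],
                subject_id=row.subject_id,
                condition=row.condition,
                missed=missed,
            )
        )
        k += 3
    return sessions, truth
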