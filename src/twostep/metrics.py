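"""Model-agnostic behavioral statistics.

The one-trial-back stay-switch analysis conditions the probability of
repeating the previous first-stage choice on the previous trial's
transition-by-reward cell: Common-Rewarded (CR), Rare-Rewarded (RR),
Common-Unrewarded (CU), Rare-Unrewarded (RU). Two contrasts of the four
stay probabilities summarize strategy:

    MF = (P(stay|CR) + P(stay|RR)) - (P(stay|CU) + P(stay|RU))
    MB = (P(stay|CR) + P(stay|RU)) - (P(stay|CU) + P(stay|RR))

A reward main effect (MF index) is the signature of model-free control; a
reward-by-transition crossover (MB index) is the signature of model-based
control. Group-level tests are paired t-tests and, for the 2x2x2
(condition x transition x reward) within-subject design, a repeated-measures
ANOVA computed as paired-t contrasts (with two-level factors every effect F
equals the squared paired t on the corresponding contrast).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, NamedTuple, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .task import SessionData, label_transitions

__all__ = [
    "CELLS",
    "StayTable",
    "PairedTResult",
    "classify_trials",
    "stay_probabilities",
    "mf_mb_indices",
    "points_earned",
    "paired_t",
    "rm_anova_2x2x2",
    "stay_table_frame",
]

CELLS = ("CR", "RR", "CU", "RU")

#: (transition, reward) defining each cell
_CELL_OF = {("common", 1): "CR", ("rare", 1): "RR", ("common", 0): "CU", ("rare", 0): "RU"}


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass(frozen=True)
class StayTable:
    """Four conditional stay probabilities with their cell counts.

    ``p_stay[cell]`` is NaN when the cell holds no trial pairs.
    """

    p_stay: Mapping[str, float]
    n: Mapping[str, int]

    def as_series(self) -> pd.Series:
        data = {f"p_stay_{c}": self.p_stay[c] for c in CELLS}
        data.update({f"n_{c}": self.n[c] for c in CELLS})
        return pd.Series(data)

    def cell_means(self) -> np.ndarray:
        """(2, 2) array indexed [transition(common=0, rare=1), reward(no=0, yes=1)]."""
        return np.array(
            [
                [self.p_stay["CU"], self.p_stay["CR"]],
                [self.p_stay["RU"], self.p_stay["RR"]],
            ]
        )


class PairedTResult(NamedTuple):
    t: float
    df: int
    p: float
    d: float
    ci_low: float
    ci_high: float


def classify_trials(session: SessionData, drop_block_boundaries: bool = False) -> pd.DataFrame:
    """Label each trial by the previous trial's outcome cell and stay/switch.

    Trial t (t >= 2) is labeled by trial t-1's (transition, reward) pair and
    whether choice1 repeated. Pairs where either trial is missed are
    dropped; pairs spanning a block break are retained by default
    (``drop_block_boundaries`` excludes them). Returns a DataFrame with
    columns trial, cell, stay.
    """
    if session.trials["transition"].isna().mask(session.trials["missed"].astype(bool), False).any():
        session = label_transitions(session)
    t = session.trials
    block_len = session.config.block_length
    rows = []
    prev = None
    for row in t.itertuples(index=False):
        cur_missed = bool(row.missed)
        if prev is not None and not cur_missed and not bool(prev.missed):
            spans_break = drop_block_boundaries and int(prev.trial) % block_len == 0
            if not spans_break:
                cell = _CELL_OF[(str(prev.transition), int(prev.reward))]
                rows.append((int(row.trial), cell, int(row.choice1) == int(prev.choice1)))
        prev = row
    return pd.DataFrame(rows, columns=["trial", "cell", "stay"])


def stay_probabilities(session: SessionData) -> StayTable:
    """Conditional stay probabilities per outcome cell: stays / cell count."""
    labeled = classify_trials(session)
    p: Dict[str, float] = {}
    n: Dict[str, int] = {}
    for cell in CELLS:
        sub = labeled[labeled["cell"] == cell]
        n[cell] = len(sub)
        p[cell] = float(sub["stay"].mean()) if len(sub) else float("nan")
    return StayTable(p_stay=p, n=n)


def mf_mb_indices(table: StayTable) -> Tuple[float, float]:
    """Model-free and model-based indices from the four stay probabilities.

    MF contrasts reward vs no-reward; MB contrasts the reward-by-transition
    interaction. Both lie in [-2, 2]. Raises on an empty cell.
    """
    p = table.p_stay
    if any(np.isnan(p[c]) for c in CELLS):
        empty = [c for c in CELLS if np.isnan(p[c])]
        raise DegenerateInputError(f"stay probability undefined for cell(s) {empty}")
    mf = (p["CR"] + p["RR"]) - (p["CU"] + p["RU"])
    mb = (p["CR"] + p["RU"]) - (p["CU"] + p["RR"])
    return mf, mb


def points_earned(session: SessionData) -> int:
    """Total points: rewards times the per-reward point value, missed trials excluded."""
    t = session.trials
    ok = ~t["missed"].astype(bool)
    return int(t.loc[ok, "reward"].sum()) * session.config.reward_value


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Classical paired t-test with Cohen's d and the 95% CI of the difference.

    d = mean(diff) / sd(diff); CI from Student-t quantiles at df = n - 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples of size >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.all(diff == 0):
            # identical samples: no evidence of a difference
            return PairedTResult(t=0.0, df=len(x) - 1, p=1.0, d=0.0, ci_low=float(diff[0]), ci_high=float(diff[0]))
        raise DegenerateInputError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    n = len(x)
    df = n - 1
    d = float(diff.mean() / sd)
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(n)
    return PairedTResult(
        t=float(res.statistic),
        df=df,
        p=float(res.pvalue),
        d=d,
        ci_low=float(diff.mean() - half),
        ci_high=float(diff.mean() + half),
    )


# effect name -> +/-1 codes over (condition, transition, reward) axes
_EFFECTS = {
    "condition": (True, False, False),
    "transition": (False, True, False),
    "reward": (False, False, True),
    "condition x transition": (True, True, False),
    "condition x reward": (True, False, True),
    "transition x reward": (False, True, True),
    "condition x transition x reward": (True, True, True),
}


def rm_anova_2x2x2(
    stay_tables: Mapping[str, Mapping[str, StayTable]],
    conditions: Sequence[str],
) -> pd.DataFrame:
    """Three-way repeated-measures ANOVA on the stay probabilities.

    ``stay_tables[subject][condition]`` holds one StayTable per cell of the
    paired design. Every factor (condition, transition, reward) has two
    levels, so each main effect and interaction reduces to a one-sample t
    on the corresponding +/-1 contrast of the eight cell means per subject,
    with F = t^2, df = (1, n-1) and partial eta squared t^2 / (t^2 + df).
    Subjects missing a condition or with an empty cell are dropped with a
    warning.
    """
    if len(conditions) != 2:
        raise ValueError("exactly two conditions required")
    cubes = []
    for subject, per_cond in stay_tables.items():
        if any(c not in per_cond for c in conditions):
            warnings.warn(f"subject {subject} missing a condition; dropped")
            continue
        cube = np.stack([per_cond[c].cell_means() for c in conditions])  # (cond, trans, reward)
        if np.isnan(cube).any():
            warnings.warn(f"subject {subject} has an empty stay cell; dropped")
            continue
        cubes.append(cube)
    if len(cubes) < 2:
        raise DegenerateInputError("need at least two complete subjects")
    data = np.stack(cubes)  # (n, 2, 2, 2)
    n = data.shape[0]

    rows = []
    for effect, axes in _EFFECTS.items():
        code = np.ones((2, 2, 2))
        for ax, active in enumerate(axes):
            if active:
                sign = np.array([1.0, -1.0]).reshape([2 if k == ax else 1 for k in range(3)])
                code = code * sign
        contrast = (data * code).reshape(n, 8).sum(axis=1) / 4.0
        mean = contrast.mean()
        sd = contrast.std(ddof=1)
        df = n - 1
        if sd == 0:
            t_val, p = 0.0, 1.0
        else:
            t_val = float(mean / (sd / np.sqrt(n)))
            p = float(2 * stats.t.sf(abs(t_val), df))
        f_val = t_val**2
        pes = f_val / (f_val + df) if (f_val + df) > 0 else 0.0
        rows.append(
            {
                "effect": effect,
                "statistic": f_val,
                "df1": 1,
                "df2": df,
                "p": p,
                "partial_eta_sq": pes,
            }
        )
    return pd.DataFrame(rows)


def stay_table_frame(sessions: Sequence[SessionData]) -> pd.DataFrame:
    """Per-session stay tables and indices as one tidy table."""
    rows = []
    for s in sessions:
        tab = stay_probabilities(s)
        row = {"subject_id": s.subject_id, "condition": s.condition}
        row.update(tab.as_series().to_dict())
        try:
            mf, mb = mf_mb_indices(tab)
        except DegenerateInputError:
            mf, mb = float("nan"), float("nan")
        row["mf_index"] = mf
        row["mb_index"] = mb
        row["points"] = points_earned(s)
        rows.append(row)
    return pd.DataFrame(rows)
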