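"""Session CSV round-tripping, run configuration, and output helpers.

One flat CSV dialect is used everywhere: comma-separated, UTF-8, header
row, 1-based trial indices, one row per trial with columns subject_id,
condition, trial, choice1, state2, choice2, transition, reward, missed.
Missed trials keep their choice/state/reward cells empty. Output files
written by the pipeline carry the run-configuration hash in a leading
comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .task import (
    PAIR_OF_STATE,
    SESSION_COLUMNS,
    STATE_LABELS,
    SessionData,
    TaskConfig,
    label_transitions,
)

__all__ = [
    "SessionFormatError",
    "RunConfig",
    "read_sessions",
    "write_sessions",
    "load_run_config",
    "config_hash",
    "write_csv",
]

FILE_COLUMNS = ["subject_id", "condition"] + SESSION_COLUMNS


class SessionFormatError(ValueError):
    """Raised when a session file violates the declared schema."""


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-backed)."""

    seed: int
    outdir: str = "twostep_out"
    input_sessions: Optional[str] = None
    task: Dict[str, Any] = field(default_factory=dict)
    cohort: Dict[str, Any] = field(default_factory=dict)
    fit: Dict[str, Any] = field(default_factory=dict)
    recovery: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ValueError("an explicit integer seed is required")

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)


def load_run_config(path: Union[str, Path]) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError(f"config {path} is missing the required 'seed' field")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(**raw)


def config_hash(config: Union[RunConfig, Dict[str, Any]]) -> str:
    """Short stable hash of the analysis-relevant configuration.

    The output directory is excluded: two runs differing only in where
    results land are the same analysis.
    """
    obj = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    obj.pop("outdir", None)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: Union[str, Path], cfg_hash: Optional[str] = None) -> None:
    """Write a DataFrame as CSV, optionally with a config-hash comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def write_sessions(
    sessions: Sequence[SessionData], path: Union[str, Path], cfg_hash: Optional[str] = None
) -> None:
    """Write sessions to one flat CSV (lossless; missed cells left empty)."""
    frames = []
    for s in sessions:
        t = s.trials.copy()
        t.insert(0, "condition", s.condition)
        t.insert(0, "subject_id", s.subject_id)
        frames.append(t)
    write_csv(pd.concat(frames, ignore_index=True), path, cfg_hash)


def _check_row(i: int, row) -> None:
    if int(row.choice1) not in (1, 2):
        raise SessionFormatError(f"row {i}, column 'choice1': invalid code {row.choice1!r}")
    if str(row.state2) not in STATE_LABELS:
        raise SessionFormatError(f"row {i}, column 'state2': invalid code {row.state2!r}")
    if int(row.choice2) not in PAIR_OF_STATE[str(row.state2)]:
        raise SessionFormatError(
            f"row {i}, column 'choice2': stimulus {row.choice2!r} not in state {row.state2!r}"
        )
    if int(row.reward) not in (0, 1):
        raise SessionFormatError(f"row {i}, column 'reward': invalid value {row.reward!r}")


def read_sessions(
    path: Union[str, Path], config: Optional[TaskConfig] = None
) -> List[SessionData]:
    """Read sessions from the flat CSV schema.

    Validates codes row by row (errors name the offending row and column),
    fills missing transition labels from the fixed dominant mapping, and
    groups rows into one SessionData per (subject_id, condition). When no
    TaskConfig is given, a single-block config matching each session's
    trial count is inferred.
    """
    try:
        raw = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as e:
        raise SessionFormatError(f"{path}: empty or unreadable CSV") from e
    missing = [c for c in FILE_COLUMNS if c not in raw.columns]
    if missing:
        raise SessionFormatError(f"{path}: missing columns {missing}")
    if raw.empty:
        return []

    sessions: List[SessionData] = []
    for (sid, cond), grp in raw.groupby(["subject_id", "condition"], sort=True):
        grp = grp.sort_values("trial").reset_index(drop=True)
        missed = grp["missed"].astype(bool)
        for i, row in enumerate(grp.itertuples(index=False)):
            if bool(row.missed):
                continue
            for col in ("choice1", "state2", "choice2", "reward"):
                if pd.isna(getattr(row, col)):
                    raise SessionFormatError(
                        f"row {i}, column {col!r}: missing value on a completed trial"
                    )
            _check_row(i, row)
        trials = pd.DataFrame(
            {
                "trial": grp["trial"].astype(int),
                "choice1": grp["choice1"].astype("Int64"),
                "state2": grp["state2"].astype("string"),
                "choice2": grp["choice2"].astype("Int64"),
                "transition": grp["transition"].astype("string")
                if "transition" in grp
                else pd.NA,
                "reward": grp["reward"].astype("Int64"),
                "missed": missed.to_numpy(),
            }
        )
        n = len(trials)
        cfg = config or TaskConfig(n_trials=n, n_blocks=1, block_length=n)
        session = SessionData(subject_id=str(sid), condition=str(cond), trials=trials, config=cfg)
        sessions.append(label_transitions(session))
    return sessions
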