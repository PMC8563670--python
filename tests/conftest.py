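import numpy as np
import pandas as pd
import pytest

from twostep.task import SESSION_COLUMNS, SessionData, TaskConfig, transition_label


def build_session(trial_specs, subject_id="T0", condition="cond", config=None):
    """Hand-build a session from (choice1, state2, choice2, reward) tuples;
    None marks a missed trial."""
    rows = []
    for i, spec in enumerate(trial_specs):
        if spec is None:
            rows.append((i + 1, pd.NA, pd.NA, pd.NA, pd.NA, pd.NA, True))
        else:
            c1, s2, c2, r = spec
            rows.append((i + 1, c1, s2, c2, transition_label(c1, s2), r, False))
    trials = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    trials["choice1"] = trials["choice1"].astype("Int64")
    trials["choice2"] = trials["choice2"].astype("Int64")
    trials["reward"] = trials["reward"].astype("Int64")
    trials["state2"] = trials["state2"].astype("string")
    trials["transition"] = trials["transition"].astype("string")
    trials["missed"] = trials["missed"].astype(bool)
    n = len(trials)
    cfg = config or TaskConfig(n_trials=n, n_blocks=1, block_length=n)
    return SessionData(subject_id=subject_id, condition=condition, trials=trials, config=cfg)


@pytest.fixture
def make_session():
    return build_session


@pytest.fixture
def default_config():
    return TaskConfig()


@pytest.fixture
def long_config():
    def _make(n):
        return TaskConfig(n_trials=n, n_blocks=1, block_length=n)

    return _make
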