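"""Numba-compiled trial-loop likelihood kernel.

The sequential Q-learning recursion cannot be vectorized across trials, so
the inner loop is JIT-compiled. The readable reference implementation lives
in :mod:`twostep.agent`; tests assert the two routes agree.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _log_sigmoid(x: float) -> float:
    # log(1 / (1 + exp(-x))), stable for large |x|
    if x < -35.0:
        return x
    return -np.log1p(np.exp(-x))


@njit(cache=True)
def loglik_core(
    alpha1: float,
    alpha21: float,
    alpha2: float,
    beta_mb: float,
    beta_mf: float,
    beta2: float,
    pi: float,
    choice1: np.ndarray,
    state2: np.ndarray,
    choice2: np.ndarray,
    reward: np.ndarray,
    missed: np.ndarray,
    p_common: float,
    q_init: float,
) -> float:
    """Sum of log P(choice1) + log P(choice2) over non-missed trials.

    Arrays are integer-coded: choice1/state2 in {0,1}, choice2 in {0..3}
    (global stimulus index), reward in {0,1}. Missed trials contribute
    nothing and leave all learning state (including the perseveration
    reference) untouched.
    """
    q_mf = np.full(2, q_init)
    q_s2 = np.full(4, q_init)
    prev = -1  # last completed first-stage choice, -1 before the first
    ll = 0.0
    for t in range(choice1.shape[0]):
        if missed[t]:
            continue
        c1 = choice1[t]
        s2 = state2[t]
        c2 = choice2[t]
        r = reward[t]

        m_a = max(q_s2[0], q_s2[1])
        m_b = max(q_s2[2], q_s2[3])
        q_mb0 = p_common * m_a + (1.0 - p_common) * m_b
        q_mb1 = (1.0 - p_common) * m_a + p_common * m_b
        q_h0 = beta_mb * q_mb0 + beta_mf * q_mf[0]
        q_h1 = beta_mb * q_mb1 + beta_mf * q_mf[1]
        c = 0.0
        if prev == 0:
            c = 1.0
        elif prev == 1:
            c = -1.0
        logit1 = (q_h0 - q_h1) + pi * c
        if c1 == 0:
            ll += _log_sigmoid(logit1)
        else:
            ll += _log_sigmoid(-logit1)

        left = 2 * s2
        logit2 = beta2 * (q_s2[left] - q_s2[left + 1])
        if c2 == left:
            ll += _log_sigmoid(logit2)
        else:
            ll += _log_sigmoid(-logit2)

        # both prediction errors use the pre-update chosen second-stage value
        q_c2 = q_s2[c2]
        q_mf[c1] += alpha1 * (q_c2 - q_mf[c1]) + alpha21 * (r - q_c2)
        q_s2[c2] += alpha2 * (r - q_c2)
        prev = c1
    return ll
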