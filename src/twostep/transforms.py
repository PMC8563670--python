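"""Bijections between native parameters and the Gaussian (unconstrained) scale.

The population model and all group-level t-tests live on an unconstrained
scale: learning rates map through the logit, the non-negative weights
through the natural log, and the perseveration parameter is already
unbounded (identity). Values at the closed boundary of their native range
are clipped inward by a small epsilon before transforming, with a warning.
"""

from __future__ import annotations

import warnings
from typing import Callable, Dict, Sequence, Tuple

import numpy as np
from scipy.special import expit, logit

from .agent import PARAM_NAMES, AgentParams

__all__ = [
    "TRANSFORMS",
    "CLIP_EPS",
    "to_gaussian_scale",
    "from_gaussian_scale",
]

CLIP_EPS = 1e-6

# name -> (forward to Gaussian scale, inverse back to native)
TRANSFORMS: Dict[str, Tuple[Callable[[float], float], Callable[[float], float]]] = {
    "alpha1": (logit, expit),
    "alpha21": (logit, expit),
    "alpha2": (logit, expit),
    "beta_mb": (np.log, np.exp),
    "beta_mf": (np.log, np.exp),
    "beta2": (np.log, np.exp),
    "pi": (lambda x: x, lambda x: x),
}

_RATE_NAMES = ("alpha1", "alpha21", "alpha2")
_WEIGHT_NAMES = ("beta_mb", "beta_mf", "beta2")


def to_gaussian_scale(params: AgentParams, eps: float = CLIP_EPS) -> np.ndarray:
    """Map native parameters to the unconstrained scale (canonical order).

    Rates exactly at 0 or 1 and weights exactly at 0 are clipped inward by
    ``eps`` (warning emitted), since their transforms are infinite there.
    """
    values = []
    for name in PARAM_NAMES:
        v = float(getattr(params, name))
        if name in _RATE_NAMES and (v <= 0.0 or v >= 1.0):
            warnings.warn(f"{name}={v} clipped to ({eps}, {1 - eps}) before logit")
            v = min(max(v, eps), 1.0 - eps)
        elif name in _WEIGHT_NAMES and v <= 0.0:
            warnings.warn(f"{name}={v} clipped to {eps} before log")
            v = eps
        values.append(float(TRANSFORMS[name][0](v)))
    return np.asarray(values, dtype=float)


def from_gaussian_scale(theta: Sequence[float]) -> AgentParams:
    """Inverse of :func:`to_gaussian_scale`."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (7,):
        raise ValueError(f"expected 7 values, got shape {theta.shape}")
    native = {
        name: float(TRANSFORMS[name][1](theta[i])) for i, name in enumerate(PARAM_NAMES)
    }
    return AgentParams(**native)
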