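"""Current-status log-likelihood, hazard-scale quantity and score weight.

For one subject with indicator ``delta`` and examination time ``u`` the model
contributes

    l = delta * log(1 - exp(-h)) - (1 - delta) * h,

where h = Lambda(u) * exp{beta'x + g(z) + (gamma'x + h(z)) 1{e > zeta}} is the
conditional cumulative hazard at the examination time.  The scalar score
weight shared by the theta-score, the efficient-score projection and the
change-point test is

    Q = h * ( delta * exp(-h)/(1 - exp(-h)) - (1 - delta) ).

All special functions switch branches for numerical stability, h is floored
at ``EPS_H`` and exponents are clipped at +/-50 before exponentiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EPS_H", "log1mexp", "hazard_value", "loglik_from_h", "q_from_h",
           "q_over_h", "floor_hits", "ModelState"]

EPS_H = 1e-12
_CLIP = 50.0
_LOG2 = np.log(2.0)


def log1mexp(x):
    """log(1 - exp(-x)) for x > 0, stable across magnitudes."""
    x = np.asarray(x, dtype=float)
    small = x < _LOG2
    out = np.empty_like(x)
    out[small] = np.log(-np.expm1(-x[small]))
    out[~small] = np.log1p(-np.exp(-x[~small]))
    return out


def hazard_value(lam_u, lp):
    """h = Lambda(U) * exp(linear predictor), clipped and floored."""
    lp = np.clip(np.asarray(lp, dtype=float), -_CLIP, _CLIP)
    if not np.all(np.isfinite(lp)):
        row = int(np.flatnonzero(~np.isfinite(lp))[0])
        raise FloatingPointError(f"non-finite linear predictor at row {row}")
    return np.maximum(np.asarray(lam_u, dtype=float) * np.exp(lp), EPS_H)


def loglik_from_h(delta, h):
    """Mean per-subject log-likelihood given the hazard-scale vector."""
    delta = np.asarray(delta, dtype=float)
    h = np.asarray(h, dtype=float)
    terms = np.where(delta > 0, log1mexp(np.maximum(h, EPS_H)), -h)
    return float(terms.mean())


def q_over_h(delta, h):
    """Q/h = delta * exp(-h)/(1-exp(-h)) - (1-delta), bounded by the h floor."""
    delta = np.asarray(delta, dtype=float)
    h = np.maximum(np.asarray(h, dtype=float), EPS_H)
    ratio = np.exp(-h) / (-np.expm1(-h))
    return np.where(delta > 0, ratio, -1.0)


def q_from_h(delta, h):
    h = np.maximum(np.asarray(h, dtype=float), EPS_H)
    return h * q_over_h(delta, h)


def floor_hits(delta, h) -> int:
    """Count event rows whose hazard hit the numerical floor."""
    return int(np.sum((np.asarray(delta) > 0) & (np.asarray(h) <= EPS_H)))


@dataclass
class ModelState:
    """Full parameter state eta = (Lambda, beta, g, gamma, h, zeta).

    ``effects`` is any object with ``predict(z) -> (g, h)``; ``has_jump``
    distinguishes the change-point model from its restricted (null) version,
    in which gamma = 0 and h = 0 and zeta does not enter the likelihood.
    The threshold is strict: a subject jumps iff e > zeta.
    """

    hazard: Any
    beta: np.ndarray
    gamma: np.ndarray
    effects: Any
    zeta: float
    has_jump: bool = True
    meta: dict = field(default_factory=dict)

    def jump(self, e: np.ndarray) -> np.ndarray:
        if not self.has_jump:
            return np.zeros(len(e))
        return (np.asarray(e) > self.zeta).astype(float)

    def linear_predictor(self, data, g=None, h=None, jump=None) -> np.ndarray:
        if g is None or h is None:
            g, h = self.effects.predict(data.z)
        if jump is None:
            jump = self.jump(data.e)
        return data.x @ self.beta + g + (data.x @ self.gamma + h) * jump

    def h_eta(self, data) -> np.ndarray:
        return hazard_value(self.hazard(data.u), self.linear_predictor(data))

    def loglik(self, data) -> float:
        return loglik_from_h(data.delta, self.h_eta(data))

    def q_weight(self, data) -> np.ndarray:
        return q_from_h(data.delta, self.h_eta(data))

    def xtilde(self, data) -> np.ndarray:
        """Augmented design (x, x * 1{e > zeta}), shape (n, 2p)."""
        return np.hstack([data.x, data.x * self.jump(data.e)[:, None]])

    def theta_score(self, data) -> np.ndarray:
        """Analytic score of the mean log-likelihood in theta = (beta, gamma)."""
        q = self.q_weight(data)
        return self.xtilde(data).T @ q / data.n
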