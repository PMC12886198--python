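"""Monotone cumulative-hazard sieve built from integrated B-splines.

The baseline cumulative hazard is represented as Lambda(t) = sum_j c_j M_j(t)
with c_j >= 0, where each M_j is the antiderivative of a B-spline basis
function on [L_U, R_U], rescaled so that M_j(L_U) = 0 and M_j(R_U) = 1.
Since B-splines are nonnegative, every M_j is nondecreasing, and any
nonnegative coefficient vector yields a monotone hazard.  With m_n interior
knots and basis degree ``ell`` the sieve has m_n + ell + 1 coefficients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .likelihood import q_over_h, loglik_from_h, EPS_H

__all__ = ["MonotoneSplineHazard", "build_knots", "default_mn", "fit_spline_step",
           "bspline_design"]


def default_mn(n: int) -> int:
    """Default interior-knot count, ceil(n^(1/3))."""
    return math.ceil(n ** (1.0 / 3.0))


def _full_knots(interior: np.ndarray, lo: float, hi: float, degree: int) -> np.ndarray:
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


@dataclass
class MonotoneSplineHazard:
    degree: int
    interior_knots: np.ndarray
    boundary: tuple[float, float]
    coeffs: np.ndarray = None

    def __post_init__(self):
        self.interior_knots = np.asarray(self.interior_knots, dtype=float)
        lo, hi = self.boundary
        if np.any(np.diff(self.interior_knots) < 0):
            raise ValueError("interior knots must be sorted")
        if len(self.interior_knots) and not (
            lo < self.interior_knots[0] and self.interior_knots[-1] < hi
        ):
            raise ValueError("interior knots must lie strictly inside the boundary")
        if self.coeffs is None:
            self.coeffs = np.zeros(self.dim)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if len(self.coeffs) != self.dim:
            raise ValueError(f"expected {self.dim} coefficients, got {len(self.coeffs)}")
        if np.any(self.coeffs < 0):
            raise ValueError("coefficients must be nonnegative")
        self._build()

    def _build(self):
        lo, hi = self.boundary
        t = _full_knots(self.interior_knots, lo, hi, self.degree)
        # antiderivatives of all basis functions at once (identity coefficients)
        anti = BSpline(t, np.eye(self.dim), self.degree).antiderivative()
        a_lo = anti(lo)
        scale = anti(hi) - a_lo          # integral of each B-spline, > 0
        self._anti, self._a_lo, self._scale = anti, a_lo, scale

    @property
    def dim(self) -> int:
        """Number of basis functions: m_n + degree + 1."""
        return len(self.interior_knots) + self.degree + 1

    def basis(self, t) -> np.ndarray:
        """Integrated-spline design matrix, shape (len(t), dim).

        Each column is nondecreasing, 0 at L_U and 1 at R_U; evaluation
        outside [L_U, R_U] clamps to the endpoint values.
        """
        lo, hi = self.boundary
        tt = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), lo, hi)
        return (self._anti(tt) - self._a_lo) / self._scale

    def __call__(self, t) -> np.ndarray:
        return self.basis(t) @ self.coeffs

    def with_coeffs(self, c) -> "MonotoneSplineHazard":
        return MonotoneSplineHazard(self.degree, self.interior_knots, self.boundary, c)

    # serialization -----------------------------------------------------------

    def to_dict(self) -> dict:
        return {"degree": self.degree,
                "interior_knots": self.interior_knots.tolist(),
                "boundary": list(self.boundary),
                "coeffs": self.coeffs.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "MonotoneSplineHazard":
        return cls(d["degree"], np.asarray(d["interior_knots"]),
                   tuple(d["boundary"]), np.asarray(d["coeffs"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MonotoneSplineHazard":
        return cls.from_dict(json.loads(s))


def build_knots(u: np.ndarray, m_n: int, degree: int = 3) -> MonotoneSplineHazard:
    """Place interior knots at empirical quantiles of the examination times.

    The boundary is widened slightly beyond the data range so every
    observation is interior.  Coefficients start at zero.
    """
    u = np.asarray(u, dtype=float)
    if len(np.unique(u)) < 2:
        raise ValueError("need at least 2 distinct examination times")
    if m_n + degree + 1 > len(u):
        raise ValueError("over-parameterized sieve: m_n + degree + 1 exceeds n")
    lo = u.min() * (1 - 1e-6)
    hi = u.max() * (1 + 1e-6)
    if m_n > 0:
        qs = np.arange(1, m_n + 1) / (m_n + 1)
        interior = np.quantile(u, qs)
        interior = np.clip(interior, lo * (1 + 1e-9), hi * (1 - 1e-9))
    else:
        interior = np.empty(0)
    return MonotoneSplineHazard(degree, interior, (lo, hi))


def fit_spline_step(hazard: MonotoneSplineHazard, basis_u: np.ndarray,
                    delta: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, bool]:
    """Maximize the log-likelihood over nonnegative spline coefficients.

    `basis_u` is the integrated-spline design at the observed U,
    `w = exp(linear predictor)` with all non-hazard components held fixed.
    Returns (coefficients, success flag); the returned coefficients never
    have smaller log-likelihood than the incoming ones.
    """
    n = len(delta)

    def negll(c):
        h = np.maximum((basis_u @ c) * w, EPS_H)
        return -loglik_from_h(delta, h)

    def grad(c):
        h = np.maximum((basis_u @ c) * w, EPS_H)
        # d loglik / d h_i = Q_i / h_i ; d h_i / d c_j = basis_ij * w_i
        return -(basis_u.T @ (q_over_h(delta, h) * w)) / n

    c0 = hazard.coeffs.copy()
    res = minimize(negll, c0, jac=grad, method="L-BFGS-B",
                   bounds=[(0.0, None)] * len(c0),
                   options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10})
    c_new = np.maximum(res.x, 0.0)
    if negll(c_new) <= negll(c0):
        return c_new, bool(res.success)
    return c0, False


def bspline_design(t, interior: np.ndarray, boundary: tuple[float, float],
                   degree: int = 3) -> np.ndarray:
    """Plain (non-integrated) B-spline design matrix with clamped evaluation."""
    lo, hi = boundary
    tt = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), lo, hi)
    knots = _full_knots(np.asarray(interior, dtype=float), lo, hi, degree)
    dim = len(knots) - degree - 1
    return BSpline(knots, np.eye(dim), degree, extrapolate=False)(tt)
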