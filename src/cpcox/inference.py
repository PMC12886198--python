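"""Plug-in semiparametric-efficient Wald inference for theta = (beta, gamma).

The efficient score for theta removes from the raw score the best
approximation of the augmented design xtilde = (x, x 1{e > zeta}) by
functions of the examination time U and of the covariates Z.  Empirically,
each column of xtilde is regressed, with weights Q^2, onto the span of a
cubic B-spline basis in U (built on the fitted baseline-hazard knots; this
span contains constants) plus an additive, empirically centered cubic-spline
basis in the Z coordinates.  The information matrix is the weighted second
moment of the residuals,

    I_hat = (1/n) sum_i Q_i^2 R_i R_i',

and ESE_k = sqrt((I_hat^{-1})_kk / n).  The fitted threshold is treated as
known here: the threshold estimator converges at rate n and is
asymptotically independent of the regression estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .likelihood import ModelState
from .splines import bspline_design

__all__ = ["ProjectionResult", "WaldSummary", "project_scores",
           "information_matrix", "wald_summary", "InformationDegenerateError"]

_RIDGE = 1e-8


class InformationDegenerateError(np.linalg.LinAlgError):
    pass


@dataclass
class ProjectionResult:
    basis: np.ndarray        # (n, d) combined projection basis
    coef: np.ndarray         # (d, 2p) per-coordinate solutions
    residuals: np.ndarray    # (n, 2p) xtilde - fitted
    weights: np.ndarray      # Q^2

    def orthogonality(self) -> float:
        """max |sum_i w_i R_ik phi_i| over basis columns and coordinates."""
        return float(np.abs(self.basis.T @ (self.residuals * self.weights[:, None])).max())


@dataclass
class WaldSummary:
    theta: np.ndarray
    info: np.ndarray
    ese: np.ndarray
    conf_int: np.ndarray
    pvalues: np.ndarray             # two-sided
    pvalues_one_sided: np.ndarray


def _z_basis(z: np.ndarray, n_funcs: int = 5) -> np.ndarray:
    """Additive per-coordinate cubic B-spline basis, empirically centered."""
    cols = []
    for j in range(z.shape[1]):
        zj = z[:, j]
        lo, hi = zj.min(), zj.max()
        span = max(hi - lo, 1e-12)
        lo -= 1e-6 * span
        hi += 1e-6 * span
        # cubic basis with n_funcs functions needs n_funcs - 4 interior knots
        n_int = max(n_funcs - 4, 0)
        interior = (np.quantile(zj, np.arange(1, n_int + 1) / (n_int + 1))
                    if n_int else np.empty(0))
        interior = np.clip(interior, lo + 1e-9 * span, hi - 1e-9 * span)
        b = bspline_design(zj, interior, (lo, hi), degree=3)
        cols.append(b - b.mean(axis=0))
    return np.hstack(cols)


def project_scores(data, state: ModelState, n_z_funcs: int = 5) -> ProjectionResult:
    """Weighted least-squares projection of xtilde onto span{a(U)} + span{b(Z)}."""
    q = state.q_weight(data)
    w = q ** 2
    haz = state.hazard
    phi_u = bspline_design(data.u, haz.interior_knots, haz.boundary, haz.degree)
    phi = np.hstack([phi_u, _z_basis(data.z, n_z_funcs)])
    xt = state.xtilde(data) if state.has_jump else data.x

    wphi = phi * w[:, None]
    gram = phi.T @ wphi + _RIDGE * np.eye(phi.shape[1])
    rhs = wphi.T @ xt
    try:
        coef = np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError as exc:
        raise InformationDegenerateError("information degenerate") from exc
    resid = xt - phi @ coef
    return ProjectionResult(basis=phi, coef=coef, residuals=resid, weights=w)


def information_matrix(data, state: ModelState,
                       proj: ProjectionResult) -> WaldSummary:
    r = proj.residuals
    xt = state.xtilde(data) if state.has_jump else data.x
    info = (r * proj.weights[:, None]).T @ r / data.n
    info = 0.5 * (info + info.T)
    raw = (xt * proj.weights[:, None]).T @ xt / data.n
    cond = np.linalg.cond(info)
    # a residual second moment vanishing relative to the unprojected one
    # means the design column lies in the span of the nuisance directions
    if (not np.isfinite(cond) or cond > 1e12
            or np.any(np.diag(info) <= 1e-8 * np.diag(raw))):
        raise InformationDegenerateError("information degenerate")
    inv = np.linalg.inv(info)
    ese = np.sqrt(np.diag(inv) / data.n)
    theta = (np.concatenate([state.beta, state.gamma]) if state.has_jump
             else state.beta)
    ci = np.column_stack([theta - 1.96 * ese, theta + 1.96 * ese])
    zscores = theta / ese
    p_two = 2 * stats.norm.sf(np.abs(zscores))
    p_one = stats.norm.sf(np.abs(zscores))
    return WaldSummary(theta=theta, info=info, ese=ese, conf_int=ci,
                       pvalues=p_two, pvalues_one_sided=p_one)


def wald_summary(data, state: ModelState) -> WaldSummary:
    return information_matrix(data, state, project_scores(data, state))
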