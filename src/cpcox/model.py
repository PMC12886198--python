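"""Change-point partially linear Cox model for current status data.

The model for the conditional cumulative hazard of the failure time is

    Lambda(t | x, z, e) = Lambda0(t) * exp{ beta'x + g(z)
                                            + (gamma'x + h(z)) 1{e > zeta} },

estimated by sieve maximum likelihood: Lambda0 over monotone integrated
splines, (g, h) either as a two-headed ReLU network ("deep" kinds) or as
linear forms g(z) = s'z, h(z) = v'z + v0 ("linear" kinds, the change-point
Cox PH baseline), theta = (beta, gamma) in R^{2p}, and the threshold zeta by
grid search.  Fitting alternates conditional maximizations over the blocks
(network/linear effects -> spline -> theta -> zeta) until the sup-norm change
in theta falls below a tolerance; the mean log-likelihood is non-decreasing
across outer iterations by construction.

The restricted ("null") kinds freeze gamma = 0 and h = 0, drop the zeta
update, and fit the ordinary deep (or linear) partially linear model, as
required by the score-based change-point test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.optimize import minimize

from .datasets import CurrentStatusData
from .likelihood import ModelState, hazard_value, loglik_from_h, q_from_h
from .network import NetConfig, TwoHeadNet, fit_network_step
from .splines import build_knots, default_mn, fit_spline_step

__all__ = ["FitConfig", "ChangePointCoxModel", "ChangePointCoxResults",
           "LinearEffects", "NetworkEffects", "MODEL_KINDS"]

MODEL_KINDS = ("deep-cp", "deep-null", "linear-cp", "linear-null")
_ASCENT_TOL = 1e-6


@dataclass
class FitConfig:
    """Tuning parameters of the profiling estimation loop."""

    net: NetConfig = field(default_factory=NetConfig)
    m_n: int | None = None              # interior knots; default ceil(n^(1/3))
    spline_degree: int = 3
    zeta_grid_gap: float = 0.01
    zeta_trim: tuple = (0.05, 0.95)     # quantiles of e bounding the grid
    tol: float = 1e-3
    max_outer: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.tol <= 0 or self.zeta_grid_gap <= 0:
            raise ValueError("tol and zeta_grid_gap must be positive")
        lo, hi = self.zeta_trim
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("zeta_trim must satisfy 0 < lo < hi < 1")


class NetworkEffects:
    """Deep nonparametric effects: both heads of a shared ReLU network."""

    kind = "deep"

    def __init__(self, net: TwoHeadNet, null: bool = False):
        self.net = net
        self.null = null

    def predict(self, z):
        g, h = self.net.predict(z)
        if self.null:
            return g, np.zeros_like(h)
        return g, h

    def fit_step(self, data, lam_u, beta, gamma, jump, rng):
        # under the null the jump vector is all zero, detaching the h head
        return fit_network_step(self.net, data, lam_u, beta, gamma, jump, rng)

    def to_dict(self):
        return {"kind": "deep", "null": self.null, "net": self.net.to_dict()}


class LinearEffects:
    """Linear effects g(z) = s'z and h(z) = v'z + v0 (change-point Cox PH).

    g carries no intercept: a constant in g is absorbed by the scale of the
    baseline hazard.  The h intercept acts only above the threshold and is a
    genuine parameter.
    """

    kind = "linear"

    def __init__(self, r: int, null: bool = False):
        self.r = r
        self.null = null
        self.s = np.zeros(r)            # varsigma
        self.v = np.zeros(r)            # vartheta
        self.v0 = 0.0

    def predict(self, z):
        z = np.atleast_2d(z)
        g = z @ self.s
        h = np.zeros(len(z)) if self.null else z @ self.v + self.v0
        return g, h

    def fit_step(self, data, lam_u, beta, gamma, jump, rng):
        self.fit_step_joint(data, lam_u, beta, gamma, jump,
                            update_theta=False, with_scale=False)
        return []

    def fit_step_joint(self, data, lam_u, beta, gamma, jump,
                       update_theta: bool = True, with_scale: bool = True):
        """Maximize over the linear-effect coefficients, optionally jointly
        with theta.  The joint solve avoids the slow geometric convergence
        of alternating between two strongly coupled finite blocks."""
        z = data.z
        x = data.x
        p = data.p
        n = data.n
        # theta block: beta only under the null (gamma is frozen at zero)
        nt = 0 if not update_theta else (p if self.null else 2 * p)
        head = (np.concatenate([beta, gamma])[:nt] if nt else np.empty(0))
        tail = (self.s if self.null
                else np.concatenate([self.s, self.v, [self.v0]]))
        p0 = np.concatenate([head, tail])

        # a free intercept kappa acts as the log-scale of the baseline
        # hazard; optimizing it here and folding it into the spline
        # coefficients avoids the slow intercept hand-off between blocks
        if with_scale:
            p0 = np.concatenate([p0, [0.0]])

        def unpack(pv):
            b = pv[:p] if nt else beta
            g = pv[p: 2 * p] if nt and not self.null else gamma
            s = pv[nt: nt + self.r]
            kappa = pv[-1] if with_scale else 0.0
            if self.null:
                return b, g, s, np.zeros(self.r), 0.0, kappa
            v0 = pv[-2] if with_scale else pv[-1]
            return b, g, s, pv[nt + self.r: nt + 2 * self.r], v0, kappa

        def lp_of(pv):
            b, g, s, v, v0, kappa = unpack(pv)
            return x @ b + z @ s + kappa + (x @ g + z @ v + v0) * jump

        def negll(pv):
            return -loglik_from_h(data.delta, hazard_value(lam_u, lp_of(pv)))

        def grad(pv):
            q = q_from_h(data.delta, hazard_value(lam_u, lp_of(pv)))
            parts = []
            if nt:
                parts.append(x.T @ q)
                if not self.null:
                    parts.append(x.T @ (q * jump))
            parts.append(z.T @ q)
            if not self.null:
                parts += [z.T @ (q * jump), np.array([(q * jump).sum()])]
            if with_scale:
                parts.append(np.array([q.sum()]))
            return -np.concatenate(parts) / n

        res = minimize(negll, p0, jac=grad, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-10})
        best = res.x if negll(res.x) <= negll(p0) else p0
        b, g, self.s, self.v, self.v0, kappa = unpack(best)
        return (np.asarray(b), np.asarray(g)), float(kappa)

    def to_dict(self):
        return {"kind": "linear", "null": self.null,
                "s": self.s.tolist(), "v": self.v.tolist(), "v0": self.v0}


def profile_zeta(data, hazard_u, beta, gamma, geff, heff, e_grid,
                 current_zeta: float) -> float:
    """Grid search for the threshold: smallest grid point maximizing l_n.

    The incoming zeta is kept only if every grid value is strictly worse
    (the incoming value may be off-grid), preserving the ascent property.
    """
    if len(e_grid) == 0:
        raise ValueError("empty zeta grid (degenerate change-point covariate)")
    base = data.x @ beta + geff
    add = data.x @ gamma + heff
    # l_n as a function of zeta only flips indicator terms; evaluate in a block
    jumps = data.e[None, :] > e_grid[:, None]          # (n_grid, n)
    lps = base[None, :] + add[None, :] * jumps
    hs = np.maximum(hazard_u[None, :] * np.exp(np.clip(lps, -50, 50)), 1e-12)
    from .likelihood import log1mexp
    terms = np.where(data.delta[None, :] > 0, log1mexp(hs), -hs)
    lls = terms.mean(axis=1)
    k = int(np.argmax(lls))                            # first/smallest argmax
    jump_cur = (data.e > current_zeta).astype(float)
    ll_cur = loglik_from_h(
        data.delta,
        np.maximum(hazard_u * np.exp(np.clip(base + add * jump_cur, -50, 50)), 1e-12),
    )
    if lls[k] >= ll_cur - 1e-12:
        return float(e_grid[k])
    return float(current_zeta)


@dataclass
class ChangePointCoxResults:
    """Estimates, fit trajectory and (lazily computed) Wald inference."""

    model: "ChangePointCoxModel"
    state: ModelState
    theta_path: np.ndarray
    zeta_path: np.ndarray
    loglik_path: np.ndarray
    converged: bool
    n_iter: int

    _wald: Any = field(default=None, repr=False)

    @property
    def data(self) -> CurrentStatusData:
        return self.model.data

    @property
    def params(self) -> np.ndarray:
        """theta = (beta, gamma)."""
        return np.concatenate([self.state.beta, self.state.gamma])

    @property
    def beta(self) -> np.ndarray:
        return self.state.beta

    @property
    def gamma(self) -> np.ndarray:
        return self.state.gamma

    @property
    def zeta(self) -> float:
        return self.state.zeta

    @property
    def loglike(self) -> float:
        return float(self.loglik_path[-1])

    def predict_effects(self, z):
        """(g_hat(z), h_hat(z)) at new covariate values, uncentered."""
        return self.state.effects.predict(z)

    def baseline_hazard(self, t):
        return self.state.hazard(t)

    def wald(self, refresh: bool = False):
        """Plug-in semiparametric-efficient Wald summary for theta."""
        if self._wald is None or refresh:
            from .inference import wald_summary
            self._wald = wald_summary(self.data, self.state)
        return self._wald

    @property
    def bse(self) -> np.ndarray:
        return self.wald().ese

    def conf_int(self) -> np.ndarray:
        return self.wald().conf_int

    @property
    def pvalues(self) -> np.ndarray:
        return self.wald().pvalues

    def summary(self) -> str:
        names = [f"beta_{j + 1}" for j in range(len(self.beta))]
        if self.model.has_jump:
            names += [f"gamma_{j + 1}" for j in range(len(self.gamma))]
        lines = [
            "Change-point partially linear Cox model (current status data)",
            f"kind: {self.model.kind}   n = {self.data.n}   "
            f"p = {self.data.p}   r = {self.data.r}",
            f"log-likelihood (mean): {self.loglike:.6f}   "
            f"converged: {self.converged}   outer iterations: {self.n_iter}",
        ]
        if self.model.has_jump:
            lines.append(f"change point zeta_hat = {self.zeta:.4f}")
        try:
            w = self.wald()
            lines.append(f"{'param':>10} {'estimate':>10} {'ESE':>9} "
                         f"{'p-value':>10} {'95% CI':>22}")
            est = self.params if self.model.has_jump else self.beta
            for k, name in enumerate(names):
                lo, hi = w.conf_int[k]
                lines.append(f"{name:>10} {est[k]:>10.4f} {w.ese[k]:>9.4f} "
                             f"{w.pvalues[k]:>10.4g} [{lo:>9.4f}, {hi:>9.4f}]")
        except Exception as exc:  # information degenerate, etc.
            lines.append(f"(Wald inference unavailable: {exc})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "kind": self.model.kind,
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "zeta": self.zeta,
            "loglik": self.loglike,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "theta_path": self.theta_path.tolist(),
            "loglik_path": self.loglik_path.tolist(),
        }
        return out

    def save_model(self, path) -> None:
        """Model bundle: spline JSON + effects parameters, one JSON file."""
        import json
        bundle = {"kind": self.model.kind,
                  "beta": self.beta.tolist(), "gamma": self.gamma.tolist(),
                  "zeta": self.zeta,
                  "hazard": self.state.hazard.to_dict(),
                  "effects": self.state.effects.to_dict()}
        with open(path, "w") as fh:
            json.dump(bundle, fh)


class ChangePointCoxModel:
    """Sieve maximum-likelihood estimator for the change-point model.

    Parameters
    ----------
    data : CurrentStatusData
    kind : one of "deep-cp", "deep-null", "linear-cp", "linear-null"
        "deep" uses the two-headed ReLU network for (g, h); "linear" the
        Cox PH forms.  "-null" fits the restricted model without a
        change-point effect (gamma = 0, h = 0).
    """

    def __init__(self, data: CurrentStatusData, kind: str = "deep-cp"):
        if kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")
        self.data = data
        self.kind = kind

    @classmethod
    def from_dataframe(cls, df, kind: str = "deep-cp", **roles):
        return cls(CurrentStatusData.from_frame(df, **roles), kind=kind)

    @property
    def has_jump(self) -> bool:
        return self.kind.endswith("-cp")

    @property
    def is_deep(self) -> bool:
        return self.kind.startswith("deep")

    # -- Building blocks ------------------------------------------------------

    def _initial_state(self, cfg: FitConfig) -> ModelState:
        data = self.data
        m_n = default_mn(data.n) if cfg.m_n is None else cfg.m_n
        hazard = build_knots(data.u, m_n, cfg.spline_degree)
        hazard = hazard.with_coeffs(np.full(hazard.dim, 0.1))
        p = data.p
        if self.is_deep:
            net = TwoHeadNet(replace(cfg.net, seed=cfg.seed), data.r)
            effects = NetworkEffects(net, null=not self.has_jump)
        else:
            effects = LinearEffects(data.r, null=not self.has_jump)
        # zeta starts at mean(e) (a placeholder under the null), snapped to
        # the search grid so every later profile step compares grid points
        zeta0 = float(data.e.mean())
        if self.has_jump:
            grid = self._zeta_grid(cfg)
            zeta0 = float(grid[np.argmin(np.abs(grid - zeta0))])
        return ModelState(hazard=hazard, beta=np.zeros(p), gamma=np.zeros(p),
                          effects=effects, zeta=zeta0,
                          has_jump=self.has_jump)

    def _update_theta(self, state: ModelState) -> None:
        data = self.data
        lam_u = state.hazard(data.u)
        g, h = state.effects.predict(data.z)
        jump = state.jump(data.e)
        xt = np.hstack([data.x, data.x * jump[:, None]]) if self.has_jump else data.x
        base = g + h * jump
        n = data.n

        def negll(th):
            return -loglik_from_h(data.delta,
                                  hazard_value(lam_u, xt @ th + base))

        def grad(th):
            q = q_from_h(data.delta, hazard_value(lam_u, xt @ th + base))
            return -(xt.T @ q) / n

        th0 = (np.concatenate([state.beta, state.gamma]) if self.has_jump
               else state.beta.copy())
        res = minimize(negll, th0, jac=grad, method="L-BFGS-B",
                       options={"maxiter": 200, "ftol": 1e-12})
        th = res.x if negll(res.x) <= negll(th0) else th0
        p = data.p
        if self.has_jump:
            state.beta, state.gamma = th[:p], th[p:]
        else:
            state.beta = th

    def _zeta_grid(self, cfg: FitConfig) -> np.ndarray:
        # grid points are integer multiples of the gap inside the trimmed
        # range, so candidate thresholds do not drift with the sample
        lo, hi = np.quantile(self.data.e, cfg.zeta_trim)
        if hi <= lo:
            raise ValueError("degenerate change-point covariate after trimming")
        gap = cfg.zeta_grid_gap
        ks = np.arange(int(np.ceil(lo / gap)), int(np.floor(hi / gap)) + 1)
        if len(ks) == 0:
            raise ValueError("empty threshold grid; decrease zeta_grid_gap")
        return ks * gap

    # -- The profiling loop ---------------------------------------------------

    def fit(self, cfg: FitConfig | None = None, **kwargs) -> ChangePointCoxResults:
        if cfg is None:
            cfg = FitConfig(**kwargs)
        elif kwargs:
            cfg = replace(cfg, **kwargs)
        data = self.data
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x5eed]))
        state = self._initial_state(cfg)
        grid = self._zeta_grid(cfg) if self.has_jump else None

        theta_path = [np.concatenate([state.beta, state.gamma])]
        zeta_path = [state.zeta]
        ll_path = [state.loglik(data)]
        converged = False
        it = 0
        for it in range(1, cfg.max_outer + 1):
            jump = state.jump(data.e)
            lam_u = state.hazard(data.u)
            # Step 2: nonparametric effects (jointly with theta when linear)
            if self.is_deep:
                state.effects.fit_step(data, lam_u, state.beta, state.gamma,
                                       jump, rng)
            else:
                (b, g), kappa = state.effects.fit_step_joint(
                    data, lam_u, state.beta, state.gamma, jump)
                state.beta = b
                if self.has_jump:
                    state.gamma = g
                if kappa != 0.0:
                    state.hazard = state.hazard.with_coeffs(
                        state.hazard.coeffs * np.exp(kappa))
            # Step 3: spline coefficients
            g, h = state.effects.predict(data.z)
            lp_nolam = data.x @ state.beta + g + (data.x @ state.gamma + h) * jump
            w = np.exp(np.clip(lp_nolam, -50, 50))
            basis_u = state.hazard.basis(data.u)
            c_new, _ = fit_spline_step(state.hazard, basis_u, data.delta, w)
            state.hazard = state.hazard.with_coeffs(c_new)
            # Step 4: regression parameters
            self._update_theta(state)
            # Step 5: change point
            if self.has_jump:
                g, h = state.effects.predict(data.z)
                state.zeta = profile_zeta(data, state.hazard(data.u),
                                          state.beta, state.gamma, g, h,
                                          grid, state.zeta)
            ll = state.loglik(data)
            if ll < ll_path[-1] - _ASCENT_TOL:
                raise RuntimeError(
                    f"block-ascent violation at outer iteration {it}: "
                    f"log-likelihood fell from {ll_path[-1]:.8f} to {ll:.8f}")
            ll_path.append(ll)
            theta = np.concatenate([state.beta, state.gamma])
            theta_path.append(theta)
            zeta_path.append(state.zeta)
            # Step 6: stop on theta stabilization
            if np.max(np.abs(theta - theta_path[-2])) < cfg.tol:
                converged = True
                break
        state.meta = {"n_iter": it, "converged": converged, "final_loglik": ll_path[-1]}
        return ChangePointCoxResults(
            model=self, state=state,
            theta_path=np.asarray(theta_path), zeta_path=np.asarray(zeta_path),
            loglik_path=np.asarray(ll_path), converged=converged, n_iter=it)
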