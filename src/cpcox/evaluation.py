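"""Simulation metrics and the replication harness.

Metrics follow the usual simulation-study conventions: per regression
parameter the bias, sampling standard error (SSE), mean of the model-based
standard errors (ESE) and 95% coverage probability (CP); for the
nonparametric effects the centered relative error on an independent test set

    RE(g_hat) = sqrt( mean{ (g_hat - mean(g_hat)) - g0 }^2 / mean{ g0^2 } );

and for the change point the bias, the empirical 95% CI length (difference
between the 97.5% and 2.5% quantiles of the replicated estimates, linear
interpolation) and the SSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ChangePointCoxModel, FitConfig
from .simulate import SimConfig, sample_dataset, truth_functions, sample_covariates

__all__ = ["relative_error", "prediction_errors", "zeta_ci_length",
           "replicate_experiment", "SimulationSummary"]


def relative_error(g_hat, g_true) -> float:
    g_hat = np.asarray(g_hat, dtype=float)
    g_true = np.asarray(g_true, dtype=float)
    if len(g_hat) != len(g_true) or len(g_true) < 2:
        raise ValueError("need two equal-length vectors with at least 2 points")
    denom = np.mean(g_true ** 2)
    if denom <= 0:
        raise ValueError("relative error undefined: truth is identically zero")
    num = np.mean(((g_hat - g_hat.mean()) - g_true) ** 2)
    return float(np.sqrt(num / denom))


def prediction_errors(g_hat, g_true) -> np.ndarray:
    return np.asarray(g_hat, dtype=float) - np.asarray(g_true, dtype=float)


def zeta_ci_length(estimates) -> float:
    est = np.asarray(estimates, dtype=float)
    if len(est) < 2:
        raise ValueError("need at least 2 replications")
    lo, hi = np.quantile(est, [0.025, 0.975])  # linear interpolation
    return float(hi - lo)


@dataclass
class SimulationSummary:
    """Aggregated replication results in the layout of a simulation table."""

    case_id: int
    n: int
    M: int
    kind: str
    records: pd.DataFrame                 # one row per successful replication
    n_failed: int
    failures: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return self.n_failed == 0

    def param_table(self, theta0) -> pd.DataFrame:
        theta0 = np.atleast_1d(np.asarray(theta0, dtype=float))
        rows = []
        names = ([f"beta_{j+1}" for j in range(len(theta0) // 2)]
                 + [f"gamma_{j+1}" for j in range(len(theta0) // 2)])
        for k, name in enumerate(names):
            est = self.records[f"theta_{k}"].to_numpy()
            ese = self.records[f"ese_{k}"].to_numpy()
            cover = self.records[f"cover_{k}"].to_numpy()
            rows.append({"param": name,
                         "Bias": est.mean() - theta0[k],
                         "SSE": est.std(ddof=1),
                         "ESE": np.nanmean(ese),
                         "CP": np.nanmean(cover)})
        return pd.DataFrame(rows).set_index("param")

    def re_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "RE": [self.records["re_g"].mean(), self.records["re_h"].mean()],
            "SSE": [self.records["re_g"].std(ddof=1),
                    self.records["re_h"].std(ddof=1)],
        }, index=["g_hat", "h_hat"])

    def zeta_table(self, zeta0: float) -> pd.Series:
        z = self.records["zeta"].to_numpy()
        return pd.Series({"Bias": z.mean() - zeta0,
                          "95% CI Length": zeta_ci_length(z),
                          "SSE": z.std(ddof=1)})


def _test_covariates(sim_cfg: SimConfig, n_t: int, seed: int):
    cfg_t = replace(sim_cfg, n=n_t, seed=seed)
    _, z_t, _ = sample_covariates(cfg_t)
    return z_t


def replicate_experiment(case_id: int, n: int, M: int,
                         fit_cfg: FitConfig | None = None,
                         base_seed: int = 0, kind: str = "deep-cp",
                         sim_cfg: SimConfig | None = None,
                         n_t: int = 200) -> SimulationSummary:
    """Simulate-fit-evaluate M times and aggregate.

    Replication m uses seed base_seed + m for the training data and an
    independent seed for the fresh test covariates on which the relative
    errors are evaluated.  Failed replications are recorded and excluded.
    """
    if fit_cfg is None:
        fit_cfg = FitConfig()
    if sim_cfg is None:
        sim_cfg = SimConfig(n=n, case_id=case_id)
    else:
        sim_cfg = replace(sim_cfg, n=n, case_id=case_id)
    g0, h0 = truth_functions(case_id, centered=True)
    theta0 = np.concatenate([sim_cfg.beta0, sim_cfg.gamma0])

    rows = []
    failures = []
    for m in range(1, M + 1):
        try:
            data = sample_dataset(sim_cfg.with_seed(base_seed + m))
            fit = ChangePointCoxModel(data, kind=kind).fit(
                replace(fit_cfg, seed=base_seed + m))
            z_t = _test_covariates(sim_cfg, n_t, base_seed + 100_000 + m)
            g_hat, h_hat = fit.predict_effects(z_t)
            row = {"rep": m, "zeta": fit.zeta, "loglik": fit.loglike,
                   "converged": fit.converged,
                   "re_g": relative_error(g_hat, g0(z_t)),
                   "re_h": relative_error(h_hat, h0(z_t))}
            for k, v in enumerate(fit.params):
                row[f"theta_{k}"] = v
            try:
                w = fit.wald()
                for k in range(len(fit.params)):
                    row[f"ese_{k}"] = w.ese[k]
                    lo, hi = w.conf_int[k]
                    row[f"cover_{k}"] = float(lo <= theta0[k] <= hi)
            except Exception:
                for k in range(len(fit.params)):
                    row[f"ese_{k}"] = np.nan
                    row[f"cover_{k}"] = np.nan
            rows.append(row)
        except Exception as exc:  # pragma: no cover - transparent degradation
            failures.append((m, repr(exc)))
    return SimulationSummary(case_id=case_id, n=n, M=M, kind=kind,
                             records=pd.DataFrame(rows),
                             n_failed=len(failures), failures=failures)
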