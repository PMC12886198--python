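"""Current status data container and delimited-text I/O.

A current status (case-I interval-censored) sample records, per subject, a
single examination time ``u`` and the indicator ``delta = 1{T <= u}``; the
failure time ``T`` itself is never observed.  Covariates split into treatment
columns ``x`` (entering linearly), nonparametric columns ``z``, and a scalar
change-point covariate ``e``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["CurrentStatusData", "SchemaError"]


class SchemaError(ValueError):
    """Raised when a dataset violates the current-status schema."""


@dataclass
class CurrentStatusData:
    """In-memory current status dataset.

    Parameters
    ----------
    delta : (n,) array of {0, 1}
        Censoring indicator, 1 if the event occurred by the examination time.
    u : (n,) array of positive floats
        Examination times.
    x : (n, p) array
        Treatment covariates (linear and jump effects).
    z : (n, r) array
        Covariates modelled nonparametrically.
    e : (n,) array
        Change-point covariate.
    t_true, g_true, h_true : optional (n,) arrays
        Generating truth, retained by the simulator for oracle checks.
    """

    delta: np.ndarray
    u: np.ndarray
    x: np.ndarray
    z: np.ndarray
    e: np.ndarray
    t_true: np.ndarray | None = None
    g_true: np.ndarray | None = None
    h_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        self.e = np.asarray(self.e, dtype=float)
        if self.x.shape[0] != self.n and self.x.shape[1] == self.n:
            self.x = self.x.T
        if self.z.shape[0] != self.n and self.z.shape[1] == self.n:
            self.z = self.z.T
        bad = ~np.isin(self.delta, (0.0, 1.0))
        if bad.any():
            raise SchemaError(
                f"delta must be 0/1; first offending row: {int(np.flatnonzero(bad)[0])}"
            )
        if not np.all(self.u > 0):
            row = int(np.flatnonzero(~(self.u > 0))[0])
            raise SchemaError(f"u must be positive; offending row: {row}")
        for name, arr in (("x", self.x), ("z", self.z), ("e", self.e)):
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"non-finite values in column block '{name}'")
        lens = {len(self.delta), len(self.u), self.x.shape[0], self.z.shape[0], len(self.e)}
        if len(lens) != 1:
            raise SchemaError(f"inconsistent row counts: {sorted(lens)}")
        if self.t_true is not None:
            self.t_true = np.asarray(self.t_true, dtype=float)
            if not np.array_equal(self.delta, (self.t_true <= self.u).astype(float)):
                raise SchemaError("delta does not equal 1{T <= U} in the truth block")

    @property
    def n(self) -> int:
        return len(self.delta)

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def r(self) -> int:
        return self.z.shape[1]

    @property
    def has_truth(self) -> bool:
        return self.t_true is not None

    def drop_truth(self) -> "CurrentStatusData":
        return CurrentStatusData(self.delta, self.u, self.x, self.z, self.e)

    def subset(self, idx: np.ndarray) -> "CurrentStatusData":
        pick = lambda a: None if a is None else a[idx]
        return CurrentStatusData(
            self.delta[idx], self.u[idx], self.x[idx], self.z[idx], self.e[idx],
            pick(self.t_true), pick(self.g_true), pick(self.h_true),
        )

    # ---- pandas / CSV round trip -------------------------------------------

    def to_frame(self, with_truth: bool = True) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"delta": self.delta.astype(int), "u": self.u}
        for j in range(self.p):
            cols[f"x{j + 1}"] = self.x[:, j]
        for j in range(self.r):
            cols[f"z{j + 1}"] = self.z[:, j]
        cols["e"] = self.e
        if with_truth and self.has_truth:
            cols["t_true"] = self.t_true
            cols["g0"] = self.g_true
            cols["h0"] = self.h_true
        return pd.DataFrame(cols)

    def to_csv(self, path, with_truth: bool = True) -> None:
        # 17 significant digits for exact float round-trip
        self.to_frame(with_truth).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        delta: str = "delta",
        u: str = "u",
        x: Sequence[str] | None = None,
        z: Sequence[str] | None = None,
        e: str = "e",
    ) -> "CurrentStatusData":
        """Build a dataset from a dataframe with explicit column roles.

        When ``x``/``z`` are omitted the conventional header
        ``delta,u,x1..xp,z1..zr,e`` is assumed.
        """
        if x is None:
            x = sorted((c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
        if z is None:
            z = sorted((c for c in df.columns if c.startswith("z") and c[1:].isdigit()),
                       key=lambda c: int(c[1:]))
        if not x or not z:
            raise SchemaError("could not infer x/z columns; pass them explicitly")
        for col in (delta, u, e, *x, *z):
            if col not in df.columns:
                raise SchemaError(f"missing column '{col}'")
            if df[col].isna().any():
                raise SchemaError(f"missing values in column '{col}'")
        truth = {}
        if {"t_true", "g0", "h0"} <= set(df.columns):
            truth = dict(t_true=df["t_true"].to_numpy(),
                         g_true=df["g0"].to_numpy(), h_true=df["h0"].to_numpy())
        return cls(df[delta].to_numpy(), df[u].to_numpy(),
                   df[list(x)].to_numpy(), df[list(z)].to_numpy(),
                   df[e].to_numpy(), **truth)

    @classmethod
    def read_csv(cls, path, **roles) -> "CurrentStatusData":
        # round_trip parser: exact float64 recovery of the 17-digit writer
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, **roles)
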