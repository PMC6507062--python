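"""Right-censored survival dataset container used throughout the package."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SurvivalDataset:
    """Observed times, event indicators and one continuous predictor.

    ``time`` is T = min(T0, C) in whatever units the data come in, ``status``
    is 1 for an observed event and 0 for right censoring, ``x`` the continuous
    predictor whose discretization is under study, and ``covariates`` an
    optional (n, q) matrix of adjustment variables that enter Cox fits
    linearly.
    """

    time: np.ndarray
    status: np.ndarray
    x: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        n = len(self.time)
        if len(self.status) != n or len(self.x) != n:
            raise ValueError("time, status and x must have equal length")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                self.covariates = self.covariates.T
            if self.covariates.shape[0] != n:
                raise ValueError("covariate matrix does not match dataset length")
        for name, arr in (("time", self.time), ("status", self.status), ("x", self.x)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in column '{name}'")
        if np.any(self.time < 0):
            raise ValueError("negative observed times")
        if not np.all(np.isin(self.status, (0, 1))):
            raise ValueError("status must be coded 0 (censored) / 1 (event)")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        cov = None if self.covariates is None else self.covariates[idx]
        return SurvivalDataset(self.time[idx], self.status[idx], self.x[idx], cov,
                               list(self.covariate_names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "status": self.status, "x": self.x})
        if self.covariates is not None:
            names = self.covariate_names or [
                f"z{i + 1}" for i in range(self.covariates.shape[1])
            ]
            for j, name in enumerate(names):
                df[name] = self.covariates[:, j]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        status_col: str = "status",
        x_col: str = "x",
        covariate_cols: list[str] | None = None,
    ) -> "SurvivalDataset":
        for col in [time_col, status_col, x_col, *(covariate_cols or [])]:
            if col not in df.columns:
                raise KeyError(f"column '{col}' not found in the input table")
        required = [time_col, status_col, x_col, *(covariate_cols or [])]
        sub = df[required]
        keep = sub.notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("dropped %d rows with missing required fields", dropped)
        sub = sub[keep]
        status = _coerce_status(sub[status_col])
        time = pd.to_numeric(sub[time_col]).to_numpy(dtype=float)
        bad = np.flatnonzero(time < 0)
        if bad.size:
            raise ValueError(f"negative times in rows {bad.tolist()[:10]}")
        cov = None
        if covariate_cols:
            cov = sub[covariate_cols].to_numpy(dtype=float)
        return cls(time, status, pd.to_numeric(sub[x_col]).to_numpy(dtype=float),
                   cov, list(covariate_cols or []))


def _coerce_status(col: pd.Series) -> np.ndarray:
    vals = pd.unique(col)
    mapping = {0: 0, 1: 1, "0": 0, "1": 1, False: 0, True: 1,
               "censored": 0, "event": 1, 0.0: 0, 1.0: 1}
    out = []
    for v in col:
        if v not in mapping:
            raise ValueError(
                f"unknown status code {v!r}; observed codes: {list(vals)[:10]}"
            )
        out.append(mapping[v])
    return np.asarray(out, dtype=int)


def read_dataset(
    path,
    time_col: str = "time",
    status_col: str = "status",
    x_col: str = "x",
    covariate_cols: list[str] | None = None,
    sep: str = ",",
) -> SurvivalDataset:
    """Read a delimited text table into a validated :class:`SurvivalDataset`."""
    df = pd.read_csv(path, sep=sep)
    return SurvivalDataset.from_frame(df, time_col, status_col, x_col, covariate_cols)
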