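"""Survival data container, validation and CSV loading.

A cohort is a set of triples (x_i, t_i, d_i): a covariate vector, the last
time the subject was under observation, and an event indicator (1 = the
event of interest occurred at t_i, 0 = right-censored at t_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SurvivalDataset:
    """Right-censored survival cohort.

    Attributes
    ----------
    X : ndarray of shape (n, p)
        Numeric covariates.
    t : ndarray of shape (n,)
        Non-negative observation times (event or censoring).
    d : ndarray of shape (n,)
        Event indicator: 1 = event observed, 0 = right-censored.
    covariate_names : list of str
        Column names, one per covariate.
    """

    X: np.ndarray
    t: np.ndarray
    d: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.d = np.asarray(self.d).ravel().astype(int)
        if not self.covariate_names:
            self.covariate_names = [f"x{j}" for j in range(self.X.shape[1])]
        self._validate()

    def _validate(self) -> None:
        n = self.X.shape[0]
        if n == 0:
            raise ValueError("dataset is empty")
        if self.t.shape[0] != n or self.d.shape[0] != n:
            raise ValueError(
                f"length mismatch: X has {n} rows, t has {self.t.shape[0]}, "
                f"d has {self.d.shape[0]}"
            )
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names length does not match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("covariates contain missing or non-finite values")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("times contain non-finite values")
        if np.any(self.t < 0):
            raise ValueError("negative observation times are not allowed")
        bad = np.setdiff1d(np.unique(self.d), [0, 1])
        if bad.size:
            rows = np.flatnonzero(~np.isin(self.d, [0, 1]))
            raise ValueError(
                f"event indicator must be 0 (censored) or 1 (event); found "
                f"{bad.tolist()} in rows {rows[:10].tolist()} (single-risk model)"
            )
        zero_events = np.flatnonzero((self.t == 0) & (self.d == 1))
        if zero_events.size:
            raise ValueError(
                f"events recorded at t=0 in rows {zero_events[:10].tolist()}: "
                "the cumulative hazard is anchored at zero so the event density "
                "vanishes at the origin; remove or re-time these records"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def uncensored(self) -> np.ndarray:
        """Boolean mask of subjects with an observed event."""
        return self.d == 1

    @property
    def censoring_rate(self) -> float:
        return float(np.mean(self.d == 0))

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(
            self.X[idx], self.t[idx], self.d[idx], list(self.covariate_names)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.covariate_names)
        df["time"] = self.t
        df["event"] = self.d
        return df

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other) -> bool:
        if not isinstance(other, SurvivalDataset):
            return NotImplemented
        return (
            np.array_equal(self.X, other.X)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.d, other.d)
            and self.covariate_names == other.covariate_names
        )


def load_dataset(
    path,
    time_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
) -> SurvivalDataset:
    """Load a survival cohort from a delimited text table.

    Rows with missing values are dropped (their count is logged). Every
    numeric column other than the time and event columns is used as a
    covariate unless ``covariates`` names a subset.
    """
    df = pd.read_csv(path)
    for col in (time_col, event_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (time_col, event_col)]
    else:
        missing = [c for c in covariates if c not in df.columns]
        if missing:
            raise ValueError(f"covariate columns not found: {missing}")
    cols = covariates + [time_col, event_col]
    sub = df[cols]
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.warning("dropped %d rows with missing values", n_dropped)
    if len(sub) == 0:
        raise ValueError("no complete rows after dropping missing values")
    try:
        X = sub[covariates].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric covariate values: {exc}") from exc
    return SurvivalDataset(
        X, sub[time_col].to_numpy(dtype=float),
        sub[event_col].to_numpy(), list(covariates),
    )
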