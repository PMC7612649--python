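"""Evaluation stack for right-censored predictions.

Implements the product-limit (Kaplan-Meier) estimator, inverse probability
of censoring weights (IPCW), the time-dependent Brier score

    BS(t) = 1/n sum_i [ omega(t_i) 1{i in U, t_i <= t} S_hat(t|x_i)^2
                       + omega(t) 1{t_i > t} (1 - S_hat(t|x_i))^2 ]

and the cumulative time-dependent concordance index

    C(t) = sum_{i,j} omega(t_i) 1{(t_i <= t) & (t < t_j) & (S_hat(t|x_j) > S_hat(t|x_i))}
           / ( [sum_k 1{t_k > t}] [sum_k omega(t_k) 1{t_k <= t}] )

with omega(t_i) = d_i / G(t_i^-), the reciprocal of the censoring-survival
Kaplan-Meier at the left limit, so censored subjects carry weight zero in
both sums (a censored subject with t_i <= t cannot be ordered against
anyone). Ties in the predicted survival contribute nothing (strict
inequality); note the weight enters once, not squared as in Uno's variant.

Models are evaluated at the 0.25 / 0.5 / 0.75 quantiles of the uncensored
subjects' event times and averaged over a 5-fold cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .data import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "KaplanMeierCurve",
    "CensoringWeights",
    "EvalTimes",
    "MetricReport",
    "kaplan_meier",
    "censoring_weights",
    "brier_score",
    "c_index",
    "eval_times",
    "cross_validate",
]


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate (right-continuous step function)."""

    times: np.ndarray     # distinct event times, increasing
    survival: np.ndarray  # value of S just after each event time
    at_risk: np.ndarray
    events: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """S(t): right-continuous, 1 before the first event time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def evaluate_left(self, t) -> np.ndarray:
        """Left limit S(t^-): the product over event times strictly before t."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="left")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def median(self) -> float:
        """Smallest time with S <= 0.5; +inf when the curve never crosses."""
        below = self.survival <= 0.5
        if not np.any(below):
            return float("inf")
        return float(self.times[np.argmax(below)])


def kaplan_meier(times, events) -> KaplanMeierCurve:
    """Product-limit estimate from observation times and 0/1 event indicators.

    Ties at a time are processed jointly; deaths at a time occur before
    censorings at the same time (both remain in the risk set for it).
    """
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).ravel().astype(int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    event_times = np.unique(times[events == 1])
    n_at_risk = np.array([(times >= u).sum() for u in event_times])
    n_events = np.array([((times == u) & (events == 1)).sum() for u in event_times])
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - n_events / n_at_risk
    survival = np.cumprod(factors)
    return KaplanMeierCurve(event_times, survival, n_at_risk, n_events)


@dataclass
class CensoringWeights:
    """IPCW weights from the censoring-distribution Kaplan-Meier G."""

    per_subject: np.ndarray          # d_i / G(t_i^-); 0 for censored subjects
    at_horizon: dict[float, float]   # t -> 1 / G(t)
    curve: KaplanMeierCurve = field(repr=False, default=None)


def censoring_weights(data: SurvivalDataset, horizons=()) -> CensoringWeights:
    """Weights 1/G for the Brier score and C-index.

    G is the Kaplan-Meier estimate of the censoring distribution (event
    indicator flipped). Event subjects get omega_i = 1/G(t_i^-); censored
    subjects get 0. Subjects (or horizons) where G vanishes are given
    weight 0 and logged — they carry no usable information.
    """
    curve = kaplan_meier(data.t, 1 - data.d)
    g_left = curve.evaluate_left(data.t)
    per_subject = np.zeros(data.n)
    ev = data.d == 1
    zero = ev & (g_left <= 0)
    if np.any(zero):
        logger.warning(
            "%d event subjects fall where the censoring survival is 0; "
            "their IPCW weight is set to 0 and they are excluded",
            int(zero.sum()),
        )
    ok = ev & (g_left > 0)
    per_subject[ok] = 1.0 / g_left[ok]
    at_horizon = {}
    for t in np.atleast_1d(np.asarray(horizons, dtype=float)):
        g = float(curve.evaluate(t)[0])
        if g <= 0:
            logger.warning("censoring survival is 0 at horizon %g; weight 0", t)
            at_horizon[float(t)] = 0.0
        else:
            at_horizon[float(t)] = 1.0 / g
    return CensoringWeights(per_subject, at_horizon, curve)


def _pred_at(pred, t: float) -> np.ndarray:
    """Column of predicted survival at horizon t (t must be on the grid)."""
    times = np.asarray(pred.times, dtype=float)
    idx = np.flatnonzero(np.isclose(times, t, rtol=0.0, atol=1e-12))
    if idx.size == 0:
        raise ValueError(f"prediction grid does not cover horizon t={t}")
    return np.asarray(pred.survival)[:, idx[0]]


def brier_score(pred, data: SurvivalDataset, t: float) -> float:
    """IPCW time-dependent Brier score at horizon t (divides by the full n)."""
    t = float(t)
    if t < 0:
        raise ValueError("horizon must be non-negative")
    s_hat = _pred_at(pred, t)
    w = censoring_weights(data, horizons=[t])
    past_event = (data.d == 1) & (data.t <= t)
    future = data.t > t
    total = (w.per_subject[past_event] * s_hat[past_event] ** 2).sum()
    total += w.at_horizon[t] * ((1.0 - s_hat[future]) ** 2).sum()
    return float(total / data.n)


def c_index(pred, data: SurvivalDataset, t: float) -> float:
    """Cumulative time-dependent concordance index at horizon t.

    Returns NaN (with a warning) when no comparable pair exists.
    """
    t = float(t)
    s_hat = _pred_at(pred, t)
    w = censoring_weights(data)
    past = (data.d == 1) & (data.t <= t)
    future = data.t > t
    n_future = int(future.sum())
    w_past = w.per_subject[past]
    denom = n_future * w_past.sum()
    if n_future == 0 or not np.any(past) or denom == 0:
        warnings.warn(f"no comparable pairs at horizon t={t}; C-index undefined")
        return float("nan")
    s_future_sorted = np.sort(s_hat[future])
    # for each event subject i, count future subjects with strictly larger S
    n_greater = n_future - np.searchsorted(s_future_sorted, s_hat[past],
                                           side="right")
    num = (w_past * n_greater).sum()
    return float(num / denom)


@dataclass
class EvalTimes:
    """Evaluation horizons: quantiles of the uncensored event times."""

    quantiles: np.ndarray
    times: np.ndarray


def eval_times(data: SurvivalDataset,
               quantiles=(0.25, 0.5, 0.75)) -> EvalTimes:
    """Horizons at the stated quantiles of the uncensored subjects' times.

    Quantiles use linear interpolation between order statistics; censored
    records never affect the result.
    """
    ev = data.t[data.d == 1]
    if ev.size == 0:
        raise ValueError("no uncensored subjects: evaluation times undefined")
    q = np.asarray(quantiles, dtype=float)
    return EvalTimes(q, np.quantile(ev, q))


@dataclass
class MetricReport:
    """Per-fold metric values at each horizon, with fold mean and sd."""

    metric: str
    quantiles: np.ndarray
    times: np.ndarray
    fold_values: np.ndarray  # (n_folds, n_times); NaN marks degenerate folds

    @property
    def mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.fold_values, axis=0)

    @property
    def sd(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.fold_values, axis=0)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "horizon_quantile": self.quantiles.tolist(),
            "horizon_time": self.times.tolist(),
            "folds": self.fold_values.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
        }


def cross_validate(data: SurvivalDataset,
                   head_config=None, assign_config=None, fit_config=None,
                   n_folds: int = 5, seed: int = 0,
                   fitter=None, splits=None) -> dict[str, MetricReport]:
    """K-fold cross-validated Brier score and C-index.

    Horizons are the 0.25/0.5/0.75 quantiles of the full dataset's
    uncensored event times, computed once and reused across folds so they
    stay comparable. Fold splits are deterministic given ``seed``. A fold
    without events (or without comparable pairs) is flagged with NaN.

    ``fitter`` may replace the default training routine: a callable
    ``fitter(train_dataset, fold_index) -> model`` returning any object
    with a ``survival(X, times)`` method. ``splits`` may supply explicit
    (train_idx, test_idx) pairs instead of the seeded KFold.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    et = eval_times(data)

    if fitter is None:
        from .training import FitConfig, fit

        base = fit_config or FitConfig()

        def fitter(train, fold):
            from dataclasses import replace
            model, _ = fit(train, head_config, assign_config,
                           replace(base, seed=(base.seed + 1009 * fold) % (2**31)))
            return model

    if splits is None:
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(kf.split(np.arange(data.n)))
    else:
        splits = list(splits)
        n_folds = len(splits)
    briers = np.full((n_folds, et.times.size), np.nan)
    cindex = np.full((n_folds, et.times.size), np.nan)
    for fold, (tr, te) in enumerate(splits):
        train, test = data.subset(tr), data.subset(te)
        if not np.any(train.d == 1) or not np.any(test.d == 1):
            logger.warning("fold %d lacks events; flagged", fold)
            continue
        model = fitter(train, fold)
        pred = model.survival(test.X, et.times)
        for j, t in enumerate(et.times):
            briers[fold, j] = brier_score(pred, test, t)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cindex[fold, j] = c_index(pred, test, t)
    return {
        "brier": MetricReport("brier", et.quantiles, et.times, briers),
        "c_index": MetricReport("c_index", et.quantiles, et.times, cindex),
    }
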