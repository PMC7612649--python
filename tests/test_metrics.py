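"""Kaplan-Meier, IPCW weights, time-dependent Brier score and C-index,
evaluation horizons and cross-validation plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survclust.data import SurvivalDataset
from survclust.metrics import (MetricReport, brier_score, c_index,
                               censoring_weights, cross_validate, eval_times,
                               kaplan_meier)
from survclust.mixture import SurvivalPrediction

from conftest import stub_mixture


def make_pred(times, survival):
    survival = np.asarray(survival, dtype=float)
    K = 1
    return SurvivalPrediction(np.asarray(times, dtype=float), survival,
                              np.ones((survival.shape[0], K)),
                              np.zeros((K, len(times))))


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_single_event_product_limit():
    km = kaplan_meier([2.0, 3.0, 4.0, 5.0], [1, 0, 0, 0])
    assert km.evaluate(1.9)[0] == 1.0
    assert km.evaluate(2.0)[0] == pytest.approx(3 / 4)


def test_km_no_events_is_identically_one():
    km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
    np.testing.assert_array_equal(km.evaluate([0.5, 1.5, 10.0]), 1.0)


def test_km_hand_computed_product_limit():
    km = kaplan_meier([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
    assert km.evaluate(1)[0] == pytest.approx(4 / 5)
    assert km.evaluate(3)[0] == pytest.approx(8 / 15)
    assert km.evaluate(4)[0] == pytest.approx(4 / 15)


def test_km_matches_lifelines_with_ties():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(0)
    t = rng.integers(1, 15, 200).astype(float)  # many ties
    d = rng.integers(0, 2, 200)
    km = kaplan_meier(t, d)
    kmf = lifelines.KaplanMeierFitter().fit(t, d)
    grid = np.arange(0, 16, dtype=float)
    ours = km.evaluate(grid)
    theirs = kmf.survival_function_at_times(grid).to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_km_empty_input_rejected():
    with pytest.raises(ValueError):
        kaplan_meier([], [])


def test_km_without_ties_equals_singleton_risk_set_product():
    rng = np.random.default_rng(1)
    t = rng.permutation(np.arange(1.0, 21.0))
    d = rng.integers(0, 2, 20)
    km = kaplan_meier(t, d)
    order = np.argsort(t)
    s = 1.0
    expected = {}
    for rank, i in enumerate(order):
        if d[i] == 1:
            s *= 1.0 - 1.0 / (20 - rank)
        expected[t[i]] = s
    for ti, si in expected.items():
        assert km.evaluate(ti)[0] == pytest.approx(si)


# ---------------------------------------------------------------------------
# censoring weights


def test_weights_are_one_without_censoring():
    ds = SurvivalDataset(np.zeros((5, 1)), [1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
    w = censoring_weights(ds, horizons=[2.5])
    np.testing.assert_array_equal(w.per_subject, 1.0)
    assert w.at_horizon[2.5] == 1.0


def test_horizon_weight_is_one_before_any_censoring():
    ds = SurvivalDataset(np.zeros((4, 1)), [5, 5, 5, 5], [0, 0, 0, 0])
    w = censoring_weights(ds, horizons=[3.0])
    assert w.at_horizon[3.0] == 1.0


def test_weights_match_hand_computed_censoring_km():
    # subjects: (t, d) = (1,1), (2,0), (3,1), (4,0), (5,1), (6,1)
    # censoring KM G: censorings at t=2 (5 at risk, factor 4/5) and t=4
    # (3 at risk, factor 2/3); G = 1 on [0,2), 4/5 on [2,4), 8/15 on [4,inf)
    ds = SurvivalDataset(np.zeros((6, 1)), [1, 2, 3, 4, 5, 6],
                         [1, 0, 1, 0, 1, 1])
    w = censoring_weights(ds, horizons=[2.5, 4.5])
    expected = [1.0, 0.0, 5 / 4, 0.0, 15 / 8, 15 / 8]
    np.testing.assert_allclose(w.per_subject, expected)
    assert w.at_horizon[2.5] == pytest.approx(5 / 4)
    assert w.at_horizon[4.5] == pytest.approx(15 / 8)


# ---------------------------------------------------------------------------
# Brier score


def brier_oracle(pred, ds, t):
    """Element-by-element summation of the printed formula."""
    g = kaplan_meier(ds.t, 1 - ds.d)
    s_hat = pred.survival[:, np.flatnonzero(np.isclose(pred.times, t))[0]]
    total = 0.0
    for i in range(ds.n):
        if ds.d[i] == 1 and ds.t[i] <= t:
            gi = g.evaluate_left(ds.t[i])[0]
            total += (1.0 / gi) * s_hat[i] ** 2 if gi > 0 else 0.0
        elif ds.t[i] > t:
            gt = g.evaluate(t)[0]
            total += (1.0 / gt) * (1.0 - s_hat[i]) ** 2 if gt > 0 else 0.0
    return total / ds.n


def test_brier_is_zero_at_time_zero():
    ds = SurvivalDataset(np.zeros((4, 1)), [1, 2, 3, 4], [1, 1, 0, 1])
    pred = make_pred([0.0], np.ones((4, 1)))
    assert brier_score(pred, ds, 0.0) == 0.0


def test_brier_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    for trial in range(5):
        n = 50
        ds = SurvivalDataset(np.zeros((n, 1)), rng.uniform(0.1, 10, n),
                             rng.integers(0, 2, n))
        times = np.array([2.0, 5.0, 8.0])
        pred = make_pred(times, rng.random((n, 3)))
        for t in times:
            assert brier_score(pred, ds, t) == pytest.approx(
                brier_oracle(pred, ds, t), abs=1e-10)


def test_brier_perfect_prediction_scores_zero():
    ds = SurvivalDataset(np.zeros((6, 1)), [1, 2, 3, 4, 5, 6], np.ones(6))
    t = 3.5
    s_hat = (ds.t > t).astype(float)
    pred = make_pred([t], s_hat[:, None])
    assert brier_score(pred, ds, t) == 0.0


def test_brier_equals_mean_squared_error_without_censoring():
    rng = np.random.default_rng(3)
    n = 40
    ds = SurvivalDataset(np.zeros((n, 1)), rng.uniform(0.1, 10, n), np.ones(n))
    t = 5.0
    s_hat = rng.random(n)
    pred = make_pred([t], s_hat[:, None])
    status = (ds.t > t).astype(float)  # observed survival status at t
    mse = np.mean((status - s_hat) ** 2)
    assert brier_score(pred, ds, t) == pytest.approx(mse, abs=1e-12)


# ---------------------------------------------------------------------------
# C-index


def cindex_oracle(pred, ds, t):
    """Exhaustive double loop over all ordered pairs (i, j)."""
    g = kaplan_meier(ds.t, 1 - ds.d)
    s_hat = pred.survival[:, np.flatnonzero(np.isclose(pred.times, t))[0]]
    num = 0.0
    for i in range(ds.n):
        if ds.d[i] != 1 or ds.t[i] > t:
            continue
        gi = g.evaluate_left(ds.t[i])[0]
        wi = 1.0 / gi if gi > 0 else 0.0
        for j in range(ds.n):
            if ds.t[j] > t and s_hat[j] > s_hat[i]:
                num += wi
    n_future = np.sum(ds.t > t)
    w_past = 0.0
    for k in range(ds.n):
        if ds.d[k] == 1 and ds.t[k] <= t:
            gk = g.evaluate_left(ds.t[k])[0]
            w_past += 1.0 / gk if gk > 0 else 0.0
    return num / (n_future * w_past)


def test_cindex_perfectly_concordant_is_one():
    n = 10
    t_obs = np.arange(1.0, n + 1)
    ds = SurvivalDataset(np.zeros((n, 1)), t_obs, np.ones(n))
    t = 5.5
    pred = make_pred([t], (t_obs / (n + 1))[:, None])  # later event, higher S
    assert c_index(pred, ds, t) == 1.0


def test_cindex_matches_brute_force_pairwise_oracle():
    rng = np.random.default_rng(4)
    for trial in range(5):
        n = 20
        ds = SurvivalDataset(np.zeros((n, 1)), rng.uniform(0.1, 10, n),
                             rng.integers(0, 2, n))
        if not np.any((ds.d == 1) & (ds.t <= 5.0)) or not np.any(ds.t > 5.0):
            continue
        pred = make_pred([5.0], rng.random((n, 1)))
        assert c_index(pred, ds, 5.0) == pytest.approx(
            cindex_oracle(pred, ds, 5.0), abs=1e-12)


def test_cindex_all_tied_predictions_scores_zero():
    ds = SurvivalDataset(np.zeros((6, 1)), [1, 2, 3, 4, 5, 6], np.ones(6))
    pred = make_pred([3.5], np.full((6, 1), 0.5))
    assert c_index(pred, ds, 3.5) == 0.0


def test_cindex_without_comparable_pairs_is_flagged_nan():
    ds = SurvivalDataset(np.zeros((3, 1)), [1, 2, 3], np.ones(3))
    pred = make_pred([10.0], np.random.rand(3, 1))
    with pytest.warns(UserWarning, match="no comparable"):
        assert np.isnan(c_index(pred, ds, 10.0))


@settings(deadline=None, max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 5.0))
def test_cindex_invariant_to_monotone_transforms(seed, scale):
    rng = np.random.default_rng(seed)
    n = 25
    ds = SurvivalDataset(np.zeros((n, 1)), rng.uniform(0.1, 10, n),
                         rng.integers(0, 2, n))
    t = 5.0
    if not np.any((ds.d == 1) & (ds.t <= t)) or not np.any(ds.t > t):
        return
    s = rng.random(n)
    base = c_index(make_pred([t], s[:, None]), ds, t)
    transformed = c_index(make_pred([t], np.exp(scale * s)[:, None]), ds, t)
    assert transformed == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# evaluation horizons


def test_eval_times_quantiles_with_linear_interpolation():
    ds = SurvivalDataset(np.zeros((100, 1)), np.arange(1.0, 101.0),
                         np.ones(100))
    et = eval_times(ds)
    np.testing.assert_allclose(et.times, [25.75, 50.5, 75.25])


def test_eval_times_single_event():
    ds = SurvivalDataset(np.zeros((3, 1)), [7.0, 1.0, 2.0], [1, 0, 0])
    np.testing.assert_array_equal(eval_times(ds).times, [7.0, 7.0, 7.0])


def test_eval_times_ignore_censored_records():
    base = SurvivalDataset(np.zeros((5, 1)), [1, 2, 3, 4, 5], np.ones(5))
    more = SurvivalDataset(np.zeros((8, 1)), [1, 2, 3, 4, 5, 0.1, 9, 20],
                           [1, 1, 1, 1, 1, 0, 0, 0])
    np.testing.assert_array_equal(eval_times(base).times,
                                  eval_times(more).times)
    with pytest.raises(ValueError, match="no uncensored"):
        eval_times(SurvivalDataset(np.zeros((2, 1)), [1, 2], [0, 0]))


# ---------------------------------------------------------------------------
# cross-validation


def test_symmetric_folds_give_identical_metrics():
    """Two folds that are exact copies of each other, evaluated with a
    deterministic stub model, must produce identical per-fold values."""
    rng = np.random.default_rng(5)
    n_half = 30
    X = rng.standard_normal((n_half, 2))
    t = rng.uniform(0.5, 9.5, n_half)
    d = rng.integers(0, 2, n_half)
    d[0] = 1
    ds = SurvivalDataset(np.vstack([X, X]), np.concatenate([t, t]),
                         np.concatenate([d, d]))
    half = np.arange(n_half)
    splits = [(half + n_half, half), (half, half + n_half)]
    stub = stub_mixture(rates=[0.2, 1.0], probs=[0.5, 0.5])

    reports = cross_validate(ds, fitter=lambda train, fold: stub,
                             splits=splits)
    for rep in reports.values():
        np.testing.assert_array_equal(rep.fold_values[0], rep.fold_values[1])


def test_report_mean_and_sd_recomputable_from_folds():
    vals = np.array([[0.1, 0.2], [0.3, 0.4], [np.nan, 0.6]])
    rep = MetricReport("brier", np.array([0.25, 0.5]), np.array([1.0, 2.0]),
                       vals)
    np.testing.assert_allclose(rep.mean, [0.2, 0.4])
    np.testing.assert_allclose(rep.sd, [np.nanstd(vals[:, 0]),
                                        np.nanstd(vals[:, 1])])
    d = rep.to_dict()
    assert d["metric"] == "brier" and len(d["folds"]) == 3
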