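"""Interpretation of the fitted survival clusters.

Once the mixture is trained, each subject is discretely allocated to the
cluster with the highest membership probability; the resulting groups are
summarised by their Kaplan-Meier median survival, cohort share, censoring
proportion and covariate means, compared pairwise with the two-sample
log-rank test, and interrogated with covariate permutation importance on
the assignment network. The number of components itself is chosen by an
elbow rule on the held-out negative log-likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import SurvivalDataset
from .metrics import kaplan_meier

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "ClusterSummary",
    "PermutationImportance",
    "ElbowResult",
    "hard_assign",
    "cluster_summaries",
    "logrank_test",
    "permutation_importance",
    "select_k",
]


@dataclass
class ClusterAssignment:
    labels: np.ndarray      # argmax cluster per subject, ties -> lowest index
    posteriors: np.ndarray  # (n, K) membership probabilities


def hard_assign(model, X) -> ClusterAssignment:
    """Discrete allocation to the highest estimated cluster probability."""
    post = np.asarray(model.assign(X))
    return ClusterAssignment(labels=np.argmax(post, axis=1), posteriors=post)


@dataclass
class ClusterSummary:
    cluster: int
    n_subjects: int
    median_survival: float          # KM median; inf if never reached
    median_censored_above: float | None  # last observed time when median not reached
    population_pct: float
    censored_pct: float
    covariate_means: dict[str, float]

    def format_median(self) -> str:
        if np.isinf(self.median_survival):
            return f">{self.median_censored_above:g}"
        return f"{self.median_survival:g}"


def cluster_summaries(assignment: ClusterAssignment, data: SurvivalDataset,
                      covariates: list[str] | None = None,
                      ) -> list[ClusterSummary]:
    """Per-cluster characteristics table.

    The median survival is the Kaplan-Meier median within the cluster;
    when the curve never crosses 0.5 the median is reported as greater
    than the last observed time in the cluster.
    """
    labels = np.asarray(assignment.labels)
    if labels.shape[0] != data.n:
        raise ValueError("labels and data are not aligned")
    if covariates is None:
        covariates = data.covariate_names
    cov_idx = [data.covariate_names.index(c) for c in covariates]
    K = assignment.posteriors.shape[1]
    out = []
    for k in range(K):
        mask = labels == k
        n_k = int(mask.sum())
        if n_k == 0:
            logger.warning("cluster %d is empty; statistics unavailable", k)
            out.append(ClusterSummary(k, 0, float("nan"), None, 0.0,
                                      float("nan"), {c: float("nan")
                                                     for c in covariates}))
            continue
        km = kaplan_meier(data.t[mask], data.d[mask])
        med = km.median()
        above = float(data.t[mask].max()) if np.isinf(med) else None
        out.append(ClusterSummary(
            cluster=k,
            n_subjects=n_k,
            median_survival=med,
            median_censored_above=above,
            population_pct=100.0 * n_k / data.n,
            censored_pct=100.0 * float(np.mean(data.d[mask] == 0)),
            covariate_means={c: float(data.X[mask, j].mean())
                             for c, j in zip(covariates, cov_idx)},
        ))
    return out


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sample log-rank (Mantel-Haenszel) test.

    Returns (chi-square statistic with 1 df, upper-tail p-value). Ties are
    handled with the hypergeometric variance.
    """
    ta = np.asarray(times_a, dtype=float).ravel()
    tb = np.asarray(times_b, dtype=float).ravel()
    da = np.asarray(events_a).ravel().astype(int)
    db = np.asarray(events_b).ravel().astype(int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    t_all = np.concatenate([ta, tb])
    d_all = np.concatenate([da, db])
    grp = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    event_times = np.unique(t_all[d_all == 1])
    if event_times.size == 0:
        raise ValueError("no events in the pooled sample; log-rank undefined")
    o_minus_e = 0.0
    var = 0.0
    for u in event_times:
        at_risk = t_all >= u
        n = at_risk.sum()
        n1 = (at_risk & (grp == 0)).sum()
        dead = (t_all == u) & (d_all == 1)
        d = dead.sum()
        d1 = (dead & (grp == 0)).sum()
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def pairwise_logrank(labels: np.ndarray, data: SurvivalDataset) -> dict:
    """All pairwise log-rank tests between clusters (no multiplicity
    correction; all p-values are reported so users can adjust)."""
    labels = np.asarray(labels)
    out = {}
    ks = np.unique(labels)
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            ma, mb = labels == a, labels == b
            try:
                chi2, p = logrank_test(data.t[ma], data.d[ma],
                                       data.t[mb], data.d[mb])
            except ValueError:
                chi2, p = float("nan"), float("nan")
            out[(int(a), int(b))] = {"statistic": chi2, "p_value": p}
    return out


@dataclass
class PermutationImportance:
    covariates: list[str]
    scores: np.ndarray   # mean score per covariate over repeats
    n_repeats: int
    seed: int
    score_type: str      # "disagreement" or "nll"


def permutation_importance(model, data: SurvivalDataset, n_repeats: int = 10,
                           seed: int = 0, score: str = "disagreement",
                           ) -> PermutationImportance:
    """Covariate importance for the cluster assignment.

    Each covariate column is permuted across subjects and the effect is
    scored, averaged over ``n_repeats`` seeded permutations:

    * ``"disagreement"`` (default): fraction of subjects whose hard cluster
      label changes — a direct measure of how discriminative the covariate
      is between the groups;
    * ``"nll"``: increase in mean negative log-likelihood.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if score not in ("disagreement", "nll"):
        raise ValueError("score must be 'disagreement' or 'nll'")
    rng = np.random.default_rng(seed)
    base_labels = hard_assign(model, data.X).labels
    if score == "nll":
        from .training import mean_nll
        base_nll = mean_nll(model, data)
    scores = np.zeros(data.n_covariates)
    for j in range(data.n_covariates):
        vals = []
        for _ in range(n_repeats):
            Xp = data.X.copy()
            Xp[:, j] = Xp[rng.permutation(data.n), j]
            if score == "disagreement":
                labels = hard_assign(model, Xp).labels
                vals.append(float(np.mean(labels != base_labels)))
            else:
                perm = SurvivalDataset(Xp, data.t, data.d,
                                       list(data.covariate_names))
                from .training import mean_nll
                vals.append(mean_nll(model, perm) - base_nll)
        scores[j] = np.mean(vals)
    return PermutationImportance(list(data.covariate_names), scores,
                                 n_repeats, seed, score)


@dataclass
class ElbowResult:
    k_values: list[int]
    nll: list[float]        # held-out NLL per candidate K
    selected_k: int


def select_k(data: SurvivalDataset, k_range, head_config=None,
             fit_config=None, dropout_rate: float = 0.25,
             ) -> ElbowResult:
    """Choose the number of mixture components by the elbow rule.

    Fits each candidate K and records the held-out NLL (the early-stopping
    validation loss of the best snapshot); the selected K maximises the
    discrete curvature (second difference) of the NLL sequence. With fewer
    than three candidates, or a curve with no positive curvature, there is
    no elbow: the candidate with the lowest held-out NLL (smallest K on
    ties) is returned with a warning.
    """
    from .mixture import AssignmentNetConfig
    from .training import FitConfig, fit

    k_values = sorted(int(k) for k in k_range)
    if not k_values:
        raise ValueError("k_range must be non-empty")
    base = fit_config or FitConfig()
    nlls = []
    for k in k_values:
        ac = AssignmentNetConfig(n_clusters=k, dropout_rate=dropout_rate)
        _, history = fit(data, head_config, ac, base)
        nlls.append(history[-1].best_validation_nll)
    selected = _elbow(k_values, nlls)
    return ElbowResult(k_values, [float(v) for v in nlls], selected)


def _elbow(k_values: list[int], nlls: list[float]) -> int:
    if len(k_values) == 1:
        return k_values[0]
    if len(k_values) < 3:
        warnings.warn("fewer than 3 candidates: no elbow; choosing lowest NLL")
        return k_values[int(np.argmin(nlls))]
    nll = np.asarray(nlls, dtype=float)
    curvature = nll[:-2] - 2 * nll[1:-1] + nll[2:]  # at interior candidates
    scale = max(1.0, float(np.max(np.abs(nll))))
    if np.max(curvature) <= 1e-12 * scale:
        warnings.warn("no elbow (curve has no positive curvature); "
                      "returning the smallest candidate K")
        return k_values[0]
    return k_values[1 + int(np.argmax(curvature))]
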