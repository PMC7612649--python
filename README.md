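# survclust

Survival clustering with mixtures of monotone neural cumulative hazards.

Clinical cohorts are rarely homogeneous: different latent subpopulations
(phenotypes) follow different time-to-event distributions, and knowing
*which groups exist* is often as valuable as predicting individual risk.
`survclust` discovers such groups directly from right-censored survival
data, for biostatisticians and epidemiologists who want interpretable
population-level survival curves rather than a black-box risk score.

## Model

Each subject contributes a triple (x, t, d): covariates, the last
observation time, and an event indicator (d = 1 event, d = 0
right-censored). The model is a K-component mixture

    S(t | x) = Σ_k α_k(x) · exp(−Λ_k(t))

* **Cluster hazards.** Λ_k(t) is a small feed-forward network taking the
  (rescaled) time and a learnable latent cluster code l_k. All weights on
  paths from the time input are squared (hence non-negative) and the
  activation (tanh) is increasing, so Λ_k is non-decreasing in t; the
  network's value at t = 0 is subtracted so Λ_k(0) = 0 exactly. Each
  component is therefore a valid, fully non-parametric cumulative hazard
  that does **not** read any subject's covariates — clusters are
  population-level objects.
* **Assignment.** α(x) is the softmax output of an MLP with inter-layer
  dropout: covariates only decide *membership*, never the shape of a
  cluster's survival curve.
* **Training.** The exact right-censored log likelihood

      l = Σ_{i: d_i=1} log Σ_k α_k(x_i) λ_k(t_i) e^{−Λ_k(t_i)}
        + Σ_{i: d_i=0} log Σ_k α_k(x_i) e^{−Λ_k(t_i)}

  is maximised with Adam, where the instantaneous hazard
  λ_k = dΛ_k/dt is the *exact* derivative of the network (computed
  analytically by a forward-mode sweep, not by quadrature), evaluated in
  the log domain for numerical stability. Early stopping monitors the
  NLL of a 10% held-out slice of the training split.

The package also ships the matching evaluation stack (Kaplan–Meier,
IPCW, time-dependent Brier score and cumulative time-dependent C-index
at the 0.25/0.5/0.75 quantiles of the uncensored event times, 5-fold
cross-validation), cluster interpretation tools (hard allocation,
per-cluster Kaplan–Meier summaries, pairwise log-rank tests, covariate
permutation importance, elbow-rule selection of K) and seeded synthetic
cohort generators with closed-form ground truth.

## Worked example

```python
import numpy as np
from survclust import SurvivalMixtureClustering, SimConfig, simulate_clustered
from survclust.cluster import cluster_summaries, hard_assign, pairwise_logrank

cohort = simulate_clustered(SimConfig(seed=3))   # 2 Weibull clusters, 30% censoring
ds = cohort.dataset

est = SurvivalMixtureClustering(n_clusters=2, random_state=3)
est.fit(ds.X, (ds.t, ds.d))

labels = est.predict(ds.X)                       # hard cluster allocation
assignment = hard_assign(est.model_, ds.X)
summaries = cluster_summaries(assignment, ds, covariates=[])
tests = pairwise_logrank(assignment.labels, ds)
surv = est.cluster_survival(np.array([0.5, 1.0, 2.0, 4.0]))
```

Output:

```
cohort: n=2000, 30.0% censored
adjusted Rand index vs ground truth: 0.939
cluster 0: median survival 4.57535,  52.8% of cohort, 47.6% censored
cluster 1: median survival 0.768823,  47.2% of cohort, 10.3% censored
log-rank cluster 0 vs 1: chi2=1932.7, p=0.00e+00
cluster survival S_k(t) at t = [0.5, 1.0, 2.0, 4.0]
[[0.997 0.992 0.97  0.668]
 [0.709 0.371 0.049 0.001]]
```

The two recovered population curves track the generating Weibull
survivals (scales 5.0 and 1.0): cluster 0 collects the long-term
survivors (median ~4.6, heavier censoring because fewer events are
observed), cluster 1 the early-event group (median ~0.77), the
allocation agrees with the generating labels (adjusted Rand index 0.94,
at the cohort's Bayes-optimal level), and the log-rank test confirms the
two survival distributions are sharply distinct.

The same pipeline is available from the shell:

```sh
survclust simulate --n 2000 -k 2 --seed 3 --out cohort.csv
survclust fit --data cohort.csv -k 2 --seed 3 --out model.json
survclust evaluate --data cohort.csv --checkpoint model.json --out metrics.json
survclust cluster-report --data cohort.csv --checkpoint model.json --out clusters.json
```

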