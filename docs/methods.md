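# Methods

## Model

`survclust` models a right-censored cohort {(x_i, t_i, d_i)} as a finite
mixture of K population-level survival distributions,

S(t | x) = Σ_k α_k(x) e^{−Λ_k(t)},

with two separated sub-networks:

* **Hazard heads.** Each Λ_k is a feed-forward network on the rescaled
  time s = t / t_max together with a learnable latent code l_k (one per
  cluster, shared by all subjects). Monotonicity in t is enforced
  structurally: every weight on a path from the time input to the output
  is the square of an unconstrained raw parameter, and tanh is strictly
  increasing, so the map s ↦ N(s, l_k) is non-decreasing; subtracting
  N(0, l_k) anchors Λ_k(0) = 0 exactly. The latent code enters through an
  *unconstrained* linear injection at every hidden layer: it conditions
  the curve without breaking monotonicity in t (only time-path weights
  need the constraint). Biases are likewise unconstrained. The output
  layer is a plain positive-weighted linear map — positivity of Λ follows
  from anchoring plus monotonicity, with no output squashing. Squaring
  was chosen over exponentiation or |·| for the positivity map because it
  is smooth at 0 and lets an effective weight vanish exactly.
* **Assignment network.** α(x) = softmax of a ReLU MLP with inter-layer
  (inverted) dropout on z-scored covariates. Dropout is active only
  during training; all predictions are deterministic. Covariates are
  standardised with statistics of the data passed to `fit`, stored in the
  checkpoint; this is a package choice, not part of the model definition.

Assumptions: a single event type, non-informative right censoring, and
covariates that influence *membership* but not the within-cluster
distribution. The family of cluster distributions is otherwise
unconstrained (no proportional hazards, no parametric shape).

## Likelihood and optimisation

The instantaneous hazard λ_k = dΛ_k/dt is computed exactly by a
forward-mode derivative sweep of the head (chain rule through the
affine/tanh layers, with the 1/t_max rescaling factor), so the censored
likelihood

l = Σ_{d_i=1} log Σ_k α_k(x_i) λ_k(t_i) e^{−Λ_k(t_i)} +
Σ_{d_i=0} log Σ_k α_k(x_i) e^{−Λ_k(t_i)}

is exact — no time discretisation or quadrature. It is evaluated as a
max-shifted log-sum-exp over clusters; λ is floored at 1e−10 inside the
logarithm because squared weights can be exactly zero. Parameter
gradients (reverse mode, including through the forward-mode derivative,
which contributes the −2·h·(1−h²) second-order terms of tanh) and the
Adam optimiser are implemented in numpy and verified against central
finite differences in the test suite.

Training minimises the mean NLL per subject (so the gradient scale does
not depend on batch size; the `log_likelihood` API returns the total).
Defaults follow the reference protocol: Adam, learning rate 1e−3 (grid
{1e−3, 1e−4}), batch size 250 (grid {100, 250}), up to 1000 epochs,
early stopping on a 10% slice of the training split. The slice is
stratified on the event indicator and patience is 50 epochs (both
package choices; the protocol states neither). Mini-batches are
reshuffled every epoch from the run seed and the last partial batch is
kept; two fits with the same seed are bit-identical. The returned
parameters are the snapshot with the best held-out NLL. Hyper-parameter
search samples uniformly from the grid (layers 1–3 and width 50/100
shared by both sub-networks, K in 2–5, latent size 10/50/100); duplicate
draws are evaluated once.

Degenerate inputs are rejected rather than patched: events recorded at
t = 0 (the anchor forces zero density there), all-censored cohorts (the
likelihood is maximised by Λ ≡ 0), cohorts with fewer than two records.
Censored records at t = 0 are legal and contribute log 1 = 0. Times
beyond the training maximum are allowed at prediction (extrapolation)
with a warning.

## Evaluation metrics

* **Kaplan–Meier**: product-limit over distinct event times; at tied
  times deaths precede censorings. Curves evaluate right-continuously;
  the left limit G(t⁻) is exposed for weighting. The KM median is the
  smallest t with S(t) ≤ 0.5, reported as "> last observed time" when
  the curve never crosses.
* **IPCW**: G is the KM of the censoring distribution (indicator
  flipped). Event subjects receive ω_i = 1/G(t_i⁻) (left limit — the
  standard convention; the formula leaves it implicit); censored subjects
  receive weight 0, which also resolves the horizon-time sums: a
  censored subject with t_i ≤ t cannot be ordered against anyone.
  Subjects or horizons where G = 0 get weight 0 and are logged.
* **Brier score**: the time-dependent IPCW form, dividing by the full
  sample size n. With no censoring it reduces to the plain mean squared
  error between predicted survival and survival status.
* **C-index**: the cumulative time-dependent form with the weight
  entering once (not squared — deliberately as printed in the source
  formula, which differs from Uno's ω² variant), the i-sum restricted to
  uncensored subjects, and strict inequality on predicted survival, so
  fully tied predictions score 0 and are reported as degenerate.
* **Horizons**: the 0.25/0.5/0.75 empirical quantiles of the uncensored
  subjects' event times, with linear interpolation between order
  statistics (a fixed, documented convention), computed once on the full
  dataset and reused across folds so horizons stay comparable.
* **Cross-validation**: seeded 5-fold splits; per-fold fits use seeds
  derived from the base seed; folds without events or without comparable
  pairs are flagged NaN and excluded from fold means.

## Cluster interpretation

Hard allocation is the argmax of α(x) with lowest-index tie-break.
Summaries report per-cluster KM median, cohort share, censoring
proportion and covariate means — all recomputable from the labels by
integer arithmetic. Pairwise two-sample log-rank tests use the
Mantel–Haenszel statistic with hypergeometric (tie-aware) variance,
1 df; all pairwise p-values are reported without multiplicity
correction so users can adjust as they see fit. Permutation importance
permutes one covariate column at a time and scores the mean hard-label
disagreement rate over seeded repeats (a direct measure of how
discriminative the covariate is between groups); an increase in
held-out NLL is available as an alternative score. The number of
components is selected by the elbow rule on held-out NLL: the candidate
K maximising the discrete second difference; with no positive curvature
the smallest K is returned with a warning, and with fewer than three
candidates the lowest-NLL candidate is returned with a warning.

## Synthetic cohorts

`simulate_clustered` draws standard-normal covariates, assigns cluster
labels through a softmax of a fixed random projection scaled by a
sharpness parameter, and draws event times from per-cluster Weibull
distributions, whose closed-form Λ_k(t) = (t/scale)^shape enables exact
oracle comparisons. Censoring times are independent uniforms whose upper
bound is bisected so the realised censored fraction hits the target.
Defaults: n = 2000, 5 covariates, K = 2, shapes (1.5, 4.0), scales
(1.0, 5.0), 30% censoring, sharpness 16 with orthonormalised projection
rows. The orthonormalisation keeps the logit margin comparable across
seeds, and at sharpness 16 the Bayes-optimal assignment computed from
the true projection reaches an adjusted Rand index of about 0.9 — the
defaults describe clusters that are genuinely recoverable, with a small
irreducible label noise at the decision boundary that no model can
remove.

`simulate_nonlinear_nonph` emulates a harder regime: three covariates
with hazard λ(t|x) = a(x) t^{b(x)−1}, where a(x) = 0.3 + 0.15((x₀ +
0.5x₁)² + x₂²) and b(x) = 0.8 + 1.2·sigmoid(x₁ + 0.5x₀x₂ − 0.3x₂²)
(fixed coefficients). Subject-specific shapes b(x) spanning (0.8, 2.0)
make hazard ratios cross over time — non-proportional hazards — and
event times are drawn by exact inverse-transform sampling, with default
censoring calibrated to 34.5%.

What the generators do *not* emulate: mixed/categorical covariates,
informative censoring, covariate-dependent censoring, measurement error
and non-Weibull within-cluster shapes. Passing the recovery tests shows
the machinery is correct under the stated conditions, not that clusters
found in real clinical data are real phenotypes.

## Problem sizes and numerical tolerances

The test-suite and acceptance-script studies use desk-scale sizes chosen
as this package's own defaults: likelihood exactness on hundreds to a
thousand random instances (tolerance 1e−8 relative); derivative
exactness on 10⁴ (head, time) points against central differences with
step 1e−4·t_max (1e−3 relative); metric estimators against brute-force
double-loop oracles at n = 50 (1e−10); single-component recovery of the
unit-exponential cumulative hazard at n = 5000 (within 10% relative on
the inner 80% of observed times); cluster recovery at n = 2000 over five
seeds (ARI ≥ 0.8 and time-averaged |ΔS| < 0.05 per matched cluster —
curve error is averaged over the observed time range so the threshold is
a probability-scale quantity, invariant to time units); log-rank
nominal level over 2000 null simulations of n = 100 + 100. The external
25k-subject benchmark protocol is implemented but requires a
user-supplied download (`data/external/benchmark_synthetic.csv`); the
corresponding check reports failure when the file is absent.

## Known limitations

* Cluster distributions cannot depend on covariates by design; cohorts
  whose heterogeneity is continuous rather than group-structured are
  better served by individual-level models.
* The likelihood is non-convex; different seeds can find different local
  optima (mitigated by early stopping and, in protocol use, random
  search over hyper-parameters).
* IPCW-based metrics become unstable when the censoring survival G
  approaches zero before an evaluation horizon; affected subjects are
  down-weighted to zero and logged rather than extrapolated.
* Heads are fit jointly with the assignment; label switching across
  folds is resolved only at reporting time (clusters can be matched by
  median survival), not during training.
* The single-monotone-network variant with a K-dimensional output
  (a scalability option) is not implemented; K separate heads are used.
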