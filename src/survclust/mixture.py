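"""Mixture-of-hazards survival model.

An individual's survival function is a covariate-weighted mixture of K
population-level survival distributions:

    S(t | x) = sum_k alpha_k(x) * exp(-Lambda_k(t))

where alpha(x) is the output of a softmax assignment network (a plain MLP
with inter-layer dropout) and each Lambda_k is a monotone neural
cumulative hazard conditioned only on its latent cluster code. The two
sub-networks never mix their inputs: the hazard heads do not read x, the
assignment network does not read t — this is what makes the clusters
population-level objects that can be inspected on their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .hazard import HazardHead, HazardHeadConfig, TimeScaler

__all__ = [
    "AssignmentNetConfig",
    "AssignmentNet",
    "MixtureModel",
    "SurvivalPrediction",
    "assign",
    "survival",
    "mixture_density",
]


@dataclass(frozen=True)
class AssignmentNetConfig:
    """Architecture of the cluster-assignment MLP.

    The reference search grid uses K in [2, 5]; any K >= 1 is accepted.
    """

    n_layers: int = 2
    n_hidden: int = 50
    dropout_rate: float = 0.25
    n_clusters: int = 2

    def __post_init__(self):
        if self.n_layers < 0 or self.n_hidden < 1:
            raise ValueError("invalid assignment architecture")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")


class AssignmentNet:
    """ReLU MLP with inter-layer (inverted) dropout and a linear softmax head.

    Dropout is active only when ``training=True``; prediction is
    deterministic.
    """

    def __init__(self, config: AssignmentNetConfig, n_features: int,
                 rng: np.random.Generator | None = None):
        self.config = config
        self.n_features = n_features
        if rng is None:
            rng = np.random.default_rng()
        self.params: dict[str, np.ndarray] = {}
        H, K = config.n_hidden, config.n_clusters
        fan_in = n_features
        for j in range(config.n_layers):
            # He initialisation for ReLU layers
            self.params[f"W{j}"] = rng.normal(0.0, (2.0 / fan_in) ** 0.5,
                                              size=(H, fan_in))
            self.params[f"b{j}"] = np.zeros(H)
            fan_in = H
        self.params["W_out"] = rng.normal(0.0, fan_in**-0.5, size=(K, fan_in))
        self.params["b_out"] = np.zeros(K)

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Return (logits, cache). Dropout masks are drawn only in training."""
        p_drop = self.config.dropout_rate
        h = X
        cache = {"h": [h], "mask": []}
        for j in range(self.config.n_layers):
            z = h @ self.params[f"W{j}"].T + self.params[f"b{j}"]
            h = np.maximum(z, 0.0)
            if training and p_drop > 0.0:
                mask = (rng.random(h.shape) >= p_drop) / (1.0 - p_drop)
                h = h * mask
            else:
                mask = None
            cache["h"].append(h)
            cache["mask"].append(mask)
        logits = h @ self.params["W_out"].T + self.params["b_out"]
        return logits, cache

    def backward(self, cache: dict, d_logits: np.ndarray,
                 grads: dict[str, np.ndarray]) -> None:
        grads["W_out"] += d_logits.T @ cache["h"][-1]
        grads["b_out"] += d_logits.sum(axis=0)
        dh = d_logits @ self.params["W_out"]
        for j in range(self.config.n_layers - 1, -1, -1):
            h_j = cache["h"][j + 1]
            mask = cache["mask"][j]
            if mask is not None:
                dh = dh * mask
            # after dropout scaling, relu derivative via activation sign
            dz = dh * (h_j > 0)
            grads[f"W{j}"] += dz.T @ cache["h"][j]
            grads[f"b{j}"] += dz.sum(axis=0)
            dh = dz @ self.params[f"W{j}"]


@dataclass
class SurvivalPrediction:
    """Mixture survival evaluated on a time grid.

    ``survival[i, j] = sum_k cluster_probs[i, k] * cluster_survival[k, j]``,
    non-increasing along the time axis and equal to 1 at t = 0.
    """

    times: np.ndarray
    survival: np.ndarray          # (n_subjects, n_times)
    cluster_probs: np.ndarray     # (n_subjects, K), rows on the simplex
    cluster_survival: np.ndarray  # (K, n_times)


class MixtureModel:
    """K hazard heads plus the assignment network; evaluates S(t | x).

    Covariates are z-scored with training-split statistics stored on the
    model, so prediction-time inputs are given in original units.
    """

    def __init__(self, heads: list, assignment: AssignmentNet,
                 scaler: TimeScaler, covariate_names: list[str],
                 x_mean: np.ndarray | None = None,
                 x_std: np.ndarray | None = None):
        self.heads = list(heads)
        self.assignment = assignment
        self.scaler = scaler
        self.covariate_names = list(covariate_names)
        p = len(covariate_names)
        self.x_mean = np.zeros(p) if x_mean is None else np.asarray(x_mean, float)
        self.x_std = np.ones(p) if x_std is None else np.asarray(x_std, float)

    @classmethod
    def initialise(cls, covariate_names: list[str], scaler: TimeScaler,
                   head_config: HazardHeadConfig,
                   assign_config: AssignmentNetConfig,
                   rng: np.random.Generator,
                   x_mean=None, x_std=None) -> "MixtureModel":
        heads = [HazardHead(head_config, scaler, rng)
                 for _ in range(assign_config.n_clusters)]
        net = AssignmentNet(assign_config, len(covariate_names), rng)
        return cls(heads, net, scaler, covariate_names, x_mean, x_std)

    @property
    def n_clusters(self) -> int:
        return len(self.heads)

    # -- parameter plumbing (flat dicts for the optimiser / checkpoint) ----

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for k, head in enumerate(self.heads):
            for name, arr in head.params.items():
                out[f"head{k}.{name}"] = arr
        for name, arr in self.assignment.params.items():
            out[f"assign.{name}"] = arr
        return out

    def set_parameters(self, flat: dict[str, np.ndarray]) -> None:
        for k, head in enumerate(self.heads):
            for name in head.params:
                head.params[name] = np.array(flat[f"head{k}.{name}"], dtype=float)
        for name in self.assignment.params:
            self.assignment.params[name] = np.array(flat[f"assign.{name}"],
                                                    dtype=float)

    # -- evaluation --------------------------------------------------------

    def _standardise(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.covariate_names):
            raise ValueError(
                f"expected {len(self.covariate_names)} covariate columns, "
                f"got {X.shape[1]}"
            )
        return (X - self.x_mean) / self.x_std

    def assignment_logits(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.assignment.forward(self._standardise(X))
        return logits

    def assign(self, X: np.ndarray) -> np.ndarray:
        """Cluster-membership probabilities alpha(x); rows on the simplex."""
        return softmax(self.assignment_logits(X), axis=1)

    def log_assign(self, X: np.ndarray) -> np.ndarray:
        return log_softmax(self.assignment_logits(X), axis=1)

    def cluster_cumulative_hazards(self, t) -> np.ndarray:
        """Lambda_k on a time grid, shape (K, n_times)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack([head.cumulative_hazard(t) for head in self.heads])

    def cluster_hazards(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return np.stack([head.instantaneous_hazard(t) for head in self.heads])

    def survival(self, X: np.ndarray, t) -> SurvivalPrediction:
        """Mixture survival S(t|x) = sum_k alpha_k(x) exp(-Lambda_k(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        alpha = self.assign(X)
        cluster_surv = np.exp(-self.cluster_cumulative_hazards(t))  # (K, T)
        return SurvivalPrediction(
            times=t,
            survival=alpha @ cluster_surv,
            cluster_probs=alpha,
            cluster_survival=cluster_surv,
        )

    def mixture_density(self, X: np.ndarray, t) -> np.ndarray:
        """Event density f(t|x) = sum_k alpha_k(x) lambda_k(t) exp(-Lambda_k(t))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        alpha = self.assign(X)
        lam = self.cluster_hazards(t)                          # (K, T)
        surv = np.exp(-self.cluster_cumulative_hazards(t))     # (K, T)
        return alpha @ (lam * surv)


def assign(model: MixtureModel, X) -> np.ndarray:
    """Cluster probabilities alpha(x) for each subject."""
    return model.assign(X)


def survival(model: MixtureModel, X, t) -> SurvivalPrediction:
    """Mixture survival prediction on a time grid."""
    return model.survival(X, t)


def mixture_density(model: MixtureModel, X, t) -> np.ndarray:
    """Mixture event density on a time grid."""
    return model.mixture_density(X, t)
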