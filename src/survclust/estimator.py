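"""scikit-learn style estimator facade.

``SurvivalMixtureClustering`` wraps the mixture model, training loop and
cluster allocation behind the familiar fit/predict surface so the model
composes with sklearn pipelines and model selection. ``y`` may be a
scikit-survival style structured array (event indicator field first,
time field second), a ``(times, events)`` pair of arrays, or a 2-column
array ``[time, event]``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .cluster import hard_assign
from .data import SurvivalDataset
from .hazard import HazardHeadConfig
from .mixture import AssignmentNetConfig
from .training import FitConfig, fit, log_likelihood

__all__ = ["SurvivalMixtureClustering", "as_survival_y"]


def as_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Coerce the accepted y encodings to (times, events)."""
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        if len(names) != 2:
            raise ValueError("structured y must have exactly 2 fields")
        # scikit-survival convention: (event, time)
        event = np.asarray(y[names[0]])
        time = np.asarray(y[names[1]], dtype=float)
        if event.dtype == bool or set(np.unique(event)) <= {0, 1}:
            return time, event.astype(int)
        # fields the other way round
        return np.asarray(y[names[0]], dtype=float), np.asarray(y[names[1]]).astype(int)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return (np.asarray(y[0], dtype=float),
                np.asarray(y[1]).astype(int))
    arr = np.asarray(y)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0].astype(float), arr[:, 1].astype(int)
    raise ValueError(
        "y must be a structured (event, time) array, a (times, events) "
        "pair, or a 2-column [time, event] array"
    )


class SurvivalMixtureClustering(BaseEstimator):
    """Mixture of monotone neural cumulative hazards with softmax assignment.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of mixture components K.
    n_layers, n_hidden : int
        Depth and width used for both the hazard heads and the assignment
        network (the reference grid explores layers 1-3, nodes 50/100).
    latent_dim : int, default=10
        Size of each cluster's learnable latent code.
    dropout_rate : float, default=0.25
        Inter-layer dropout of the assignment network (training only).
    learning_rate, batch_size, n_epochs, early_stop_fraction, patience
        Optimisation settings (Adam with early stopping on held-out NLL).
    random_state : int, default=0
        Seed for initialisation, batching and the early-stopping split.

    Attributes
    ----------
    model_ : MixtureModel
        The fitted mixture (best held-out-NLL snapshot).
    history_ : list of TrainingState
        Per-epoch losses.
    n_features_in_ : int
    """

    def __init__(self, n_clusters: int = 2, n_layers: int = 2,
                 n_hidden: int = 50, latent_dim: int = 10,
                 dropout_rate: float = 0.25, learning_rate: float = 1e-3,
                 batch_size: int = 250, n_epochs: int = 1000,
                 early_stop_fraction: float = 0.10, patience: int = 50,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.n_layers = n_layers
        self.n_hidden = n_hidden
        self.latent_dim = latent_dim
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.n_epochs = n_epochs
        self.early_stop_fraction = early_stop_fraction
        self.patience = patience
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------

    def _dataset(self, X, y) -> SurvivalDataset:
        X = check_array(X, dtype=float)
        t, d = as_survival_y(y)
        names = list(getattr(self, "feature_names_in_", []) or
                     [f"x{j}" for j in range(X.shape[1])])
        return SurvivalDataset(X, t, d, names)

    def fit(self, X, y):
        """Fit by maximum censored-data likelihood."""
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        data = self._dataset(X, y)
        head_cfg = HazardHeadConfig(n_layers=self.n_layers,
                                    n_hidden=self.n_hidden,
                                    latent_dim=self.latent_dim)
        assign_cfg = AssignmentNetConfig(n_layers=self.n_layers,
                                         n_hidden=self.n_hidden,
                                         dropout_rate=self.dropout_rate,
                                         n_clusters=self.n_clusters)
        fit_cfg = FitConfig(learning_rate=self.learning_rate,
                            batch_size=self.batch_size,
                            n_epochs=self.n_epochs,
                            early_stop_fraction=self.early_stop_fraction,
                            patience=self.patience,
                            seed=self.random_state)
        self.model_, self.history_ = fit(data, head_cfg, assign_cfg, fit_cfg)
        self.n_features_in_ = data.n_covariates
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Cluster membership probabilities alpha(x), rows on the simplex."""
        check_is_fitted(self, "model_")
        return self.model_.assign(check_array(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        """Hard cluster labels (argmax of alpha, lowest index on ties)."""
        check_is_fitted(self, "model_")
        return hard_assign(self.model_, check_array(X, dtype=float)).labels

    def predict_survival(self, X, times) -> np.ndarray:
        """Matrix S(t|x) of shape (n_subjects, n_times)."""
        check_is_fitted(self, "model_")
        return self.model_.survival(check_array(X, dtype=float), times).survival

    def cluster_survival(self, times) -> np.ndarray:
        """Population-level S_k(t) per cluster, shape (K, n_times)."""
        check_is_fitted(self, "model_")
        return np.exp(-self.model_.cluster_cumulative_hazards(times))

    def score(self, X, y) -> float:
        """Mean log likelihood per subject (higher is better)."""
        check_is_fitted(self, "model_")
        data = self._dataset(X, y)
        return log_likelihood(self.model_, data) / data.n
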