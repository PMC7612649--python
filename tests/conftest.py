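import numpy as np
import pytest

from survclust.data import SurvivalDataset
from survclust.hazard import HazardHead, HazardHeadConfig, TimeScaler
from survclust.mixture import AssignmentNet, AssignmentNetConfig, MixtureModel


class LinearHazardStub:
    """Stub head with closed-form Lambda(t) = rate * t (constant hazard)."""

    def __init__(self, rate: float):
        self.rate = rate

    def cumulative_hazard(self, t):
        return self.rate * np.atleast_1d(np.asarray(t, dtype=float))

    def instantaneous_hazard(self, t):
        return np.full_like(np.atleast_1d(np.asarray(t, dtype=float)),
                            self.rate)


def make_head(rng, n_layers=2, n_hidden=8, latent_dim=4, t_max=5.0):
    cfg = HazardHeadConfig(n_layers=n_layers, n_hidden=n_hidden,
                           latent_dim=latent_dim)
    return HazardHead(cfg, TimeScaler(t_max), rng)


def make_model(rng, n_clusters=2, n_features=3, n_layers=2, n_hidden=6,
               latent_dim=3, dropout=0.0, t_max=5.0):
    hc = HazardHeadConfig(n_layers=n_layers, n_hidden=n_hidden,
                          latent_dim=latent_dim)
    ac = AssignmentNetConfig(n_layers=n_layers, n_hidden=n_hidden,
                             dropout_rate=dropout, n_clusters=n_clusters)
    names = [f"x{j}" for j in range(n_features)]
    return MixtureModel.initialise(names, TimeScaler(t_max), hc, ac, rng)


def stub_mixture(rates, probs, n_features=2, t_max=10.0):
    """Mixture with constant-hazard stub heads and a fixed alpha."""
    cfg = AssignmentNetConfig(n_layers=0, n_hidden=1, dropout_rate=0.0,
                              n_clusters=len(rates))
    net = AssignmentNet(cfg, n_features, np.random.default_rng(0))
    net.params["W_out"][:] = 0.0
    net.params["b_out"][:] = np.log(np.asarray(probs, dtype=float))
    heads = [LinearHazardStub(r) for r in rates]
    return MixtureModel(heads, net, TimeScaler(t_max),
                        [f"x{j}" for j in range(n_features)])


def random_dataset(rng, n=20, p=3, censor_frac=0.4):
    X = rng.standard_normal((n, p))
    t = rng.uniform(0.05, 4.0, n)
    d = (rng.random(n) > censor_frac).astype(int)
    if not d.any():
        d[0] = 1
    return SurvivalDataset(X, t, d)


@pytest.fixture(scope="session")
def clustered_cohort():
    from survclust.simulate import SimConfig, simulate_clustered
    return simulate_clustered(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_fitted(clustered_cohort):
    """A quickly fitted 2-cluster model on a subset of the cohort."""
    from survclust.training import FitConfig, fit
    ds = clustered_cohort.dataset.subset(np.arange(600))
    model, history = fit(
        ds,
        HazardHeadConfig(n_layers=1, n_hidden=16, latent_dim=4),
        AssignmentNetConfig(n_layers=1, n_hidden=16, dropout_rate=0.1,
                            n_clusters=2),
        FitConfig(n_epochs=60, patience=60, seed=5),
    )
    return model, history, ds
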