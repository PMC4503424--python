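"""Shared fixtures: tiny constructed environments and probe-only models."""

import numpy as np
import pytest

from adsyn.datasets import CategorySpec, Dataset
from adsyn.network import NetworkState
from adsyn.training import AdaptiveSynaptogenesisNetwork


def make_coactive_dataset(m: int = 10, p: float = 0.3,
                          n_patterns: int = 100) -> Dataset:
    """All ``m`` lines fire together in a fraction ``p`` of patterns.

    The simplest convergent environment: one perfectly correlated
    category whose covariance is p(1-p) everywhere, so the dominant
    eigenvector is uniform and the converged weights have the closed
    form (1-p) on every line.
    """
    n_on = int(round(p * n_patterns))
    patterns = np.zeros((n_patterns, m), dtype=np.uint8)
    patterns[:n_on] = 1
    cats = [
        CategorySpec("ON", np.arange(m), n_on, n_on / n_patterns),
        CategorySpec("OFF", np.array([], dtype=np.int64),
                     n_patterns - n_on, 1 - n_on / n_patterns),
    ]
    return Dataset(name="coactive", patterns=patterns,
                   labels=[0] * n_on + [1] * (n_patterns - n_on),
                   categories=cats, active_per_pattern=m)


def make_probe_model(connections, weights, theta: float
                     ) -> AdaptiveSynaptogenesisNetwork:
    """Wrap explicit synaptic matrices in a probe-only (fitted) model."""
    connections = np.asarray(connections, dtype=np.uint8)
    weights = np.asarray(weights, dtype=np.float64) * connections
    n_neurons, n_lines = connections.shape
    model = AdaptiveSynaptogenesisNetwork(n_neurons=n_neurons, theta=theta)
    model.state_ = NetworkState(connections, weights, np.zeros(n_neurons))
    model.connections_ = connections
    model.weights_ = weights
    model.zbar_ = model.state_.zbar
    model.n_features_in_ = n_lines
    model.converged_ = np.ones(n_neurons, dtype=bool)
    return model


@pytest.fixture
def coactive_dataset():
    return make_coactive_dataset()


@pytest.fixture(scope="session")
def coactive_run():
    """A small fully-converged run on the co-active toy environment."""
    from adsyn.training import train
    from adsyn.network import Params

    ds = make_coactive_dataset()
    params = Params(gamma=0.05, rho=0.1, theta=0.8, alpha=0.95)
    from adsyn.training import Schedule
    model = train(ds, params,
                  Schedule(max_blocks=150, stability_window=40),
                  n_neurons=6, seed=7)
    return ds, model
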