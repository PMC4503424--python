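"""Single-timestep dynamics of the McCulloch-Pitts output layer.

The layer is purely feedforward and excitatory.  On each timestep a binary
input vector ``x`` drives linear excitation ``y_j = sum_i x_i c_ij w_ij``;
a neuron fires iff ``y_j >= theta`` (boundary inclusive).  Existing
synapses are then updated by the covariance rule

    dw_ij = eps * (x_i - E[x_i] - w_ij) * y_j

which scales with the analog excitation ``y_j``, not the binary output,
so sub-threshold excitation still moves weights.  Each neuron also keeps
an exponential moving average ``zbar`` of its own firing used to gate
synaptogenesis (see :mod:`adsyn.training`).

There is no inhibition, no saturation, and no interaction between output
neurons.  Weights are never clamped: the update self-bounds them below 1
(because ``x - E[x] < 1``) and the shedding rule removes any weight that
falls under the shed threshold, so no negative weights persist.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Params",
    "PRESETS",
    "preset",
    "NetworkState",
    "excitation",
    "fire",
    "update_zbar",
    "associative_update",
]


@dataclass(frozen=True)
class Params:
    """Scalar constants of the plasticity algorithm.

    epsilon
        associative learning rate.
    alpha
        moving-average retention of the firing-rate estimate zbar.
    gamma
        Bernoulli rate of synapse formation per absent connection per
        block, while the neuron is receptive.
    rho
        minimum desired firing rate; receptivity is gamma while
        zbar < rho (strict) and exactly zero otherwise.
    theta
        firing threshold on linear excitation.
    w_init
        weight of a newly formed synapse.
    shed_threshold
        a synapse is removed when its weight falls strictly below this.
    init_connections
        number of random connections per neuron at birth.
    """

    epsilon: float = 0.001
    alpha: float = 0.99
    gamma: float = 0.001
    rho: float = 0.1
    theta: float = 0.8
    w_init: float = 0.2
    shed_threshold: float = 0.01
    init_connections: int = 1

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        for name in ("epsilon", "gamma", "theta", "w_init", "shed_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.w_init <= self.shed_threshold:
            raise ValueError("w_init must exceed shed_threshold")
        if self.init_connections < 1:
            raise ValueError("init_connections must be positive")

    def replace(self, **kw) -> "Params":
        return replace(self, **kw)


#: Published parameterizations: preset "A" for the 80-line environment,
#: preset "B" for the 390-line environments.
PRESETS = {
    "A": Params(alpha=0.95, rho=0.09, theta=3.0),
    "B": Params(alpha=0.99, rho=0.1, theta=0.8),
}


def preset(name: str) -> Params:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; expected 'A' or 'B'")


@dataclass
class NetworkState:
    """Mutable synaptic state of a layer of independent neurons.

    ``weights[j, i]`` is meaningful only where ``connections[j, i] == 1``
    and is kept at exactly 0.0 elsewhere.
    """

    connections: np.ndarray  # (n_neurons, n_lines) uint8
    weights: np.ndarray      # (n_neurons, n_lines) float64
    zbar: np.ndarray         # (n_neurons,) float64

    @property
    def n_neurons(self) -> int:
        return self.connections.shape[0]

    @property
    def n_lines(self) -> int:
        return self.connections.shape[1]

    @property
    def synapse_counts(self) -> np.ndarray:
        return self.connections.sum(axis=1).astype(np.int64)

    def effective_weights(self) -> np.ndarray:
        return self.weights * self.connections

    @classmethod
    def initialize(cls, n_neurons: int, n_lines: int, params: Params,
                   rng: np.random.Generator) -> "NetworkState":
        """Give each neuron ``init_connections`` random lines at w_init.

        zbar starts at 0, so every neuron is initially receptive.
        """
        connections = np.zeros((n_neurons, n_lines), dtype=np.uint8)
        weights = np.zeros((n_neurons, n_lines), dtype=np.float64)
        for j in range(n_neurons):
            lines = rng.choice(n_lines, size=params.init_connections,
                               replace=False)
            connections[j, lines] = 1
            weights[j, lines] = params.w_init
        return cls(connections, weights, np.zeros(n_neurons))

    def connection_lists(self) -> list[np.ndarray]:
        """Per-neuron 0-based indices of connected lines."""
        return [np.flatnonzero(row) for row in self.connections]

    def save(self, path) -> None:
        np.savez(Path(path), connections=self.connections,
                 weights=self.weights, zbar=self.zbar)

    @classmethod
    def load(cls, path) -> "NetworkState":
        with np.load(Path(path)) as data:
            return cls(data["connections"], data["weights"], data["zbar"])


def excitation(x: np.ndarray, state: NetworkState) -> np.ndarray:
    """Linear excitation y_j = sum_i x_i c_ij w_ij for every neuron."""
    x = np.asarray(x)
    if x.shape != (state.n_lines,):
        raise ValueError(f"x has shape {x.shape}, "
                         f"expected ({state.n_lines},)")
    return state.effective_weights() @ x.astype(np.float64)


def fire(y: np.ndarray, theta: float) -> np.ndarray:
    """Threshold comparison, boundary inclusive: z_j = 1 iff y_j >= theta."""
    return (np.asarray(y) >= theta).astype(np.uint8)


def update_zbar(zbar: np.ndarray, fired: np.ndarray,
                alpha: float) -> np.ndarray:
    """One exponential-moving-average step of the firing-rate estimate."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return np.asarray(zbar) * alpha + np.asarray(fired) * (1.0 - alpha)


def associative_update(state: NetworkState, x: np.ndarray,
                       mean_activity: np.ndarray, y: np.ndarray,
                       epsilon: float) -> np.ndarray:
    """Covariance-rule weight update on existing connections.

    Returns the new weight matrix (zeros off-connection); ``y`` must be
    the excitation computed from the same ``x`` and the pre-update
    weights.  Weights may transiently fall below the shed threshold —
    removal is the shedding pass's job.
    """
    x = np.asarray(x, dtype=np.float64)
    drive = (x - np.asarray(mean_activity, dtype=np.float64))[None, :]
    delta = epsilon * (drive - state.weights) * np.asarray(y)[:, None]
    return (state.weights + delta) * state.connections
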