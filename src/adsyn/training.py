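"""Training orchestration across the three timescales.

Timescales, fastest to slowest:

1. **per step** — excitation, firing, covariance weight update, and (by
   default) shedding of any weight that falls below the shed threshold;
2. **per cycle** — every pattern of the training multiset is presented
   once, in a freshly shuffled order;
3. **per block** (10 cycles) — synaptogenesis: every neuron whose average
   firing rate ``zbar`` is strictly below the minimum desired rate ``rho``
   receives each absent connection independently with probability
   ``gamma``, at the initial weight.

A neuron whose connection set is unchanged for ``stability_window``
consecutive blocks is considered converged; by default it is then frozen
(excluded from further dynamics), which is what makes full runs cheap.
Shedding can instead be deferred to block boundaries
(``shed_cadence="block"``), and freezing can be disabled, for fidelity
studies.

The estimator follows scikit-learn conventions: all knobs are constructor
arguments, ``fit`` consumes the (n_patterns, n_lines) binary training
multiset, fitted state lives in trailing-underscore attributes, and
``transform`` maps patterns to binary firing vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._kernel import run_block
from .datasets import Dataset
from .network import NetworkState, Params, preset

__all__ = [
    "Schedule",
    "AdaptiveSynaptogenesisNetwork",
    "synaptogenesis_pass",
    "shed_pass",
    "train",
    "firing_rates",
    "history_frame",
]


@dataclass(frozen=True)
class Schedule:
    """Block structure and stopping rule of a training run."""

    cycles_per_block: int = 10
    max_blocks: int = 2000
    stability_window: int = 200
    shuffle_within_cycle: bool = True

    def __post_init__(self):
        if self.stability_window >= self.max_blocks:
            raise ValueError("stability_window must be < max_blocks")
        if self.cycles_per_block < 1:
            raise ValueError("cycles_per_block must be positive")


def synaptogenesis_pass(state: NetworkState, params: Params,
                        rng: np.random.Generator,
                        frozen: np.ndarray | None = None) -> np.ndarray:
    """Block-boundary synapse formation; returns per-neuron gain counts.

    Only neurons with ``zbar < rho`` (strict) are receptive; for them each
    absent connection independently becomes present with probability
    ``gamma`` at weight ``w_init``.  Mutates ``state`` in place.
    """
    receptive = state.zbar < params.rho
    if frozen is not None:
        receptive &= ~frozen
    gains = np.zeros(state.n_neurons, dtype=np.int64)
    rows = np.flatnonzero(receptive)
    if rows.size:
        draws = rng.random((rows.size, state.n_lines)) < params.gamma
        new = draws & (state.connections[rows] == 0)
        gains[rows] = new.sum(axis=1)
        state.connections[rows] = state.connections[rows] | new.astype(np.uint8)
        state.weights[rows] = np.where(new, params.w_init,
                                       state.weights[rows])
    return gains


def shed_pass(state: NetworkState, params: Params,
              frozen: np.ndarray | None = None) -> np.ndarray:
    """Remove every connection whose weight is strictly below the
    shed threshold; returns per-neuron shed counts.  Mutates in place."""
    mask = (state.connections == 1) & (state.weights < params.shed_threshold)
    if frozen is not None:
        mask &= ~frozen[:, None]
    sheds = mask.sum(axis=1).astype(np.int64)
    state.connections[mask] = 0
    state.weights[mask] = 0.0
    return sheds


def _run_block_numpy(patterns, order, connections, weights, zbar, frozen,
                     mean_activity, epsilon, alpha, theta, shed_threshold,
                     shed_each_step):
    """Pure-NumPy reference for :func:`adsyn._kernel.run_block`.

    Same contract and state mutation; kept as an independent check of the
    compiled kernel and as a fallback engine.
    """
    shed_count = np.zeros(connections.shape[0], dtype=np.int64)
    active = ~frozen
    for t in order:
        x = patterns[t].astype(np.float64)
        y = (weights * connections) @ x
        rows = np.flatnonzero(active & (y > 0.0))
        if rows.size:
            w_rows = weights[rows]
            w_rows = w_rows + epsilon * (
                (x - mean_activity)[None, :] - w_rows) * y[rows, None]
            w_rows *= connections[rows]
            if shed_each_step:
                shed = (connections[rows] == 1) & (w_rows < shed_threshold)
                if shed.any():
                    shed_count[rows] += shed.sum(axis=1)
                    connections[rows] = np.where(shed, 0, connections[rows])
                    w_rows[shed] = 0.0
            weights[rows] = w_rows
        zbar[active] = (zbar[active] * alpha
                        + (y[active] >= theta) * (1.0 - alpha))
    return shed_count


class AdaptiveSynaptogenesisNetwork(TransformerMixin, BaseEstimator):
    """Feedforward layer of independent neurons built by adaptive
    synaptogenesis, as a scikit-learn transformer.

    ``fit(X)`` consumes the binary training multiset (one row per
    presentation; frequency encoded by row multiplicity) and runs the
    full three-timescale dynamics until every neuron's connection set has
    been stable for ``stability_window`` blocks or ``max_blocks`` is
    reached.  ``transform(X)`` returns binary firing vectors with
    plasticity off.

    Parameters mirror :class:`adsyn.network.Params` plus the
    :class:`Schedule`; ``from_preset("A" | "B")`` applies the published
    parameterizations.

    Attributes
    ----------
    connections_, weights_, zbar_ : ndarray
        Final synaptic state (also as ``state_``).
    converged_ : bool ndarray
        Per neuron: connection set unchanged over a full stability window.
    convergence_block_ : int ndarray
        Block of the last connection change (-1 for unconverged neurons).
    history_ : dict of ndarray
        ``synapses``, ``gained``, ``shed`` — (n_blocks, n_neurons),
        recorded after each block's synaptogenesis pass.
    n_blocks_ : int
        Number of blocks actually run.
    """

    def __init__(self, n_neurons=100, *, epsilon=0.001, alpha=0.99,
                 gamma=0.001, rho=0.1, theta=0.8, w_init=0.2,
                 shed_threshold=0.01, init_connections=1,
                 cycles_per_block=10, max_blocks=2000, stability_window=200,
                 shuffle_within_cycle=True, shed_cadence="step",
                 freeze_converged=True, engine="numba", mean_activity=None,
                 random_state=None):
        self.n_neurons = n_neurons
        self.epsilon = epsilon
        self.alpha = alpha
        self.gamma = gamma
        self.rho = rho
        self.theta = theta
        self.w_init = w_init
        self.shed_threshold = shed_threshold
        self.init_connections = init_connections
        self.cycles_per_block = cycles_per_block
        self.max_blocks = max_blocks
        self.stability_window = stability_window
        self.shuffle_within_cycle = shuffle_within_cycle
        self.shed_cadence = shed_cadence
        self.freeze_converged = freeze_converged
        self.engine = engine
        self.mean_activity = mean_activity
        self.random_state = random_state

    @classmethod
    def from_preset(cls, name: str, **overrides):
        p = preset(name)
        kw = dict(epsilon=p.epsilon, alpha=p.alpha, gamma=p.gamma, rho=p.rho,
                  theta=p.theta, w_init=p.w_init,
                  shed_threshold=p.shed_threshold,
                  init_connections=p.init_connections)
        kw.update(overrides)
        return cls(**kw)

    # ------------------------------------------------------------ helpers

    def _params(self) -> Params:
        return Params(epsilon=self.epsilon, alpha=self.alpha,
                      gamma=self.gamma, rho=self.rho, theta=self.theta,
                      w_init=self.w_init, shed_threshold=self.shed_threshold,
                      init_connections=self.init_connections)

    def _schedule(self) -> Schedule:
        return Schedule(cycles_per_block=self.cycles_per_block,
                        max_blocks=self.max_blocks,
                        stability_window=self.stability_window,
                        shuffle_within_cycle=self.shuffle_within_cycle)

    @staticmethod
    def _validate_patterns(X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty 2d pattern matrix")
        if not np.isin(X, (0, 1)).all():
            raise ValueError("patterns must be binary (0/1)")
        return np.ascontiguousarray(X, dtype=np.uint8)

    # ------------------------------------------------------------ fitting

    def fit(self, X, y=None):
        """Run adaptive synaptogenesis on the training multiset ``X``.

        RNG draw order per run: initial connections, then per block the
        within-cycle pattern shuffles followed by the synaptogenesis
        draws — a single Generator stream, so runs are exactly
        reproducible from ``random_state``.
        """
        X = self._validate_patterns(X)
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be positive")
        if self.shed_cadence not in ("step", "block"):
            raise ValueError("shed_cadence must be 'step' or 'block'")
        if self.engine not in ("numba", "numpy"):
            raise ValueError("engine must be 'numba' or 'numpy'")
        params = self._params()
        sched = self._schedule()
        n_patterns, n_lines = X.shape
        self.n_features_in_ = n_lines
        rng = np.random.default_rng(self.random_state)
        ex = (X.mean(axis=0) if self.mean_activity is None
              else np.asarray(self.mean_activity, dtype=np.float64))
        if ex.shape != (n_lines,):
            raise ValueError("mean_activity has wrong length")
        state = NetworkState.initialize(self.n_neurons, n_lines, params, rng)
        frozen = np.zeros(self.n_neurons, dtype=bool)
        last_change = np.zeros(self.n_neurons, dtype=np.int64)
        step = run_block if self.engine == "numba" else _run_block_numpy
        shed_each_step = self.shed_cadence == "step"
        base = np.arange(n_patterns, dtype=np.int64)
        hist_syn, hist_gain, hist_shed = [], [], []
        block = 0
        while block < sched.max_blocks:
            block += 1
            if sched.shuffle_within_cycle:
                order = np.concatenate([rng.permutation(n_patterns)
                                        for _ in range(sched.cycles_per_block)])
            else:
                order = np.tile(base, sched.cycles_per_block)
            sheds = step(X, order, state.connections, state.weights,
                         state.zbar, frozen, ex, params.epsilon, params.alpha,
                         params.theta, params.shed_threshold, shed_each_step)
            if not shed_each_step:
                sheds = sheds + shed_pass(state, params, frozen)
            gains = synaptogenesis_pass(state, params, rng, frozen)
            changed = (gains > 0) | (sheds > 0)
            last_change[changed] = block
            hist_syn.append(state.synapse_counts)
            hist_gain.append(gains)
            hist_shed.append(sheds)
            if self.freeze_converged:
                frozen |= block - last_change >= sched.stability_window
                if frozen.all():
                    break
        self.state_ = state
        self.connections_ = state.connections
        self.weights_ = state.weights
        self.zbar_ = state.zbar
        self.mean_activity_ = ex
        self.n_blocks_ = block
        self.last_change_block_ = last_change
        self.converged_ = frozen | (block - last_change
                                    >= sched.stability_window)
        self.convergence_block_ = np.where(self.converged_, last_change, -1)
        self.history_ = {
            "synapses": np.array(hist_syn),
            "gained": np.array(hist_gain),
            "shed": np.array(hist_shed),
        }
        return self

    # ------------------------------------------------------------ probing

    def decision_function(self, X) -> np.ndarray:
        """Excitations (n_samples, n_neurons) with plasticity off."""
        if not hasattr(self, "weights_"):
            raise AttributeError("estimator is not fitted")
        X = self._validate_patterns(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has wrong number of input lines")
        return X.astype(np.float64) @ (self.weights_ * self.connections_).T

    def transform(self, X, theta: float | None = None) -> np.ndarray:
        """Binary firing vectors (n_samples, n_neurons), plasticity off.

        ``theta`` overrides the training threshold (used by probe
        analyses with a different testing threshold).
        """
        th = self.theta if theta is None else theta
        return (self.decision_function(X) >= th).astype(np.uint8)


def _check_compatible(dataset: Dataset, params: Params) -> None:
    # Published presets are tied to their dataset family.
    for name, famlines in (("A", 80), ("B", 390)):
        if params == preset(name) and dataset.n_lines != famlines:
            raise ValueError(
                f"preset {name!r} expects {famlines} input lines, but "
                f"dataset {dataset.name!r} has {dataset.n_lines}")


def train(dataset: Dataset, params: Params | str | None = None,
          schedule: Schedule | None = None, n_neurons: int = 100,
          seed: int | None = None,
          **overrides) -> AdaptiveSynaptogenesisNetwork:
    """Train a network on a dataset; thin wrapper over the estimator.

    ``params`` may be a :class:`Params`, a preset name ("A"/"B"), or None
    (preset chosen by the dataset's line count).
    """
    if params is None:
        params = preset("A" if dataset.n_lines == 80 else "B")
    elif isinstance(params, str):
        params = preset(params)
    _check_compatible(dataset, params)
    schedule = schedule or Schedule()
    kw = dict(
        n_neurons=n_neurons, epsilon=params.epsilon, alpha=params.alpha,
        gamma=params.gamma, rho=params.rho, theta=params.theta,
        w_init=params.w_init, shed_threshold=params.shed_threshold,
        init_connections=params.init_connections,
        cycles_per_block=schedule.cycles_per_block,
        max_blocks=schedule.max_blocks,
        stability_window=schedule.stability_window,
        shuffle_within_cycle=schedule.shuffle_within_cycle,
        random_state=seed)
    kw.update(overrides)
    model = AdaptiveSynaptogenesisNetwork(**kw)
    return model.fit(dataset.patterns)


def firing_rates(model: AdaptiveSynaptogenesisNetwork,
                 dataset: Dataset) -> np.ndarray:
    """Fraction of presentations firing each neuron, plasticity off."""
    return model.transform(dataset.patterns).mean(axis=0)


def history_frame(model: AdaptiveSynaptogenesisNetwork) -> pd.DataFrame:
    """Tidy per-(block, neuron) trajectory of synapse counts."""
    n_blocks, n_neurons = model.history_["synapses"].shape
    blocks = np.repeat(np.arange(1, n_blocks + 1), n_neurons)
    neurons = np.tile(np.arange(n_neurons), n_blocks)
    return pd.DataFrame({
        "block": blocks,
        "neuron": neurons,
        "synapses": model.history_["synapses"].ravel(),
        "gained": model.history_["gained"].ravel(),
        "shed": model.history_["shed"].ravel(),
    })
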