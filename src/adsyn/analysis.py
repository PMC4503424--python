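"""Evaluation battery for trained networks.

Four characterizations of how a trained layer represents its input
world:

* **neuron allocation index** — each category's share of all
  neuron-firings elicited by a held-out test set; the headline measure
  of how experience frequency and correlational structure bias neural
  resources;
* **centroid decoder** — a supervised nearest-centroid classifier over
  output vectors, used purely to quantify how discriminable the
  unsupervised code is;
* **statistical dependence** — the multi-information
  ``sum_i H(X_i) - H(X)`` in bits; its reduction from input to output is
  compression;
* **exclusivity counts** — how many neurons fire exclusively to one
  noiseless category prototype (or one overlap sub-region) at a probe
  threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .datasets import Dataset

__all__ = [
    "AllocationReport",
    "ExclusivityReport",
    "CentroidDecoder",
    "allocation_index",
    "fit_centroid_decoder",
    "decode",
    "decoder_error",
    "statistical_dependence",
    "network_size_curves",
    "exclusivity_counts",
    "assign_super_category",
]


# ------------------------------------------------------------- allocation


@dataclass
class AllocationReport:
    """Per-category allocation over a probe of the test set.

    ``shares`` is the firing-count index: the fraction of all
    neuron-firings elicited by each category's test patterns.
    ``neuron_shares`` counts each responding neuron once, assigned to
    the category eliciting the plurality of its firings (ties to the
    lowest category index); for environments with orthogonal categories,
    where every neuron responds to a single category, this is the
    fraction of neurons devoted to each category.
    """

    shares: np.ndarray                 # (n_categories,), sums to 1
    firings: np.ndarray                # raw per-category firing counts
    neuron_shares: np.ndarray          # fraction of responding neurons
    n_responding: int                  # neurons firing at least once
    total_firings: int
    n_neurons: int
    theta: float
    super_shares: np.ndarray | None = None  # aggregated by super-category
    degenerate: bool = False           # no neuron fired at all
    dataset: str = ""


def allocation_index(model, test_dataset: Dataset,
                     theta: float | None = None) -> AllocationReport:
    """Fraction of total neuron-firings produced by each category.

    Firing uses threshold ``theta`` (default: the model's training
    threshold) with plasticity off.  Zero total firings yields an
    explicit degenerate report rather than a division by zero.
    """
    Z = model.transform(test_dataset.patterns, theta=theta)
    n_cat = test_dataset.n_categories
    # firings of each neuron broken down by eliciting category
    onehot = np.zeros((test_dataset.n_patterns, n_cat))
    onehot[np.arange(test_dataset.n_patterns), test_dataset.labels] = 1
    per_neuron = onehot.T @ Z                      # (n_cat, n_neurons)
    firings = per_neuron.sum(axis=1).astype(np.int64)
    total = int(firings.sum())
    degenerate = total == 0
    shares = np.zeros(n_cat) if degenerate else firings / total
    responding = per_neuron.sum(axis=0) > 0
    n_responding = int(responding.sum())
    if n_responding:
        assigned = np.argmax(per_neuron[:, responding], axis=0)
        neuron_shares = np.bincount(assigned, minlength=n_cat) / n_responding
    else:
        neuron_shares = np.zeros(n_cat)
    super_shares = None
    if test_dataset.subregions is not None and n_cat % 3 == 0:
        super_shares = shares.reshape(-1, 3).sum(axis=1)
    return AllocationReport(
        shares=shares, firings=firings, neuron_shares=neuron_shares,
        n_responding=n_responding, total_firings=total,
        n_neurons=Z.shape[1],
        theta=model.theta if theta is None else theta,
        super_shares=super_shares, degenerate=degenerate,
        dataset=test_dataset.name)


# ---------------------------------------------------------------- decoder


class CentroidDecoder(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classifier over network output vectors.

    One centroid per category, computed from training outputs;
    classification picks the closest centroid in Euclidean distance, with
    ties broken deterministically in favour of the lowest category index.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)  # sorted ascending
        self.centroids_ = np.vstack([X[y == c].mean(axis=0)
                                     for c in self.classes_])
        self.n_features_in_ = X.shape[1]
        return self

    def _distances(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        # squared Euclidean; monotone, and exact for tie detection
        return ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(-1)

    def predict(self, X):
        d = self._distances(X)
        return self.classes_[np.argmin(d, axis=1)]  # first min = lowest idx


def fit_centroid_decoder(outputs, labels) -> CentroidDecoder:
    return CentroidDecoder().fit(outputs, labels)


def decode(model: CentroidDecoder, output_vector):
    """Label of a single output vector."""
    return model.predict(np.asarray(output_vector)[None, :])[0]


def decoder_error(model: CentroidDecoder, outputs, labels) -> float:
    """Fraction of output vectors assigned to the wrong category."""
    labels = np.asarray(labels)
    unseen = np.setdiff1d(np.unique(labels), model.classes_)
    if unseen.size:
        raise ValueError(f"labels contain categories unseen at fit time: "
                         f"{unseen.tolist()}")
    return float(np.mean(model.predict(outputs) != labels))


# ----------------------------------------------------------- dependence


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def statistical_dependence(patterns, frequencies=None) -> float:
    """Multi-information sum_i H(X_i) - H(X) in bits (plug-in).

    ``frequencies`` are per-row presentation weights (default uniform
    over the multiset).  The joint entropy aggregates identical rows.
    """
    X = np.asarray(patterns)
    n = X.shape[0]
    f = (np.full(n, 1.0 / n) if frequencies is None
         else np.asarray(frequencies, dtype=np.float64))
    if not np.isclose(f.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    p1 = f @ X  # P(X_i = 1)
    marginal = sum(_entropy(np.array([p, 1.0 - p])) for p in p1)
    _, inverse = np.unique(X, axis=0, return_inverse=True)
    joint = _entropy(np.bincount(inverse, weights=f))
    return marginal - joint


# ------------------------------------------------------------ size curves


def network_size_curves(model, train_dataset: Dataset,
                        test_dataset: Dataset, sizes=(10, 30, 50),
                        n_repeats: int = 100, seed=None,
                        decoder_inputs: str = "excitation") -> pd.DataFrame:
    """Decoder error and output dependence vs sampled network size.

    For each size, ``n_repeats`` neuron subsets are drawn without
    replacement from the trained pool; per subset a centroid decoder is
    fitted on training outputs and scored on train, test and pooled
    outputs, and the statistical dependence of the subset's binary
    training outputs is computed.  Means and standard errors across
    subsets are returned; when size equals the pool, the repeats
    collapse to the single full subset.

    ``decoder_inputs`` selects the representation the decoder sees:
    ``"excitation"`` (default) uses the analog excitations ``y``,
    ``"firing"`` the thresholded binary outputs ``z``.  Statistical
    dependence is always computed on the binary outputs — entropies of
    the spiking code are what the compression measure is about.
    """
    rng = np.random.default_rng(seed)
    if decoder_inputs not in ("excitation", "firing"):
        raise ValueError("decoder_inputs must be 'excitation' or 'firing'")
    Z_train = model.transform(train_dataset.patterns)
    Z_test = model.transform(test_dataset.patterns)
    if decoder_inputs == "excitation":
        D_train = model.decision_function(train_dataset.patterns)
        D_test = model.decision_function(test_dataset.patterns)
    else:
        D_train, D_test = Z_train, Z_test
    y_train, y_test = train_dataset.labels, test_dataset.labels
    y_pool = np.concatenate([y_train, y_test])
    n_neurons = Z_train.shape[1]
    rows = []
    for size in sizes:
        if size > n_neurons:
            raise ValueError(f"size {size} exceeds pool of {n_neurons}")
        reps = 1 if size == n_neurons else n_repeats
        err_tr, err_te, err_po, deps = [], [], [], []
        for _ in range(reps):
            cols = rng.choice(n_neurons, size=size, replace=False)
            dec = CentroidDecoder().fit(D_train[:, cols], y_train)
            pred_tr = dec.predict(D_train[:, cols])
            pred_te = dec.predict(D_test[:, cols])
            err_tr.append(np.mean(pred_tr != y_train))
            err_te.append(np.mean(pred_te != y_test))
            err_po.append(np.mean(np.concatenate([pred_tr, pred_te])
                                  != y_pool))
            deps.append(statistical_dependence(Z_train[:, cols]))
        rows.append({
            "size": size,
            "error": float(np.mean(err_po)),
            "error_se": float(np.std(err_po) / np.sqrt(reps)),
            "error_train": float(np.mean(err_tr)),
            "error_test": float(np.mean(err_te)),
            "dependence": float(np.mean(deps)),
            "dependence_se": float(np.std(deps) / np.sqrt(reps)),
            "n_repeats": reps,
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------ exclusivity


def assign_super_category(model, dataset: Dataset,
                          probe_theta: float = 2.4) -> np.ndarray:
    """Super-category (1..3) capturing each neuron, or 0 if ambiguous.

    A neuron is assigned to the super-category whose noiseless category
    probes fire it; neurons firing probes of no or of several
    super-categories get 0.
    """
    if dataset.subregions is None:
        raise ValueError("super-category assignment needs a sub-region map")
    probes = np.zeros((dataset.n_categories, dataset.n_lines),
                      dtype=np.uint8)
    for c, spec in enumerate(dataset.categories):
        probes[c, spec.prototype_lines] = 1
    F = model.transform(probes, theta=probe_theta).T.astype(bool)
    supers = np.array([dataset.super_category_of(c)
                       for c in range(dataset.n_categories)])
    fired = np.stack([(F[:, supers == s]).any(axis=1) for s in (1, 2, 3)],
                     axis=1)
    out = np.zeros(F.shape[0], dtype=np.int64)
    unique = fired.sum(axis=1) == 1
    out[unique] = np.argmax(fired[unique], axis=1) + 1
    return out


@dataclass
class ExclusivityReport:
    """Exclusive vs non-exclusive responders to noiseless probes."""

    category_exclusive: np.ndarray     # (n_categories,)
    category_nonexclusive: np.ndarray
    subregion_exclusive: np.ndarray    # (21,) for B datasets
    subregion_nonexclusive: np.ndarray
    subregion_ids: list = field(default_factory=list)
    cross_super_firers: int = 0        # neurons firing >= 2 super-categories
    probe_theta: float = 2.4
    n_neurons: int = 0


def exclusivity_counts(model, dataset: Dataset,
                       probe_theta: float = 2.4) -> ExclusivityReport:
    """Count neurons firing exclusively to category / sub-region probes.

    Probes are noiseless: the category probe activates all of a
    category's potentially active lines; a sub-region probe activates all
    lines of one overlap cell.  A neuron is exclusive to a probe when it
    fires to that probe and to no other probe of the same family.
    """
    if dataset.subregions is None:
        raise ValueError("exclusivity analysis needs a sub-region map")
    n_lines = dataset.n_lines
    cat_probes = np.zeros((dataset.n_categories, n_lines), dtype=np.uint8)
    for c, spec in enumerate(dataset.categories):
        cat_probes[c, spec.prototype_lines] = 1
    F = model.transform(cat_probes, theta=probe_theta).T.astype(bool)
    # F: (n_neurons, n_categories)
    n_fired_total = F.sum(axis=1)
    supers = np.array([dataset.super_category_of(c)
                       for c in range(dataset.n_categories)])
    fired_supers = np.stack([(F[:, supers == s]).any(axis=1)
                             for s in (1, 2, 3)], axis=1)
    cross = int((fired_supers.sum(axis=1) >= 2).sum())
    cat_excl = ((F & (n_fired_total == 1)[:, None]).sum(axis=0)
                .astype(np.int64))
    cat_nonexcl = ((F & (n_fired_total >= 2)[:, None]).sum(axis=0)
                   .astype(np.int64))

    regions = dataset.subregions.regions
    sub_probes = np.zeros((len(regions), n_lines), dtype=np.uint8)
    for i, r in enumerate(regions):
        sub_probes[i, r.lines] = 1
    G = model.transform(sub_probes, theta=probe_theta).T.astype(bool)
    g_total = G.sum(axis=1)
    sub_excl = (G & (g_total == 1)[:, None]).sum(axis=0).astype(np.int64)
    sub_nonexcl = (G & (g_total >= 2)[:, None]).sum(axis=0).astype(np.int64)
    return ExclusivityReport(
        category_exclusive=cat_excl, category_nonexclusive=cat_nonexcl,
        subregion_exclusive=sub_excl, subregion_nonexclusive=sub_nonexcl,
        subregion_ids=[(r.super_category, r.region) for r in regions],
        cross_super_firers=cross, probe_theta=probe_theta,
        n_neurons=F.shape[0])
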