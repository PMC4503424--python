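"""The convergence theorem as an executable oracle.

For a neuron whose connection set has stabilized on lines ``S``, the
stationary point of the covariance plasticity rule satisfies the
eigen-equation ``Cov(X_S) w = w E[Y]``: the converged weight vector is
proportional to the dominant eigenvector ``e1`` of the subspace
covariance matrix, with

    E[Y] = lambda_1,    w(inf) = k e1,    k = sqrt(Var(Y) / E[Y]),

equivalently ``k = lambda_1 / (E[X_S]^T e1)`` by self-consistency of
``E[Y]``.  These predictions are computed exactly from the training
pattern multiset and compared against realized weights and probe-epoch
excitation moments of a trained network.

The positivity of ``e1`` (required for weights, which shedding keeps
positive) is checked empirically rather than proved: subspace covariance
matrices routinely carry a few mildly negative entries yet still have an
all-positive dominant eigenvector.

The theorem presumes the dynamics halt.  They need not: a category that
is orthogonal to the rest of the input space and occurs less often than
the minimum desired firing rate pins its neurons' firing below the
receptivity cutoff, so synaptogenesis never stops.
:func:`detect_pathological` screens datasets for this configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import Dataset

__all__ = [
    "TheoryReport",
    "subspace_covariance",
    "dominant_eig",
    "predicted_fixed_point",
    "check_convergence_theorem",
    "detect_pathological",
]


@dataclass
class TheoryReport:
    """Per-neuron comparison of realized weights to the eigen prediction."""

    neuron: int
    connected_lines: np.ndarray
    lambda1: float
    e1: np.ndarray
    k: float
    predicted_weights: np.ndarray
    realized_weights: np.ndarray
    mean_Y: float              # predicted = lambda1
    var_Y: float               # predicted = k^2 * lambda1
    realized_mean_Y: float
    realized_var_Y: float
    alignment_error: float     # max relative element-wise deviation
    alignment_median: float    # median relative element-wise deviation
    e1_all_positive: bool
    n_negative_cov_entries: int
    converged: bool


def subspace_covariance(dataset: Dataset, lines) -> np.ndarray:
    """Covariance of the selected input lines over the pattern multiset.

    Exact plug-in Cov(X) = E[X X^T] - E[X] E[X^T]; the multiset encodes
    presentation frequencies by row multiplicity, so uniform row weights
    give the frequency-weighted covariance.
    """
    lines = np.asarray(lines, dtype=np.int64)
    if lines.size == 0:
        raise ValueError("line set is empty")
    sub = dataset.patterns[:, lines].astype(np.float64)
    mu = sub.mean(axis=0)
    return sub.T @ sub / sub.shape[0] - np.outer(mu, mu)


def dominant_eig(cov: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest eigenvalue and unit eigenvector of a symmetric matrix.

    The eigenvector sign is fixed so its entry sum is positive (weights
    live in the positive orthant).
    """
    cov = np.asarray(cov, dtype=np.float64)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(cov)
    lam = float(eigvals[-1])
    e1 = eigvecs[:, -1]
    if e1.sum() < 0:
        e1 = -e1
    return lam, e1


def predicted_fixed_point(dataset: Dataset, lines) -> dict:
    """Predicted converged weights and excitation moments for a line set.

    Solves the scale constant from self-consistency of the mean
    excitation, ``E[X_S]^T (k e1) = lambda_1``, and returns the algebraic
    twins ``E[Y] = lambda_1`` and ``Var(Y) = k^2 lambda_1`` (so that
    ``k = sqrt(Var(Y)/E[Y])`` holds identically).
    """
    lines = np.asarray(lines, dtype=np.int64)
    cov = subspace_covariance(dataset, lines)
    lam, e1 = dominant_eig(cov)
    ex = dataset.patterns[:, lines].mean(axis=0)
    denom = float(ex @ e1)
    if denom <= 0:
        raise ValueError("degenerate subspace: E[X]^T e1 <= 0")
    k = lam / denom
    return {
        "lines": lines,
        "cov": cov,
        "lambda1": lam,
        "e1": e1,
        "k": k,
        "predicted_weights": k * e1,
        "mean_Y": lam,
        "var_Y": k * k * lam,
        "e1_all_positive": bool((e1 > 0).all()),
        "n_negative_cov_entries": int((cov < 0).sum()),
    }


def check_convergence_theorem(model, dataset: Dataset,
                              tolerance: float = 0.02
                              ) -> list[TheoryReport]:
    """Score every neuron's realized weights against the eigen prediction.

    Unconverged neurons are included with ``converged=False`` and NaN
    alignment so they are flagged, never silently scored; callers filter
    on the flag.  Realized excitation moments come from a plasticity-off
    probe over the training multiset.
    """
    reports = []
    excitations = model.decision_function(dataset.patterns)
    for j in range(model.connections_.shape[0]):
        lines = np.flatnonzero(model.connections_[j])
        conv = bool(model.converged_[j]) and lines.size > 0
        if lines.size == 0:
            continue
        pred = predicted_fixed_point(dataset, lines)
        w = model.weights_[j, lines]
        y = excitations[:, j]
        if conv:
            rel = np.abs(w - pred["predicted_weights"]) / pred["predicted_weights"]
            align_max, align_med = float(rel.max()), float(np.median(rel))
        else:
            align_max = align_med = float("nan")
        reports.append(TheoryReport(
            neuron=j, connected_lines=lines,
            lambda1=pred["lambda1"], e1=pred["e1"], k=pred["k"],
            predicted_weights=pred["predicted_weights"], realized_weights=w,
            mean_Y=pred["mean_Y"], var_Y=pred["var_Y"],
            realized_mean_Y=float(y.mean()),
            realized_var_Y=float(y.var()),
            alignment_error=align_max, alignment_median=align_med,
            e1_all_positive=pred["e1_all_positive"],
            n_negative_cov_entries=pred["n_negative_cov_entries"],
            converged=conv,
        ))
    return reports


def theory_frame(reports: list[TheoryReport]) -> pd.DataFrame:
    """Flatten theory reports to one row per neuron."""
    return pd.DataFrame([{
        "neuron": r.neuron,
        "n_lines": r.connected_lines.size,
        "lambda1": r.lambda1,
        "k": r.k,
        "mean_Y_pred": r.mean_Y,
        "mean_Y_realized": r.realized_mean_Y,
        "var_Y_pred": r.var_Y,
        "var_Y_realized": r.realized_var_Y,
        "alignment_max": r.alignment_error,
        "alignment_median": r.alignment_median,
        "e1_all_positive": r.e1_all_positive,
        "n_negative_cov_entries": r.n_negative_cov_entries,
        "converged": r.converged,
    } for r in reports])


def detect_pathological(dataset: Dataset, params) -> pd.DataFrame:
    """Flag categories that can never halt synaptogenesis.

    A category is pathological when (a) its potentially active lines are
    disjoint from every other category's (orthogonal inputs) and (b) its
    total presentation frequency — the maximum achievable firing rate of
    a neuron devoted to it — is strictly below the receptivity cutoff
    ``rho``.  Neurons captured by such a category stay receptive forever.
    """
    rows = []
    for c, spec in enumerate(dataset.categories):
        others = np.concatenate([
            o.prototype_lines
            for k, o in enumerate(dataset.categories) if k != c
        ]) if dataset.n_categories > 1 else np.array([], dtype=np.int64)
        orthogonal = not np.isin(spec.prototype_lines, others).any()
        freq = spec.presentation_count / dataset.n_patterns
        rows.append({
            "category": spec.label,
            "frequency": freq,
            "orthogonal": orthogonal,
            "pathological": bool(orthogonal and freq < params.rho),
        })
    return pd.DataFrame(rows)
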