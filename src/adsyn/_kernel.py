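"""Numba-compiled inner loop: one training block of per-step dynamics.

The kernel advances every unfrozen neuron through one block of pattern
presentations (excitation -> fire -> covariance weight update -> optional
per-step shed -> zbar update).  All randomness (pattern order, synapse
formation) is drawn outside, at block granularity, so the caller owns a
single reproducible RNG stream and the pure-NumPy reference engine in
:mod:`adsyn.training` can replay the identical schedule.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_block(patterns, order, connections, weights, zbar, frozen,
              mean_activity, epsilon, alpha, theta, shed_threshold,
              shed_each_step):
    """Run one block in place; returns per-neuron shed counts.

    patterns : (n_patterns, n_lines) uint8
    order : (n_steps,) int64 — presentation order, already concatenated
        over the block's cycles.
    connections / weights / zbar : network state, mutated in place.
    frozen : (n_neurons,) bool — neurons excluded from all dynamics.
    """
    n_neurons, n_lines = connections.shape
    # Per-neuron connection lists, rebuilt in ascending line order each
    # block; sheds swap-remove within the block.
    conn_idx = np.empty((n_neurons, n_lines), dtype=np.int64)
    n_conn = np.zeros(n_neurons, dtype=np.int64)
    shed_count = np.zeros(n_neurons, dtype=np.int64)
    for j in range(n_neurons):
        if frozen[j]:
            continue
        m = 0
        for i in range(n_lines):
            if connections[j, i]:
                conn_idx[j, m] = i
                m += 1
        n_conn[j] = m
    one_minus_alpha = 1.0 - alpha
    for t in range(order.shape[0]):
        x = patterns[order[t]]
        for j in range(n_neurons):
            if frozen[j]:
                continue
            y = 0.0
            for a in range(n_conn[j]):
                i = conn_idx[j, a]
                if x[i]:
                    y += weights[j, i]
            z = 1.0 if y >= theta else 0.0
            if y > 0.0:
                a = 0
                while a < n_conn[j]:
                    i = conn_idx[j, a]
                    w = weights[j, i] + epsilon * (
                        x[i] - mean_activity[i] - weights[j, i]) * y
                    if shed_each_step and w < shed_threshold:
                        connections[j, i] = 0
                        weights[j, i] = 0.0
                        n_conn[j] -= 1
                        conn_idx[j, a] = conn_idx[j, n_conn[j]]
                        shed_count[j] += 1
                    else:
                        weights[j, i] = w
                        a += 1
            zbar[j] = zbar[j] * alpha + z * one_minus_alpha
    return shed_count
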