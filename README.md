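# adsyn — adaptive synaptogenesis networks

`adsyn` simulates the unsupervised construction of a feedforward layer of
binary (McCulloch–Pitts) neurons by **adaptive synaptogenesis**: the joint
action of three synaptic mechanisms,

1. **random synapse formation** — while neuron *j*'s average firing rate
   `z̄_j` is below a minimum desired rate ρ, each absent connection forms
   independently with probability γ per training block, at initial weight
   0.2;
2. **covariance-rule weight modification** — on every timestep,
   `Δw_ij = ε (x_i − E[x_i] − w_ij) y_j`, where
   `y_j = Σ_i x_i c_ij w_ij` is the linear excitation and the neuron fires
   `z_j = 1` iff `y_j ≥ θ`;
3. **shedding** — any synapse whose weight falls below 0.01 is removed.

Together these allocate neurons to the statistical structure of a binary
input world: more frequent pattern categories, and more strongly
correlated (overlapping) ones, capture more neurons — a model of how
self-taught experts devote cortical resources to their domain. At
stability, a neuron's weight vector is proportional to the dominant
eigenvector of the covariance matrix of its input subspace:

```
Cov(X_S) w(∞) = w(∞) E[Y],   w(∞) = k e₁,   E[Y] = λ₁,   k = √(Var(Y)/E[Y])
```

which the package verifies per neuron as an executable oracle.

The intended users are computational-neuroscience researchers studying
structural plasticity, unsupervised category learning, and neural
resource allocation.

## What is in the package

| module | contents |
| --- | --- |
| `adsyn.datasets` | generators for the benchmark environments: dataset A (80 lines, 5 orthogonal categories, frequencies .1–.3) and datasets B1/B2/B3 (390 lines, 9 categories in 3 orthogonal super-categories with 5/10/15-line overlaps); CSV+JSON round-trip |
| `adsyn.network` | per-step dynamics (excitation, threshold firing, moving-average firing rate, covariance update) and the published parameterizations (`preset("A")`, `preset("B")`) |
| `adsyn.training` | `AdaptiveSynaptogenesisNetwork`, a scikit-learn transformer running the three timescales (step / 10-cycle block / 200-block stability criterion), with a numba kernel and an equivalent NumPy reference engine |
| `adsyn.theory` | the eigen-theory oracle (`subspace_covariance`, `dominant_eig`, `predicted_fixed_point`, `check_convergence_theorem`) and `detect_pathological` for input worlds where synaptogenesis provably never halts |
| `adsyn.analysis` | neuron-allocation index, nearest-centroid decoder, plug-in statistical dependence (Σᵢ H(Xᵢ) − H(X), bits), size curves, exclusivity probes |
| `adsyn.cli` / `adsyn.experiment` | `adsyn gen-data / train / theory-check / analyze / run-all` and the reproducible `RunConfig` → run-directory pipeline |

## Worked example

```python
import numpy as np
from adsyn import (make_dataset_B, train, allocation_index,
                   check_convergence_theorem)

ds = make_dataset_B("B1", seed=11)          # 225 patterns × 390 lines
model = train(ds, n_neurons=500, seed=12)   # preset B: θ=0.8, ρ=0.1, α=0.99
print(f"{model.converged_.sum()}/500 neurons stable")

reports = [r for r in check_convergence_theorem(model, ds) if r.converged]
med = np.median([r.alignment_median for r in reports])
print(f"median weight/k·e1 deviation: {med:.4f}")

test = make_dataset_B("B1", seed=13)        # fresh exemplars, same world
rep = allocation_index(model, test)
print("super-category shares:", np.round(rep.super_shares, 3))
```

prints (exactly, for these seeds):

```
488/500 neurons stable
median weight/k·e1 deviation: 0.0006
super-category shares: [0.18 0.34 0.48]
```

Reading: 97.6% of neurons reached the 200-block stability criterion;
their converged weights agree with the predicted `k·e₁` to a median 0.06%
per element (the theorem oracle); and although the nine categories are
equiprobable, the high-overlap super-category III captures ~48% of all
evoked firings versus ~18% for the low-overlap super-category I —
correlational structure, not just frequency, drives neural allocation.

The same pipeline from a shell:

```sh
adsyn run-all --dataset B1 --neurons 500 --seed 11 --out runs/b1
```

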