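"""End-to-end experiment runner: dataset -> training -> theory -> analysis.

A run is fully described by a :class:`RunConfig` (dataset variant,
preset with overrides, schedule, neuron count, and three seeds split by
concern so the test set is provably disjoint randomness from training).
``run_experiment`` materializes a run directory with the dataset files,
the final state snapshot, the block-level history, the theory report,
the analysis tables, and a JSON manifest from which the run is exactly
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (allocation_index, exclusivity_counts,
                       network_size_curves, statistical_dependence)
from .datasets import (Dataset, make_dataset_A, make_dataset_B,
                       write_dataset)
from .network import Params, preset
from .theory import check_convergence_theorem, theory_frame
from .training import Schedule, history_frame, train

__all__ = ["RunConfig", "run_experiment", "generate"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment."""

    dataset: str = "B1"            # A | B1 | B2 | B3
    preset: str = "B"              # A | B
    n_neurons: int = 500
    dataset_seed: int = 1
    training_seed: int = 2
    test_seed: int = 3
    param_overrides: dict = field(default_factory=dict)
    cycles_per_block: int = 10
    max_blocks: int = 2000
    stability_window: int = 200
    curve_sizes: tuple = (10, 30, 50)
    curve_repeats: int = 100
    probe_theta: float = 2.4

    def params(self) -> Params:
        return preset(self.preset).replace(**self.param_overrides)

    def schedule(self) -> Schedule:
        return Schedule(cycles_per_block=self.cycles_per_block,
                        max_blocks=self.max_blocks,
                        stability_window=self.stability_window)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate(variant: str, seed: int) -> Dataset:
    """Dataset by variant name."""
    if variant == "A":
        return make_dataset_A(seed)
    return make_dataset_B(variant, seed)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig, out_dir,
                   with_curves: bool = True) -> Path:
    """Execute a full run and write its artifacts under ``out_dir``."""
    if config.dataset == "A" and config.preset != "A" or \
       config.dataset.startswith("B") and config.preset != "B":
        raise ValueError(f"dataset {config.dataset!r} requires preset "
                         f"{'A' if config.dataset == 'A' else 'B'!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    train_ds = generate(config.dataset, config.dataset_seed)
    test_ds = generate(config.dataset, config.test_seed)
    write_dataset(train_ds, out / "dataset_train")
    write_dataset(test_ds, out / "dataset_test")

    model = train(train_ds, config.params(), config.schedule(),
                  n_neurons=config.n_neurons, seed=config.training_seed)
    model.state_.save(out / "state.npz")
    history_frame(model).to_csv(out / "history.csv", index=False)

    theory_frame(check_convergence_theorem(model, train_ds)).to_csv(
        out / "theory.csv", index=False)

    alloc = allocation_index(model, test_ds)
    alloc_df = pd.DataFrame({
        "category": [c.label for c in test_ds.categories],
        "frequency": test_ds.frequencies,
        "share": alloc.shares,
        "neuron_share": alloc.neuron_shares,
        "firings": alloc.firings,
    })
    alloc_df.to_csv(out / "allocation.csv", index=False)

    results = {
        "allocation": alloc.shares.tolist(),
        "super_allocation": (None if alloc.super_shares is None
                             else alloc.super_shares.tolist()),
        "total_firings": alloc.total_firings,
        "n_converged": int(model.converged_.sum()),
        "n_blocks": model.n_blocks_,
        "input_dependence_bits": statistical_dependence(train_ds.patterns),
    }
    if with_curves:
        curves = network_size_curves(model, train_ds, test_ds,
                                     sizes=config.curve_sizes,
                                     n_repeats=config.curve_repeats,
                                     seed=config.test_seed)
        curves.to_csv(out / "curves.csv", index=False)
    if train_ds.subregions is not None:
        exc = exclusivity_counts(model, train_ds,
                                 probe_theta=config.probe_theta)
        pd.DataFrame({
            "category": [c.label for c in train_ds.categories],
            "exclusive": exc.category_exclusive,
            "nonexclusive": exc.category_nonexclusive,
        }).to_csv(out / "exclusivity.csv", index=False)
        results["cross_super_firers"] = exc.cross_super_firers

    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "adsyn_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "results": results,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=list)
    return out
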