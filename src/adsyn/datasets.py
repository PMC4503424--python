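"""Binary pattern environments driving adaptive synaptogenesis.

Two families of input environments are provided, both built from unseen
binary *prototypes* that define categories:

* **Dataset A** — 80 input lines, five orthogonal categories occupying
  disjoint 16-line blocks.  An exemplar is its prototype with two active
  lines switched off and two inactive lines switched on, so every pattern
  has exactly 16 active lines at Hamming distance 4 from its prototype.
  Category presentation counts are 10/15/20/25/30 out of 100 patterns.

* **Datasets B1/B2/B3** — 390 input lines, nine categories arranged in
  three mutually orthogonal super-categories of three overlapping
  categories each.  Every category has 60 potentially active lines; an
  exemplar activates exactly 20 of them, drawn without replacement.
  Within a super-category the 60-line sets overlap through seven
  sub-regions (three exclusive, three pairwise, one triple); the overlap
  parameter grows from 5 (super-category I) to 10 (II) to 15 (III) lines
  per shared sub-region.  The three variants differ only in category
  presentation frequencies: B1 is equiprobable (25 patterns each of 225),
  B2 and B3 use printed fraction lists realized as integer counts by
  largest-remainder rounding.

A dataset is a fixed multiset of patterns; presentation frequency is
encoded by row multiplicity, so uniform row statistics *are* the
frequency-weighted statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "CategorySpec",
    "SubRegion",
    "SubRegionMap",
    "Dataset",
    "DatasetParseError",
    "make_dataset_A",
    "make_dataset_B",
    "make_pathological_dataset",
    "mean_activity",
    "largest_remainder_counts",
    "write_dataset",
    "read_dataset",
]

# ---------------------------------------------------------------- constants

A_N_LINES = 80
A_BLOCK = 16  # lines per prototype, also active lines per pattern
A_COUNTS = (10, 15, 20, 25, 30)
A_NOISE_FLIPS = 2  # active lines switched off == inactive switched on

B_N_LINES = 390
B_ACTIVE = 20
B_POTENTIAL = 60  # potentially active lines per category
B_N_PATTERNS = 225
#: per super-category: (exclusive-region size, shared-region size).
#: Seven regions per super-category: 3 exclusive, 3 pairwise, 1 triple.
B_REGION_SIZES = {1: (45, 5), 2: (30, 10), 3: (15, 15)}
B_FREQUENCIES = {
    "B1": (1 / 9,) * 9,
    "B2": (0.13, 0.13, 0.13, 0.11, 0.11, 0.11, 0.098, 0.093, 0.093),
    "B3": (0.18, 0.17, 0.15, 0.12, 0.11, 0.087, 0.063, 0.058, 0.053),
}


class DatasetParseError(ValueError):
    """Raised when a serialized dataset cannot be parsed."""


# ---------------------------------------------------------------- containers


@dataclass(frozen=True)
class CategorySpec:
    """One category: its label, prototype support and presentation share."""

    label: str
    prototype_lines: np.ndarray  # sorted 0-based line indices
    presentation_count: int
    relative_frequency: float

    def __post_init__(self):
        object.__setattr__(
            self, "prototype_lines",
            np.asarray(np.sort(self.prototype_lines), dtype=np.int64),
        )


@dataclass(frozen=True)
class SubRegion:
    super_category: int  # 1-based: I, II, III
    region: int          # 1..7 within the super-category
    lines: np.ndarray    # 0-based line indices

    def __post_init__(self):
        object.__setattr__(self, "lines",
                           np.asarray(np.sort(self.lines), dtype=np.int64))


@dataclass(frozen=True)
class SubRegionMap:
    """The 21 overlap cells of the B datasets (7 per super-category).

    Region layout within a super-category with categories (a, b, c):
    regions 1/2/3 are exclusive to a/b/c, region 4 is shared by a and c,
    region 5 by a and b, region 6 by b and c, region 7 by all three.
    """

    regions: tuple[SubRegion, ...]

    def lines_of(self, super_category: int, region: int) -> np.ndarray:
        for r in self.regions:
            if r.super_category == super_category and r.region == region:
                return r.lines
        raise KeyError((super_category, region))


@dataclass
class Dataset:
    """A fixed multiset of binary patterns with category structure."""

    name: str
    patterns: np.ndarray          # (n_patterns, n_lines) uint8
    labels: np.ndarray            # (n_patterns,) 0-based category index
    categories: list[CategorySpec]
    active_per_pattern: int
    subregions: SubRegionMap | None = None
    seed: int | None = None

    def __post_init__(self):
        self.patterns = np.ascontiguousarray(self.patterns, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_lines(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def mean_activity(self) -> np.ndarray:
        return mean_activity(self)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-category presentation frequencies (counts / total)."""
        return np.array([c.presentation_count for c in self.categories],
                        dtype=float) / self.n_patterns

    def super_category_of(self, category: int) -> int:
        """1-based super-category of a 0-based category index (B layout)."""
        return category // 3 + 1


def mean_activity(dataset: Dataset) -> np.ndarray:
    """Presentation-frequency-weighted mean activity E[x_i] per input line.

    The pattern matrix is a multiset (frequency encoded by multiplicity),
    so this is the plain column mean.
    """
    if dataset.n_patterns == 0:
        raise ValueError("dataset is empty")
    return dataset.patterns.mean(axis=0)


# ---------------------------------------------------------------- generators


def largest_remainder_counts(fractions, total: int) -> np.ndarray:
    """Integerize fractions to counts summing to ``total``.

    Fractions are normalized first (printed lists need not sum exactly
    to one).  Floor quotas are topped up in order of descending remainder;
    remainder ties break by position.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    f = f / f.sum()
    quota = f * total
    counts = np.floor(quota).astype(np.int64)
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[: total - counts.sum()]] += 1
    return counts


def make_dataset_A(seed: int, counts=A_COUNTS) -> Dataset:
    """Generate dataset A: 5 orthogonal 16-line prototypes, 100 exemplars.

    Each exemplar inactivates two randomly chosen active prototype lines
    and activates two randomly chosen inactive lines, keeping exactly 16
    lines active and a Hamming distance of 4 from the prototype.
    """
    rng = np.random.default_rng(seed)
    total = int(np.sum(counts))
    patterns, labels, cats = [], [], []
    for c, count in enumerate(counts):
        proto = np.arange(c * A_BLOCK, (c + 1) * A_BLOCK)
        others = np.setdiff1d(np.arange(A_N_LINES), proto)
        cats.append(CategorySpec(
            label=f"A{c + 1}", prototype_lines=proto,
            presentation_count=int(count),
            relative_frequency=count / total,
        ))
        for _ in range(count):
            row = np.zeros(A_N_LINES, dtype=np.uint8)
            keep = np.delete(proto, rng.choice(A_BLOCK, A_NOISE_FLIPS,
                                               replace=False))
            noise = rng.choice(others, A_NOISE_FLIPS, replace=False)
            row[keep] = 1
            row[noise] = 1
            patterns.append(row)
            labels.append(c)
    return Dataset(name="A", patterns=np.array(patterns), labels=labels,
                   categories=cats, active_per_pattern=A_BLOCK, seed=seed)


def build_subregion_map() -> SubRegionMap:
    """The fixed 21-region overlap layout of the B datasets.

    Lines are assigned contiguously: super-category I occupies lines
    0-154, II 155-284, III 285-389; within each super-category the seven
    regions are laid out exclusive(x3), pairwise(x3), triple.
    """
    regions = []
    offset = 0
    for sc in (1, 2, 3):
        excl, shared = B_REGION_SIZES[sc]
        sizes = [excl] * 3 + [shared] * 4
        for r, size in enumerate(sizes, start=1):
            regions.append(SubRegion(sc, r, np.arange(offset, offset + size)))
            offset += size
    assert offset == B_N_LINES
    return SubRegionMap(tuple(regions))


def _category_lines(srm: SubRegionMap, sc: int, pos: int) -> np.ndarray:
    """Potentially active lines of category ``pos`` (0,1,2) in super ``sc``."""
    members = {0: (1, 4, 5, 7), 1: (2, 5, 6, 7), 2: (3, 4, 6, 7)}[pos]
    return np.sort(np.concatenate([srm.lines_of(sc, r) for r in members]))


def make_dataset_B(variant: str, seed: int,
                   n_patterns: int = B_N_PATTERNS) -> Dataset:
    """Generate dataset B1, B2 or B3 (same geometry, different frequencies).

    Every pattern activates exactly 20 of its category's 60 potentially
    active lines, drawn uniformly without replacement; no line outside the
    category's support is ever activated, so patterns from different
    super-categories are orthogonal.
    """
    if variant not in B_FREQUENCIES:
        raise ValueError(f"unknown B variant {variant!r}; "
                         f"expected one of {sorted(B_FREQUENCIES)}")
    rng = np.random.default_rng(seed)
    srm = build_subregion_map()
    counts = largest_remainder_counts(B_FREQUENCIES[variant], n_patterns)
    patterns, labels, cats = [], [], []
    for c in range(9):
        sc, pos = c // 3 + 1, c % 3
        lines = _category_lines(srm, sc, pos)
        cats.append(CategorySpec(
            label="ABCDEFGHJ"[c], prototype_lines=lines,
            presentation_count=int(counts[c]),
            relative_frequency=counts[c] / n_patterns,
        ))
        for _ in range(counts[c]):
            row = np.zeros(B_N_LINES, dtype=np.uint8)
            row[rng.choice(lines, B_ACTIVE, replace=False)] = 1
            patterns.append(row)
            labels.append(c)
    return Dataset(name=variant, patterns=np.array(patterns), labels=labels,
                   categories=cats, active_per_pattern=B_ACTIVE,
                   subregions=srm, seed=seed)


def make_pathological_dataset(seed: int = 0, *,
                              isolated_frequency: float = 0.09,
                              n_patterns: int = 100,
                              n_category_lines: int = 10,
                              n_background_lines: int = 10) -> Dataset:
    """A constructed environment that defeats synaptogenesis halting.

    One category occupies its own orthogonal line set (all its lines
    co-active) and appears with a total frequency below any minimum
    desired firing rate of interest (default 9%): a neuron devoted to it
    can never raise its average firing rate above that cutoff, so it
    stays receptive and keeps acquiring synapses forever.  The remaining
    presentations carry no activity on this neuron's world — they are
    silent rows, standing in for an orthogonal remainder of the input
    space — and the extra never-active background lines are the targets
    that sustain the gain-and-shed treadmill.

    With ``isolated_frequency`` raised above the receptivity cutoff the
    same geometry converges, which is the control case.
    """
    rng = np.random.default_rng(seed)
    n_lines = n_category_lines + n_background_lines
    n_p = int(round(isolated_frequency * n_patterns))
    p_lines = np.arange(n_category_lines)
    patterns = np.zeros((n_patterns, n_lines), dtype=np.uint8)
    patterns[:n_p, p_lines] = 1
    labels = np.array([0] * n_p + [1] * (n_patterns - n_p))
    perm = rng.permutation(n_patterns)
    cats = [
        CategorySpec("P", p_lines, n_p, n_p / n_patterns),
        CategorySpec("SILENT", np.array([], dtype=np.int64),
                     n_patterns - n_p, (n_patterns - n_p) / n_patterns),
    ]
    return Dataset(name="pathological", patterns=patterns[perm],
                   labels=labels[perm], categories=cats,
                   active_per_pattern=n_category_lines, seed=seed)


# ---------------------------------------------------------------- round trip


def write_dataset(dataset: Dataset, directory) -> Path:
    """Serialize a dataset to ``directory`` as patterns.csv + metadata.json.

    patterns.csv holds one pattern per row (0/1 values) with the 0-based
    category label as the final column.  Line indices in the JSON sidecar
    are 1-based, matching the "input lines 1-16" convention of reports.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = np.hstack([dataset.patterns.astype(np.int64),
                      dataset.labels[:, None]])
    with open(directory / "patterns.csv", "w") as fh:
        for row in rows:
            fh.write(",".join(map(str, row)) + "\n")
    meta = {
        "name": dataset.name,
        "active_per_pattern": dataset.active_per_pattern,
        "n_lines": dataset.n_lines,
        "seed": dataset.seed,
        "categories": [
            {
                "label": c.label,
                "prototype_lines": (c.prototype_lines + 1).tolist(),
                "presentation_count": c.presentation_count,
                "relative_frequency": c.relative_frequency,
            }
            for c in dataset.categories
        ],
        "subregions": None if dataset.subregions is None else [
            {
                "super_category": r.super_category,
                "region": r.region,
                "lines": (r.lines + 1).tolist(),
            }
            for r in dataset.subregions.regions
        ],
    }
    with open(directory / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    return directory


def read_dataset(directory) -> Dataset:
    """Inverse of :func:`write_dataset`; raises on malformed rows."""
    directory = Path(directory)
    try:
        with open(directory / "metadata.json") as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise DatasetParseError(f"cannot read metadata.json: {exc}") from exc
    n_lines = meta["n_lines"]
    patterns, labels = [], []
    with open(directory / "patterns.csv") as fh:
        for k, line in enumerate(fh):
            fields = line.strip().split(",")
            if len(fields) != n_lines + 1:
                raise DatasetParseError(
                    f"row {k}: expected {n_lines + 1} fields, "
                    f"got {len(fields)}")
            try:
                values = [int(v) for v in fields]
            except ValueError as exc:
                raise DatasetParseError(f"row {k}: non-integer field") from exc
            if any(v not in (0, 1) for v in values[:-1]):
                raise DatasetParseError(f"row {k}: non-binary pattern value")
            patterns.append(values[:-1])
            labels.append(values[-1])
    if not patterns:
        raise DatasetParseError("patterns.csv is empty")
    cats = [
        CategorySpec(
            label=c["label"],
            prototype_lines=np.asarray(c["prototype_lines"]) - 1,
            presentation_count=c["presentation_count"],
            relative_frequency=c["relative_frequency"],
        )
        for c in meta["categories"]
    ]
    srm = None
    if meta["subregions"] is not None:
        srm = SubRegionMap(tuple(
            SubRegion(r["super_category"], r["region"],
                      np.asarray(r["lines"]) - 1)
            for r in meta["subregions"]
        ))
    return Dataset(name=meta["name"],
                   patterns=np.array(patterns, dtype=np.uint8),
                   labels=labels, categories=cats,
                   active_per_pattern=meta["active_per_pattern"],
                   subregions=srm, seed=meta.get("seed"))
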