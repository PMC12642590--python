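"""Train/validation/test splits for DMS datasets.

Three schemes, mirroring the three evaluation regimes:

* ``random`` — a plain 70/15/15 shuffle of variants.
* ``mutational`` — the unique (position, substitution) pairs are
  partitioned 70/15/15; a variant joins a partition only if *all* of its
  mutations fall in that partition, so no mutation type seen at test time
  was ever seen in training.
* ``positional`` — the same, but partitioning mutated positions, so test
  mutations sit at residue sites entirely unseen during training.

Variants whose mutations straddle partitions cannot be placed without
leaking information and are dropped (recorded with a reason).  All splits
are pure functions of (dataset, fractions, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dms_data import DMSDataset

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass
class DataSplit:
    """Disjoint train/validation/test index sets into one dataset."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    scheme: str
    seed: int
    fractions: tuple[float, float, float]
    dropped: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        if parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2]:
            raise ValueError("split partitions overlap")

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "fractions": list(self.fractions),
            "train": [int(i) for i in self.train],
            "validation": [int(i) for i in self.validation],
            "test": [int(i) for i in self.test],
            "dropped": [[int(i), reason] for i, reason in self.dropped],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DataSplit":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["train"], dtype=int),
            np.array(d["validation"], dtype=int),
            np.array(d["test"], dtype=int),
            d["scheme"],
            d["seed"],
            tuple(d["fractions"]),
            [(i, r) for i, r in d["dropped"]],
        )


def _check_fractions(fractions) -> tuple[float, float, float]:
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(x <= 0 for x in f) or abs(sum(f) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be three positives summing to 1, got {f}")
    return f


def _partition(items: list, fractions, rng: np.random.Generator):
    """Shuffle and cut a list 70/15/15 (floor sizes, remainder to train)."""
    n = len(items)
    order = rng.permutation(n)
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    shuffled = [items[i] for i in order]
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


def random_split(
    dataset: DMSDataset,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> DataSplit:
    """Uniformly random variant split; every variant is assigned."""
    fractions = _check_fractions(fractions)
    n = len(dataset)
    if n < 3:
        raise ValueError(f"dataset of {n} variants is too small to split three ways")
    rng = np.random.default_rng(seed)
    train, val, test = _partition(list(range(n)), fractions, rng)
    return DataSplit(
        np.array(sorted(train)), np.array(sorted(val)), np.array(sorted(test)),
        "random", seed, fractions,
    )


def _keyed_split(
    dataset: DMSDataset,
    fractions,
    seed: int,
    scheme: str,
    variant_keys,
) -> DataSplit:
    """Partition the key universe, then place variants whose keys agree.

    ``variant_keys(v)`` returns the set of keys (mutations or positions) a
    variant touches.  Wild-type records have no keys and default to train.
    """
    fractions = _check_fractions(fractions)
    universe = sorted(set().union(*(variant_keys(v) for v in dataset.variants)) or set())
    if len(universe) < 3:
        raise ValueError(f"need at least 3 unique keys for a {scheme} split")
    rng = np.random.default_rng(seed)
    train_k, val_k, test_k = (set(p) for p in _partition(universe, fractions, rng))
    assignment = {}
    for k in train_k:
        assignment[k] = 0
    for k in val_k:
        assignment[k] = 1
    for k in test_k:
        assignment[k] = 2
    buckets: tuple[list[int], ...] = ([], [], [])
    dropped: list[tuple[int, str]] = []
    for i, v in enumerate(dataset.variants):
        keys = variant_keys(v)
        if not keys:
            buckets[0].append(i)  # wild type carries no held-out information
            continue
        parts = {assignment[k] for k in keys}
        if len(parts) == 1:
            buckets[parts.pop()].append(i)
        else:
            dropped.append((i, "mutations span partitions"))
    return DataSplit(
        np.array(buckets[0], dtype=int),
        np.array(buckets[1], dtype=int),
        np.array(buckets[2], dtype=int),
        scheme, seed, fractions, dropped,
    )


def mutational_split(
    dataset: DMSDataset, fractions=DEFAULT_FRACTIONS, seed: int = 0
) -> DataSplit:
    """Hold out whole mutation types: zero shared (position, aa) pairs."""
    return _keyed_split(dataset, fractions, seed, "mutational", lambda v: v.mutation_keys())


def positional_split(
    dataset: DMSDataset, fractions=DEFAULT_FRACTIONS, seed: int = 0
) -> DataSplit:
    """Hold out whole residue positions: zero shared mutated sites."""
    return _keyed_split(dataset, fractions, seed, "positional", lambda v: v.positions())


SPLITTERS = {
    "random": random_split,
    "mutational": mutational_split,
    "positional": positional_split,
}


def make_split(dataset, scheme: str, fractions=DEFAULT_FRACTIONS, seed: int = 0) -> DataSplit:
    try:
        return SPLITTERS[scheme](dataset, fractions, seed)
    except KeyError:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SPLITTERS)}") from None
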