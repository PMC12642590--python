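"""Library-size x read-depth resampling experiments.

DMS data quality is governed by two budgets: how many distinct variants
the library contains, and how many sequencing reads are spent counting
them.  This module reproduces the classic benchmark design that maps model
performance over a grid of (library size, read budget) cells: hold out a
fixed test set, then repeatedly (i) draw a variant library from the
left-over pool, (ii) resample its input and selected read counts from
multinomial distributions at the reduced budget, (iii) recompute enrichment
scores, (iv) train a model on the noisy scores, and (v) evaluate on the
fixed test set.  Cells whose library size exceeds the available pool are
reported empty.

The read budget of each cell is divided between the input and selected
pools in the same proportion as the base pool's total reads, so the
relative sequencing effort of the two conditions is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dms_data import DMSDataset, Variant
from .features import FeatureResources, encode_dataset
from .models import ModelConfig, evaluate_model, train_model
from .structure import ContactGraph

DEFAULT_TEST_SIZE = 10_000
DEFAULT_REPLICATES = 5


@dataclass
class ResampleDesign:
    """The grid of the resampling experiment."""

    library_sizes: Sequence[int]
    read_budgets: Sequence[int]
    test_size: int = DEFAULT_TEST_SIZE
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.read_budgets):
            raise ValueError("read budgets must be positive")
        if any(s <= 0 for s in self.library_sizes):
            raise ValueError("library sizes must be positive")


def _require_counts(dataset: DMSDataset) -> None:
    if any(v.count_input is None or v.count_selected is None for v in dataset.variants):
        raise ValueError("resampling requires read counts on every variant")


def make_base(dataset: DMSDataset, design: ResampleDesign) -> tuple[DMSDataset, DMSDataset]:
    """Partition the dataset into a fixed test set and a resampling pool.

    The wild-type record (needed to center enrichment scores) always stays
    in the pool.  The test set keeps the dataset's original scores.
    """
    _require_counts(dataset)
    non_wt = [i for i, v in enumerate(dataset.variants) if not v.is_wildtype]
    n_test = min(design.test_size, len(non_wt))
    rng = np.random.default_rng(design.seed)
    test_idx = set(rng.choice(non_wt, size=n_test, replace=False).tolist())
    pool_idx = [i for i in range(len(dataset)) if i not in test_idx]
    if not any(not dataset.variants[i].is_wildtype for i in pool_idx):
        raise ValueError("test set consumed every variant; nothing left to resample")
    test = DMSDataset(
        dataset.reference_sequence,
        [dataset.variants[i] for i in sorted(test_idx)],
        name=f"{dataset.name}_test",
    )
    pool = DMSDataset(
        dataset.reference_sequence,
        [dataset.variants[i] for i in pool_idx],
        name=f"{dataset.name}_pool",
    )
    return test, pool


def resample_library(
    pool: DMSDataset,
    library_size: int,
    read_budget: int,
    seed: int = 0,
    subset_seed: int | None = None,
) -> DMSDataset:
    """Draw a variant library and resample its read counts at a budget.

    A uniform random subset of ``library_size`` non-wild-type variants is
    taken (the wild type is always carried along for score centering).
    The subset's original counts define two multinomial distributions; the
    budget is split between input and selected reads proportionally to the
    pool's total input:selected read fraction, and new counts are drawn.
    The drawn reads sum exactly to the budget.

    ``subset_seed`` decouples the variant draw from the read draw: cells
    sharing a ``subset_seed`` get *nested* libraries (a prefix of one
    shuffled pool), which pairs comparisons across library sizes and read
    budgets (common random numbers).  By default the one ``seed`` drives
    both draws.
    """
    _require_counts(pool)
    non_wt = [i for i, v in enumerate(pool.variants) if not v.is_wildtype]
    if library_size > len(non_wt):
        raise ValueError(
            f"library size {library_size} exceeds the {len(non_wt)} available variants"
        )
    rng = np.random.default_rng(seed)
    subset_rng = rng if subset_seed is None else np.random.default_rng(subset_seed)
    chosen = sorted(subset_rng.permutation(non_wt)[:library_size].tolist())
    wt_idx = [i for i, v in enumerate(pool.variants) if v.is_wildtype]
    members = wt_idx + chosen
    c_in = np.array([pool.variants[i].count_input for i in members], dtype=float)
    c_sel = np.array([pool.variants[i].count_selected for i in members], dtype=float)
    if c_in.sum() == 0 or c_sel.sum() == 0:
        raise ValueError("library has zero total reads in one condition")
    total_in = sum(v.count_input for v in pool.variants)
    total_sel = sum(v.count_selected for v in pool.variants)
    frac_in = total_in / (total_in + total_sel)
    n_in = int(round(read_budget * frac_in))
    n_sel = read_budget - n_in
    new_in = rng.multinomial(n_in, c_in / c_in.sum())
    new_sel = rng.multinomial(n_sel, c_sel / c_sel.sum())
    resampled = [
        Variant(pool.variants[i].mutations, count_input=int(a), count_selected=int(b))
        for i, a, b in zip(members, new_in, new_sel)
    ]
    return DMSDataset(pool.reference_sequence, resampled, name=f"{pool.name}_lib")


def score_and_grid(
    dataset: DMSDataset,
    design: ResampleDesign,
    resources: FeatureResources,
    config: ModelConfig,
    *,
    with_biophysics: bool = True,
    graph: ContactGraph | None = None,
    val_fraction: float = 0.15,
) -> pd.DataFrame:
    """Run the full grid; returns one row per (cell, replicate).

    Cells with too few pool variants are emitted with NaN metrics and
    ``empty = True``.  The test set, its encoding, and its scores are fixed
    across the whole grid.
    """
    test, pool = make_base(dataset, design)
    X_test = encode_dataset(test, resources, with_biophysics)
    y_test = np.array([v.score for v in test.variants], dtype=float)
    test_counts = [v.n_mutations for v in test.variants]
    # encode each pool variant once; libraries re-use rows by index
    X_pool = encode_dataset(pool, resources, with_biophysics)
    key_to_row = {v.mutation_keys(): i for i, v in enumerate(pool.variants)}
    n_avail = sum(1 for v in pool.variants if not v.is_wildtype)

    rows = []
    for li, lib_size in enumerate(design.library_sizes):
        for bi, budget in enumerate(design.read_budgets):
            for rep in range(design.replicates):
                cell_seed = np.random.SeedSequence(
                    [design.seed, li, bi, rep]
                ).generate_state(1)[0] % (2**31)
                # one permutation per replicate -> nested libraries across
                # cells (paired comparisons via common random numbers)
                rep_seed = np.random.SeedSequence(
                    [design.seed, rep]
                ).generate_state(1)[0] % (2**31)
                if lib_size > n_avail:
                    rows.append(
                        {
                            "library_size": lib_size, "read_budget": budget,
                            "replicate": rep, "pearson": np.nan, "spearman": np.nan,
                            "mae": np.nan, "empty": True,
                        }
                    )
                    continue
                library = resample_library(
                    pool, lib_size, budget, seed=cell_seed, subset_seed=rep_seed
                )
                library = library.with_enrichment_scores()
                lib_rows = np.array([key_to_row[v.mutation_keys()] for v in library.variants])
                X_lib = X_pool[lib_rows]
                y_lib = np.array([v.score for v in library.variants], dtype=float)
                rng = np.random.default_rng(rep_seed + 1)
                order = rng.permutation(len(y_lib))
                n_val = max(1, int(val_fraction * len(y_lib)))
                val_idx, tr_idx = order[:n_val], order[n_val:]
                model = train_model(
                    replace(config, seed=int(rep_seed)),
                    X_lib[tr_idx], y_lib[tr_idx], X_lib[val_idx], y_lib[val_idx],
                    graph=graph if config.family == "GCN" else None,
                )
                report = evaluate_model(model, X_test, y_test, test_counts)
                rows.append(
                    {
                        "library_size": lib_size, "read_budget": budget,
                        "replicate": rep, "pearson": report.pearson,
                        "spearman": report.spearman, "mae": report.mae,
                        "empty": False,
                    }
                )
    return pd.DataFrame(rows)


def grid_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Median test Pearson per grid cell (the heat-map table)."""
    return (
        results.groupby(["library_size", "read_budget"], as_index=False)["pearson"]
        .median()
        .rename(columns={"pearson": "median_pearson"})
    )
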