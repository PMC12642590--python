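"""The four variant-effect regressor families and the experiment harness.

All models consume the per-variant ``L x D`` feature matrices from
:mod:`biovep.features` and regress the scalar functional score:

* **LR** — an affine map on the flattened matrix (ordinary linear
  regression trained by gradient descent).
* **NN** — dense layers with leaky ReLU on the flattened matrix.
* **CNN** — 1-D convolutions across residue positions (features as
  channels, stride 1, valid padding), then a dense head.
* **GCN** — graph convolutions over the residue contact graph, then a
  dense head.

NN, CNN, and GCN all end with a dense layer, leaky ReLU, dropout 0.2, and
a scalar linear output.  Training minimizes mean-squared error with early
stopping on a validation split; evaluation reports Pearson r, Spearman
rho, and MAE, with an MAE breakdown by mutations-per-variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error

from . import network as nn
from .dms_data import DMSDataset
from .features import FeatureResources, encode_dataset
from .splits import DEFAULT_FRACTIONS, DataSplit, make_split
from .structure import ContactGraph, normalize_adjacency

FAMILIES = ("LR", "NN", "CNN", "GCN")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one regressor; everything is configuration.

    Defaults are deliberately modest (small nets, Adam at 1e-3, batch 64,
    early-stopping patience 10); the grid-search hook in
    :func:`run_experiment` is the intended way to tune them.
    """

    family: str = "CNN"
    hidden: tuple[int, ...] = (64,)
    filters: int = 24
    kernel: int = 5
    n_conv_layers: int = 1
    graph_channels: tuple[int, ...] = (16, 16)
    dense_units: int = 64
    head: str = "pool"  # "pool" (position-invariant) or "flatten"
    dropout: float = 0.2
    learning_rate: float = 5e-4
    batch_size: int = 64
    epochs: int = 300
    patience: int = 30
    lr_patience: int | None = None  # reduce-on-plateau, off by default
    min_lr: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.head not in ("pool", "flatten"):
            raise ValueError(f"head must be 'pool' or 'flatten', got {self.head!r}")
        for name in ("filters", "kernel", "dense_units", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def build_model(
    config: ModelConfig,
    input_shape: tuple[int, int],
    graph: ContactGraph | None = None,
) -> nn.Network:
    """Assemble an untrained network for ``(N_res, D)`` inputs."""
    L, D = input_shape
    rng = np.random.default_rng(config.seed)
    layers: list[nn.Layer] = []
    if config.family == "LR":
        layers = [nn.Flatten(), nn.Dense(L * D, 1, rng)]
    elif config.family == "NN":
        layers = [nn.Flatten()]
        width = L * D
        for h in config.hidden:
            layers += [nn.Dense(width, h, rng), nn.LeakyReLU()]
            width = h
        layers += [nn.Dropout(config.dropout), nn.Dense(width, 1, rng)]
    elif config.family == "CNN":
        layers = []
        channels, length = D, L
        for _ in range(config.n_conv_layers):
            layers += [nn.Conv1D(channels, config.filters, config.kernel, rng), nn.LeakyReLU()]
            channels = config.filters
            length = length - config.kernel + 1
            if length < 1:
                raise ValueError("convolution stack consumes the whole sequence")
        layers += _dense_head(config, length, channels, rng)
    elif config.family == "GCN":
        if graph is None:
            raise ValueError("GCN requires a contact graph")
        if graph.n_nodes != L:
            raise ValueError(
                f"graph has {graph.n_nodes} nodes but inputs have {L} residues"
            )
        a_hat = normalize_adjacency(graph)
        layers = []
        channels = D
        for width in config.graph_channels:
            layers += [nn.GraphConv(a_hat, channels, width, rng), nn.LeakyReLU()]
            channels = width
        layers += _dense_head(config, L, channels, rng)
    return nn.Network(layers)


def _dense_head(config: ModelConfig, length: int, channels: int, rng) -> list[nn.Layer]:
    """Dense readout after the convolutional stack.

    The default ``pool`` head averages over positions before the dense
    layer, keeping the whole model position-invariant — the property that
    lets weights learned at training positions apply to never-mutated ones.
    The ``flatten`` head concatenates positions instead, giving the readout
    position-specific weights (more expressive under random splits, but
    unable to extrapolate positionally).
    """
    first = (
        [nn.MeanPool(), nn.Dense(channels, config.dense_units, rng)]
        if config.head == "pool"
        else [nn.Flatten(), nn.Dense(length * channels, config.dense_units, rng)]
    )
    return first + [
        nn.LeakyReLU(),
        nn.Dropout(config.dropout),
        nn.Dense(config.dense_units, 1, rng),
    ]


@dataclass
class TrainedModel:
    """A fitted network plus the provenance needed to use it safely."""

    network: nn.Network
    config: ModelConfig
    input_shape: tuple[int, int]
    fingerprint: dict = field(default_factory=dict)
    history: nn.TrainingHistory | None = None
    y_mean: float = 0.0
    y_scale: float = 1.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1:] != self.input_shape:
            raise ValueError(
                f"feature shape {X.shape[1:]} does not match the "
                f"{self.input_shape} this model was trained on"
            )
        return self.network.predict(X) * self.y_scale + self.y_mean


def train_model(
    config: ModelConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    graph: ContactGraph | None = None,
    fingerprint: dict | None = None,
) -> TrainedModel:
    """Build and fit one model; fully deterministic under ``config.seed``.

    Targets are standardized to zero mean and unit variance on the training
    split (predictions are mapped back), which conditions the scalar output
    layer independently of the score scale.
    """
    input_shape = X_train.shape[1:]
    y_mean = float(np.mean(y_train))
    y_scale = float(np.std(y_train)) or 1.0
    net = build_model(config, input_shape, graph)
    history = nn.fit_network(
        net,
        X_train, (y_train - y_mean) / y_scale,
        X_val, (y_val - y_mean) / y_scale,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        epochs=config.epochs,
        patience=config.patience,
        lr_patience=config.lr_patience,
        min_lr=config.min_lr,
        seed=config.seed,
    )
    return TrainedModel(net, config, input_shape, fingerprint or {}, history, y_mean, y_scale)


@dataclass
class EvalReport:
    pearson: float | None
    spearman: float | None
    mae: float
    mae_by_mutation_count: dict[int, float] = field(default_factory=dict)
    scheme: str | None = None
    seed: int | None = None
    n_test: int = 0


def _safe_corr(y_true: np.ndarray, y_pred: np.ndarray):
    """Correlations, or None where they are undefined (constant vectors)."""
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        return None, None
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    rho = float(stats.spearmanr(y_true, y_pred).statistic)
    return r, rho


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    mutation_counts: Sequence[int] | None = None,
    scheme: str | None = None,
    seed: int | None = None,
) -> EvalReport:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    r, rho = _safe_corr(y_true, y_pred)
    mae = float(mean_absolute_error(y_true, y_pred))
    by_count: dict[int, float] = {}
    if mutation_counts is not None:
        counts = np.asarray(mutation_counts)
        for c in sorted(set(counts.tolist())):
            sel = counts == c
            by_count[int(c)] = float(mean_absolute_error(y_true[sel], y_pred[sel]))
    return EvalReport(r, rho, mae, by_count, scheme, seed, len(y_true))


def evaluate_model(
    model: TrainedModel,
    X_test: np.ndarray,
    y_test: np.ndarray,
    mutation_counts: Sequence[int] | None = None,
    **kwargs,
) -> EvalReport:
    return evaluate_predictions(y_test, model.predict(X_test), mutation_counts, **kwargs)


def _split_arrays(X, y, counts, split: DataSplit):
    parts = {}
    for name, idx in (("train", split.train), ("val", split.validation), ("test", split.test)):
        parts[name] = (X[idx], y[idx], counts[idx])
    return parts


def run_experiment(
    dataset: DMSDataset,
    resources: FeatureResources,
    scheme: str,
    *,
    with_biophysics_flags: Sequence[bool] = (True, False),
    families: Sequence[str] = ("CNN",),
    configs: dict[str, ModelConfig] | None = None,
    config_grid: dict[str, Sequence[ModelConfig]] | None = None,
    graph: ContactGraph | None = None,
    n_repeats: int = 5,
    base_seed: int = 0,
    fractions=DEFAULT_FRACTIONS,
) -> pd.DataFrame:
    """Split -> encode -> train -> evaluate, repeated over seeds.

    Each repeat redraws the split with its own seed (and seeds training the
    same way), matching the repeated-splits evaluation protocol.  When a
    ``config_grid`` is given for a family, every candidate is trained and
    the one with the best validation Pearson is kept (validation-set grid
    search); otherwise ``configs`` (or defaults) are used directly.

    Returns a tidy table with one row per
    (family, biophysics flag, repeat): scheme, family, biophysics, seed,
    pearson, spearman, mae, n_train, n_test, n_dropped.
    """
    y = np.array([v.score for v in dataset.variants], dtype=float)
    if np.isnan(y).any():
        raise ValueError("every variant needs a score before training")
    counts = np.array([v.n_mutations for v in dataset.variants])
    encodings = {
        flag: encode_dataset(dataset, resources, with_biophysics=flag)
        for flag in set(with_biophysics_flags)
    }
    rows = []
    for repeat in range(n_repeats):
        seed = base_seed + repeat
        split = make_split(dataset, scheme, fractions, seed)
        for flag in with_biophysics_flags:
            parts = _split_arrays(encodings[flag], y, counts, split)
            (Xtr, ytr, _), (Xva, yva, _), (Xte, yte, cte) = (
                parts["train"], parts["val"], parts["test"],
            )
            for family in families:
                if config_grid and family in config_grid:
                    candidates = list(config_grid[family])
                elif configs and family in configs:
                    candidates = [configs[family]]
                else:
                    candidates = [ModelConfig(family=family)]
                best_model, best_val = None, -np.inf
                for cand in candidates:
                    cand = replace(cand, family=family, seed=seed)
                    model = train_model(
                        cand, Xtr, ytr, Xva, yva,
                        graph=graph if family == "GCN" else None,
                        fingerprint=resources.fingerprint() | {"with_biophysics": flag},
                    )
                    val_r, _ = _safe_corr(yva, model.predict(Xva))
                    val_score = val_r if val_r is not None else -np.inf
                    if best_model is None or val_score > best_val:
                        best_model, best_val = model, val_score
                report = evaluate_model(best_model, Xte, yte, cte, scheme=scheme, seed=seed)
                rows.append(
                    {
                        "scheme": scheme,
                        "family": family,
                        "biophysics": flag,
                        "seed": seed,
                        "pearson": report.pearson,
                        "spearman": report.spearman,
                        "mae": report.mae,
                        "n_train": len(ytr),
                        "n_test": len(yte),
                        "n_dropped": len(split.dropped),
                    }
                )
    return pd.DataFrame(rows)


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Median metrics over repeats per (scheme, family, biophysics)."""
    return (
        results.groupby(["scheme", "family", "biophysics"], as_index=False)[
            ["pearson", "spearman", "mae"]
        ]
        .median()
        .rename(columns={c: f"median_{c}" for c in ("pearson", "spearman", "mae")})
    )
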