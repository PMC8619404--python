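"""CNN architecture family, training protocol, metrics and model selection.

The benchmark compares models trained on unaugmented known peptides
(unAUG, one model group per cross-validation fold) with models trained on
augmented peptides (AUG).  At full scale the hyperparameter grid spans
24 architectures (2 block types x 4 depths x 3 filter widths), 2 learning
rates (0.005 and 0.0001), 6 training sources (5 unAUG folds + AUG) and 3
repeats — 864 models.  A reduced "desk" grid with the same structure is
provided for laptop-scale runs.

Models are scored by accuracy, precision, recall and F1 with the
neurotoxic class as positive; unAUG and AUG groups are compared with a
paired t-test on per-cell metrics, and the final model per group is the
one maximizing F1 on the simulation dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from ._nn import Adam, Conv1D, ConfigurationError, Dense, Flatten, MaxPool1D, Network, ReLU
from .datasets import DatasetBundle, EncodedBatch, one_hot_encode

__all__ = [
    "ModelSpec", "MetricsReport", "GroupComparison", "TrainedModel",
    "GridResult", "build_model", "train", "evaluate", "paired_t_test",
    "make_grid", "paper_grid", "desk_grid", "run_grid", "select_best",
    "ConfigurationError",
]

#: Learning rates of the full benchmark grid.
LEARNING_RATES = (0.005, 0.0001)


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the hyperparameter grid.

    ``block_type`` chooses the repeating unit (conv-pool or
    conv-conv-pool); ``filters`` gives the output channels of each of the
    ``n_blocks`` blocks; ``train_source`` is ``"aug"`` or
    ``"unaug_fold_<i>"`` (1-based fold index).
    """

    block_type: str  # "conv_pool" | "conv_conv_pool"
    n_blocks: int
    filters: tuple[int, ...]
    kernel_size: int = 5
    dense_units: int = 32
    learning_rate: float = 0.005
    repeat_index: int = 1
    train_source: str = "aug"

    def __post_init__(self) -> None:
        if self.block_type not in ("conv_pool", "conv_conv_pool"):
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if not (1 <= self.n_blocks <= 4):
            raise ValueError("n_blocks must be in 1..4")
        if len(self.filters) != self.n_blocks:
            raise ValueError("need one filter count per block")
        if any(f < 1 for f in self.filters):
            raise ValueError("filter counts must be positive")
        if self.kernel_size < 1 or self.dense_units < 1:
            raise ValueError("kernel_size and dense_units must be positive")
        if not (1 <= self.repeat_index <= 3):
            raise ValueError("repeat_index must be in 1..3")

    @property
    def architecture_key(self) -> str:
        """Identifies the architecture cell (ignores lr/source/repeat)."""
        return f"{self.block_type}-{self.n_blocks}x{'_'.join(map(str, self.filters))}-k{self.kernel_size}-d{self.dense_units}"

    @property
    def cell_key(self) -> str:
        return f"{self.architecture_key}|lr{self.learning_rate}|{self.train_source}|r{self.repeat_index}"


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and derived metrics for one model on one dataset.

    A metric whose denominator is zero (e.g. precision with no positive
    predictions) is ``None`` and listed in ``undefined`` — never silently
    reported as 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: tuple[str, ...] = ()

    @classmethod
    def from_counts(cls, tp: int, tn: int, fp: int, fn: int) -> "MetricsReport":
        undefined = []
        total = tp + tn + fp + fn
        accuracy = (tp + tn) / total if total else None
        if total == 0:
            undefined.append("accuracy")
        precision = tp / (tp + fp) if (tp + fp) else None
        if tp + fp == 0:
            undefined.append("precision")
        recall = tp / (tp + fn) if (tp + fn) else None
        if tp + fn == 0:
            undefined.append("recall")
        if precision is not None and recall is not None and (precision + recall) > 0:
            f1 = 2 * precision * recall / (precision + recall)
        else:
            f1 = None
            undefined.append("f1")
        return cls(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                   precision=precision, recall=recall, f1=f1,
                   undefined=tuple(undefined))


@dataclass(frozen=True)
class GroupComparison:
    """Paired t-test between two matched metric vectors."""

    metric_name: str
    group_a: tuple[float, ...]
    group_b: tuple[float, ...]
    t_statistic: float
    p_value: float
    n_pairs: int


@dataclass
class TrainedModel:
    """A trained network with its spec and training history."""

    network: Network
    spec: ModelSpec
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1

    def predict(self, batch: EncodedBatch) -> np.ndarray:
        """Class predictions (1 = neurotoxic) by argmax of the softmax."""
        return self.predict_proba(batch).argmax(axis=1)

    def predict_proba(self, batch: EncodedBatch) -> np.ndarray:
        return self.network.predict_proba(batch.tensor)


def build_model(spec: ModelSpec, L_max: int, seed: int = 0) -> Network:
    """Construct the network for one spec.

    Layout: ``n_blocks`` repeats of the block (conv-ReLU[-conv-ReLU] +
    max-pool) over the L_max x 20 input, then flatten, a ReLU dense layer
    and a 2-way softmax head.  Raises :class:`ConfigurationError` at build
    time if the spatial dimension collapses below the kernel size before
    the last block (or below the pool width).
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    length, channels = L_max, 20
    for b in range(spec.n_blocks):
        n_convs = 2 if spec.block_type == "conv_conv_pool" else 1
        for _ in range(n_convs):
            if length < spec.kernel_size:
                raise ConfigurationError(
                    f"block {b + 1}: spatial length {length} < kernel "
                    f"{spec.kernel_size}"
                )
            layers.append(Conv1D(channels, spec.filters[b], spec.kernel_size, rng))
            layers.append(ReLU())
            channels = spec.filters[b]
            length = length - spec.kernel_size + 1
        if length < 2:
            raise ConfigurationError(
                f"block {b + 1}: spatial length {length} < pool width 2"
            )
        layers.append(MaxPool1D())
        length //= 2
    layers.append(Flatten())
    layers.append(Dense(length * channels, spec.dense_units, rng))
    layers.append(ReLU())
    layers.append(Dense(spec.dense_units, 2, rng))
    return Network(layers)


def _f1_of_predictions(pred: np.ndarray, labels: np.ndarray) -> float:
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 2 * p * r / (p + r)


def train(
    network: Network,
    train_batch: EncodedBatch,
    val_batch: EncodedBatch,
    spec: ModelSpec,
    seed: int = 0,
    max_epochs: int = 200,
    batch_size: int = 32,
    patience: int = 20,
) -> TrainedModel:
    """Train with Adam and cross-entropy, early-stopping on validation F1.

    The checkpoint from the best validation epoch is restored before
    returning.  Fully deterministic for fixed seed and inputs.  Aborts
    with ``FloatingPointError`` if the loss goes non-finite.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(network.parameters, lr=spec.learning_rate)
    n = train_batch.tensor.shape[0]
    best_f1, best_state, best_epoch = -1.0, network.get_state(), -1
    history: list[dict] = []
    stale = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = network.loss_and_backward(
                train_batch.tensor[idx], train_batch.labels[idx]
            )
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // batch_size} "
                    f"(lr={spec.learning_rate}, cell={spec.cell_key})"
                )
            opt.step(network.gradients)
            epoch_loss += loss * len(idx)
        val_pred = network.predict_proba(val_batch.tensor).argmax(axis=1)
        val_f1 = _f1_of_predictions(val_pred, val_batch.labels)
        history.append({"epoch": epoch, "loss": epoch_loss / n, "val_f1": val_f1})
        if val_f1 > best_f1:
            best_f1, best_state, best_epoch = val_f1, network.get_state(), epoch
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    network.set_state(best_state)
    return TrainedModel(network=network, spec=spec, history=history,
                        best_epoch=best_epoch)


def evaluate(model: TrainedModel, batch: EncodedBatch) -> MetricsReport:
    """Confusion counts and metrics on one dataset, neurotoxic = positive."""
    if batch.tensor.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty batch")
    pred = model.predict(batch)
    y = batch.labels
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return MetricsReport.from_counts(tp=tp, tn=tn, fp=fp, fn=fn)


def paired_t_test(
    a: Sequence[float], b: Sequence[float], metric_name: str = ""
) -> GroupComparison:
    """Two-sided paired Student t-test on matched metric vectors.

    t = mean(d) / (sd(d)/sqrt(n)) on differences d = a - b, with n-1
    degrees of freedom.  Raises ``ValueError`` on zero-variance
    differences (degenerate input).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate input: all paired differences identical")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return GroupComparison(
        metric_name=metric_name,
        group_a=tuple(a),
        group_b=tuple(b),
        t_statistic=float(t),
        p_value=float(p),
        n_pairs=n,
    )


def make_grid(
    n_folds: int = 5,
    block_types: Iterable[str] = ("conv_pool", "conv_conv_pool"),
    depths: Iterable[int] = (1, 2, 3, 4),
    base_filters: Iterable[int] = (8, 16, 32),
    learning_rates: Iterable[float] = LEARNING_RATES,
    repeats: int = 3,
    kernel_size: int = 5,
    dense_units: int = 32,
) -> list[ModelSpec]:
    """Enumerate the benchmark grid.

    Architectures are block_type x depth x base filter width (filters
    double per block); training sources are the ``n_folds`` unAUG folds
    plus AUG.  The full-scale defaults enumerate 2 x 4 x 3 = 24
    architectures x 2 learning rates x (5 + 1) sources x 3 repeats = 864
    cells.
    """
    sources = [f"unaug_fold_{i + 1}" for i in range(n_folds)] + ["aug"]
    grid: list[ModelSpec] = []
    for source in sources:
        for lr in learning_rates:
            for bt in block_types:
                for depth in depths:
                    for bf in base_filters:
                        filters = tuple(bf * 2**i for i in range(depth))
                        for r in range(1, repeats + 1):
                            grid.append(ModelSpec(
                                block_type=bt, n_blocks=depth, filters=filters,
                                kernel_size=kernel_size, dense_units=dense_units,
                                learning_rate=lr, repeat_index=r,
                                train_source=source,
                            ))
    return grid


def paper_grid(n_folds: int = 5) -> list[ModelSpec]:
    """The full 864-cell grid (24 architectures x 2 lrs x 6 sources x 3)."""
    return make_grid(n_folds=n_folds)


def desk_grid(n_folds: int = 5) -> list[ModelSpec]:
    """A 12-cell laptop-scale grid: 2 shallow architectures x 1 learning
    rate x 6 training sources x 1 repeat."""
    return make_grid(
        n_folds=n_folds,
        block_types=("conv_pool", "conv_conv_pool"),
        depths=(2,),
        base_filters=(8,),
        learning_rates=(0.005,),
        repeats=1,
    )


@dataclass
class GridResult:
    """One completed grid cell."""

    spec: ModelSpec
    model: TrainedModel | None
    val_f1: float
    test_metrics: MetricsReport
    sim_metrics: MetricsReport
    n_parameters: int


def _cell_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def _split_train_val(
    batch: EncodedBatch, val_fraction: float, seed: int
) -> tuple[EncodedBatch, EncodedBatch]:
    """Stratified train/validation split of an encoded batch."""
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(batch.labels == 1)
    idx_neg = np.flatnonzero(batch.labels == 0)
    val_idx: list[int] = []
    for idx in (idx_pos, idx_neg):
        perm = rng.permutation(idx)
        n_val = max(1, int(round(len(idx) * val_fraction)))
        val_idx.extend(perm[:n_val])
    val_mask = np.zeros(batch.tensor.shape[0], dtype=bool)
    val_mask[val_idx] = True

    def take(mask: np.ndarray) -> EncodedBatch:
        ids = [i for i, m in zip(batch.ids, mask) if m] if batch.ids else None
        return EncodedBatch(
            tensor=batch.tensor[mask], lengths=batch.lengths[mask],
            labels=batch.labels[mask], L_max=batch.L_max, ids=ids,
        )

    return take(~val_mask), take(val_mask)


def run_grid(
    bundle: DatasetBundle,
    grid: list[ModelSpec],
    seed: int = 0,
    L_max: int = 300,
    max_epochs: int = 200,
    batch_size: int = 32,
    patience: int = 20,
    val_fraction: float = 0.2,
    log_path: str | Path | None = None,
    keep_models: bool = True,
) -> list[GridResult]:
    """Train and evaluate every spec in the grid.

    Each cell gets its own derived seed (independent of grid ordering), an
    80/20 stratified train/validation split of its training source, test
    metrics on the matching fold's test set (unAUG sources) or on all test
    folds pooled (AUG source), and simulation metrics on the simulation
    set.  With ``log_path`` set, completed cells are appended to a TSV log
    and already-logged cells are skipped on re-run, making an interrupted
    grid resumable (resumed cells carry no in-memory model).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    sim_batch = one_hot_encode(bundle.simulation, L_max)
    all_test = [rec for fold in bundle.test for rec in fold]

    done: dict[str, dict] = {}
    if log_path is not None and Path(log_path).exists():
        import pandas as pd

        df = pd.read_csv(log_path, sep="\t")
        done = {row["cell_key"]: dict(row) for _, row in df.iterrows()}

    results: list[GridResult] = []
    log_rows: list[dict] = []
    for index, spec in enumerate(grid):
        if spec.cell_key in done:
            row = done[spec.cell_key]
            results.append(GridResult(
                spec=spec, model=None, val_f1=row["val_f1"],
                test_metrics=MetricsReport.from_counts(
                    int(row["test_tp"]), int(row["test_tn"]),
                    int(row["test_fp"]), int(row["test_fn"])),
                sim_metrics=MetricsReport.from_counts(
                    int(row["sim_tp"]), int(row["sim_tn"]),
                    int(row["sim_fp"]), int(row["sim_fn"])),
                n_parameters=int(row["n_parameters"]),
            ))
            continue
        if spec.train_source == "aug":
            train_records = bundle.aug_train
            test_records = all_test
        else:
            fold = int(spec.train_source.rsplit("_", 1)[1]) - 1
            train_records = bundle.unaug_train[fold]
            test_records = bundle.test[fold]
        cell_seed = _cell_seed(seed, index)
        train_all = one_hot_encode(train_records, L_max)
        tr, va = _split_train_val(train_all, val_fraction, cell_seed)
        network = build_model(spec, L_max, seed=cell_seed)
        model = train(network, tr, va, spec, seed=cell_seed,
                      max_epochs=max_epochs, batch_size=batch_size,
                      patience=patience)
        val_f1 = max((h["val_f1"] for h in model.history), default=0.0)
        test_m = evaluate(model, one_hot_encode(test_records, L_max))
        sim_m = evaluate(model, sim_batch)
        result = GridResult(
            spec=spec, model=model if keep_models else None,
            val_f1=val_f1, test_metrics=test_m, sim_metrics=sim_m,
            n_parameters=model.network.n_parameters(),
        )
        results.append(result)
        log_rows.append({
            "cell_key": spec.cell_key, "val_f1": val_f1,
            "test_tp": test_m.tp, "test_tn": test_m.tn,
            "test_fp": test_m.fp, "test_fn": test_m.fn,
            "sim_tp": sim_m.tp, "sim_tn": sim_m.tn,
            "sim_fp": sim_m.fp, "sim_fn": sim_m.fn,
            "n_parameters": result.n_parameters,
        })
    if log_path is not None and log_rows:
        import pandas as pd

        df_new = pd.DataFrame(log_rows)
        if Path(log_path).exists():
            old = pd.read_csv(log_path, sep="\t")
            df_new = pd.concat([old, df_new], ignore_index=True)
        df_new.to_csv(log_path, sep="\t", index=False)
    return results


def select_best(
    results: list[GridResult],
    criterion: str = "f1",
    dataset: str = "simulation",
) -> GridResult:
    """Arg-max cell by ``criterion`` on ``dataset`` ("simulation" or
    "test"); ties broken by fewer parameters, then lower learning rate,
    then lowest repeat index.  Undefined metrics rank below any value."""
    if not results:
        raise ValueError("empty results table")

    def key(r: GridResult):
        m = r.sim_metrics if dataset == "simulation" else r.test_metrics
        value = getattr(m, criterion)
        value = -math.inf if value is None else value
        return (-value, r.n_parameters, r.spec.learning_rate, r.spec.repeat_index)

    return min(results, key=key)
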