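"""Dataset splitting, Adam training on categorical cross-entropy, and
model evaluation.

The protocol: a stratified 70/10/20 train/validation/test split; training
in mini-batches of 16 with the Adam optimizer; categorical cross-entropy
against one-hot targets (promoter = (1, 0), non-promoter = (0, 1)); and
epoch selection by best validation accuracy, so the returned parameters
are those of the epoch before over-fitting sets in, not necessarily the
last one.

The two output neurons are sigmoids, so their pair need not sum to one;
inside the loss the pair is renormalized (p_i / sum_j p_j) before the
log — the usual convention when a categorical loss is applied to
probability outputs — which is what makes the cross-class gradient
non-vanishing for this head.

All randomness (parameter init, shuffling, batch order) flows from
``TrainConfig.seed``; with the pure-numpy backend training is bit-exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnn_model import (
    INPUT_DEPTH,
    ModelParameters,
    ModelSpec,
    build_model,
    forward,
    predict_classes,
)
from .errors import ConfigurationError, DataError
from .metrics import ConfusionCounts, summary, tally
from .sequence_io import PROMOTER, SequenceRecord, encode_batch

DEFAULT_FRACTIONS = (0.70, 0.10, 0.20)


@dataclass
class DatasetSplit:
    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    test: list[SequenceRecord]
    seed: int
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    max_epochs: int = 20
    learning_rate: float = 1e-3  # Adam step size
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0
    patience: int = 3  # epochs without validation improvement before stopping

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1")


@dataclass
class TrainingHistory:
    train_accuracy: list[float] = field(default_factory=list)
    validation_accuracy: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    selected_epoch: int = 0  # 1-based; argmax validation accuracy, earliest tie

    @property
    def n_epochs(self) -> int:
        return len(self.validation_accuracy)


def split_dataset(
    records: Sequence[SequenceRecord],
    seed: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
) -> DatasetSplit:
    """Stratified train/validation/test split, deterministic given ``seed``.

    Fractions apply to the full set: by default 70% train, 10% validation,
    20% test, preserving the class ratio in each part to within one record.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions must sum to 1, got {fractions}")
    by_class: dict[int, list[SequenceRecord]] = {}
    for rec in records:
        if rec.label is None:
            raise DataError(f"record {rec.id!r} is unlabeled; every record needs a label")
        by_class.setdefault(rec.label, []).append(rec)
    for label, members in by_class.items():
        if len(members) < 10:
            raise DataError(
                f"class {label} has only {len(members)} records (< 10); "
                "use a smaller split or more data"
            )
    rng = np.random.default_rng(seed)
    parts: tuple[list[SequenceRecord], ...] = ([], [], [])
    f_train, f_val, _ = fractions
    for label in sorted(by_class):
        members = by_class[label]
        order = rng.permutation(len(members))
        n = len(members)
        n_train = int(round(f_train * n))
        n_val = int(round(f_val * n))
        if n_train < 1 or n_val < 1 or n - n_train - n_val < 1:
            raise DataError(f"class {label}: split leaves an empty part (n = {n})")
        for slot, (lo, hi) in enumerate(
            [(0, n_train), (n_train, n_train + n_val), (n_train + n_val, n)]
        ):
            parts[slot].extend(members[i] for i in order[lo:hi])
    return DatasetSplit(
        train=parts[0], validation=parts[1], test=parts[2], seed=seed, fractions=fractions
    )


def _targets(records: Sequence[SequenceRecord]) -> np.ndarray:
    """One-hot class targets: promoter -> (1, 0), non-promoter -> (0, 1)."""
    y = np.zeros((len(records), 2))
    for i, rec in enumerate(records):
        if rec.label is None:
            raise DataError(f"record {rec.id!r} is unlabeled")
        y[i, 0 if rec.label == PROMOTER else 1] = 1.0
    return y


def _loss_and_grad(scores: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy on renormalized sigmoid pairs, and
    its gradient with respect to the pre-sigmoid logits."""
    eps = 1e-12
    p = np.clip(scores, eps, 1.0 - eps)
    s = p.sum(axis=1, keepdims=True)
    loss = float(-(targets * np.log(p / s)).sum(axis=1).mean())
    # dL/dz_i = (p_i / s - y_i) * (1 - p_i), averaged over the batch
    dz = (p / s - targets) * (1.0 - p) / scores.shape[0]
    return loss, dz


def _backward(params: ModelParameters, cache: dict, dz_out: np.ndarray) -> list[np.ndarray]:
    """Gradients for every array in ``params.arrays()`` order."""
    spec = params.spec
    d_out_w = cache["dense_a"].T @ dz_out
    d_out_b = dz_out.sum(axis=0)
    d_dense_a = dz_out @ params.out_w.T
    d_dense_z = d_dense_a * (cache["dense_z"] > 0)
    d_dense_w = cache["flat"].T @ d_dense_z
    d_dense_b = d_dense_z.sum(axis=0)
    d_flat = d_dense_z @ params.dense_w.T

    last_len = spec.layer_lengths()[-1]
    grad = d_flat.reshape(d_flat.shape[0], last_len, spec.conv_layers[-1].n_filters)

    d_conv_w: list[np.ndarray] = [None] * len(spec.conv_layers)
    d_conv_b: list[np.ndarray] = [None] * len(spec.conv_layers)
    for i in range(len(spec.conv_layers) - 1, -1, -1):
        layer = spec.conv_layers[i]
        relu_map = cache["relu"][i]  # (B, conv_len, F)
        if layer.pool_size > 0:
            arg = cache["pool_arg"][i]  # (B, m, F) within-window argmax
            b, m, f = arg.shape
            scatter = np.zeros((b, m, layer.pool_size, f))
            np.put_along_axis(scatter, arg[:, :, None, :], grad[:, :, None, :], axis=2)
            d_relu = np.zeros_like(relu_map)
            d_relu[:, : m * layer.pool_size, :] = scatter.reshape(b, m * layer.pool_size, f)
        else:
            d_relu = grad
        dz = d_relu * (cache["pre_relu"][i] > 0)
        x = cache["inputs"][i]  # (B, in_len, depth)
        windows = np.lib.stride_tricks.sliding_window_view(x, layer.filter_length, axis=1)
        d_conv_w[i] = np.einsum("bodl,bof->fld", windows, dz, optimize=True)
        d_conv_b[i] = dz.sum(axis=(0, 1))
        if i > 0:
            L = layer.filter_length
            dz_pad = np.pad(dz, ((0, 0), (L - 1, L - 1), (0, 0)))
            w_flip = params.conv_weights[i][:, ::-1, :]
            dz_win = np.lib.stride_tricks.sliding_window_view(dz_pad, L, axis=1)
            grad = np.einsum("btfj,fjd->btd", dz_win, w_flip, optimize=True)
    return [*d_conv_w, *d_conv_b, d_dense_w, d_dense_b, d_out_w, d_out_b]


class _Adam:
    def __init__(self, arrays: list[np.ndarray], config: TrainConfig):
        self.config = config
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> None:
        c = self.config
        self.t += 1
        lr_t = c.learning_rate * np.sqrt(1 - c.beta2**self.t) / (1 - c.beta1**self.t)
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * g * g
            a -= lr_t * m / (np.sqrt(v) + c.eps)


def _accuracy(params: ModelParameters, batch: np.ndarray, labels: np.ndarray) -> float:
    return float((predict_classes(params, batch) == labels).mean())


def train(
    spec: ModelSpec,
    split: DatasetSplit,
    config: TrainConfig = TrainConfig(),
) -> tuple[ModelParameters, TrainingHistory]:
    """Train ``spec`` on ``split`` and return the selected-epoch parameters.

    The model snapshot with the best validation accuracy (earliest epoch on
    ties) is returned, with ``selected_epoch`` recorded in its metadata;
    training stops early after ``config.patience`` epochs without a new
    validation best, else runs to ``config.max_epochs``.
    """
    if not split.train or not split.validation:
        raise DataError("training and validation sets must be non-empty")
    for rec in split.train + split.validation:
        if len(rec) != spec.input_length:
            raise DataError(
                f"record {rec.id!r} has length {len(rec)}, expected {spec.input_length}"
            )
    x_train = encode_batch(split.train)
    y_train = _targets(split.train)
    lab_train = np.array([r.label for r in split.train])
    x_val = encode_batch(split.validation)
    lab_val = np.array([r.label for r in split.validation])

    params = build_model(spec, config.seed)
    params.metadata["train_seed"] = int(config.seed)
    params.metadata["batch_size"] = int(config.batch_size)
    params.metadata["learning_rate"] = float(config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    optimizer = _Adam(params.arrays(), config)
    history = TrainingHistory()

    best = None
    best_val = -np.inf
    since_best = 0
    n = len(split.train)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            scores, cache = forward(params, x_train[idx], return_cache=True)
            loss, dz = _loss_and_grad(scores, y_train[idx])
            grads = _backward(params, cache, dz)
            optimizer.step(params.arrays(), grads)
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / n_batches)
        history.train_accuracy.append(_accuracy(params, x_train, lab_train))
        val_acc = _accuracy(params, x_val, lab_val)
        history.validation_accuracy.append(val_acc)
        if val_acc > best_val:
            best_val = val_acc
            best = params.copy()
            history.selected_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    assert best is not None
    best.metadata["selected_epoch"] = history.selected_epoch
    best.metadata["epochs_run"] = history.n_epochs
    return best, history


def evaluate(
    params: ModelParameters, records: Sequence[SequenceRecord]
) -> tuple[ConfusionCounts, dict[str, float]]:
    """Confusion counts and Sn/Sp/AC/CC report for labeled records."""
    if not records:
        raise DataError("cannot evaluate on an empty record list")
    labels = []
    for rec in records:
        if rec.label is None:
            raise DataError(f"record {rec.id!r} is unlabeled")
        labels.append(rec.label)
    preds = predict_classes(params, encode_batch(records))
    counts = tally(labels, preds.tolist())
    return counts, summary(counts, zero_on_degenerate=True)


def write_history(history: TrainingHistory, path) -> None:
    """Per-epoch training log as delimited text."""
    with open(path, "w") as handle:
        handle.write("# epoch\ttrain_loss\ttrain_accuracy\tvalidation_accuracy\tselected\n")
        for i in range(history.n_epochs):
            sel = "*" if (i + 1) == history.selected_epoch else ""
            handle.write(
                f"{i + 1}\t{history.train_loss[i]:.6f}\t{history.train_accuracy[i]:.4f}"
                f"\t{history.validation_accuracy[i]:.4f}\t{sel}\n"
            )
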