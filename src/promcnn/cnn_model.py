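"""Convolutional promoter classifier: architecture specs, parameters,
forward pass, and model file round-tripping.

The network is the standard one-dimensional sequence CNN for promoter
recognition: one or more valid (unpadded) convolutional layers, stride 1,
ReLU activations, each optionally followed by non-overlapping max-pooling;
then a fully connected ReLU layer (128 units by default) and a 2-neuron
sigmoid output, one neuron per class — promoter encoded (1, 0),
non-promoter (0, 1).

Architectures are written as "F, L, P" triplets — F filters of length L
followed by max-pooling of size P — with "/" separating layers, e.g.
"200, 21, 4" or "100,7, 0 / 150, 21, 12".  P = 0 means no pooling after
that layer.  A valid convolution maps length n to n - L + 1, so
"300, 21, 231" on a 251-nt input pools its whole 231-length activation
map to a single value (global max pooling).

Everything here is plain numpy in double precision, so forward passes
and (in :mod:`promcnn.training`) gradients are bit-reproducible given a
seed.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError, ModelIOError

INPUT_DEPTH = 4  # one-hot A, T, G, C
MODEL_FORMAT_VERSION = 1

PROMOTER_NEURON = 0  # output column holding the promoter score
NONPROMOTER_NEURON = 1


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolutional layer: ``n_filters`` filters of ``filter_length``
    positions, followed by max-pooling of size ``pool_size`` (0 = none)."""

    n_filters: int
    filter_length: int
    pool_size: int

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ConfigurationError(f"n_filters must be >= 1, got {self.n_filters}")
        if self.filter_length < 1:
            raise ConfigurationError(f"filter_length must be >= 1, got {self.filter_length}")
        if self.pool_size < 0:
            raise ConfigurationError(f"pool_size must be >= 0, got {self.pool_size}")

    def output_length(self, input_length: int) -> int:
        """Length after valid convolution (stride 1) and pooling."""
        conv_len = input_length - self.filter_length + 1
        if conv_len < 1:
            raise ConfigurationError(
                f"filter_length {self.filter_length} exceeds input length {input_length}"
            )
        if self.pool_size > 0:
            pooled = conv_len // self.pool_size
            if pooled < 1:
                raise ConfigurationError(
                    f"pool_size {self.pool_size} exceeds activation map length {conv_len}"
                )
            return pooled
        return conv_len


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture: input length, conv layers, dense head."""

    input_length: int
    conv_layers: tuple[ConvLayerSpec, ...]
    dense_units: int = 128
    n_classes: int = 2
    stride: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_layers", tuple(self.conv_layers))
        if self.input_length < 1:
            raise ConfigurationError("input_length must be >= 1")
        if not self.conv_layers:
            raise ConfigurationError("at least one convolutional layer is required")
        if self.dense_units < 1:
            raise ConfigurationError("dense_units must be >= 1")
        if self.n_classes != 2:
            raise ConfigurationError("only binary (promoter / non-promoter) output is supported")
        if self.stride != 1:
            raise ConfigurationError("stride is fixed at 1")
        self.layer_lengths()  # raises if any layer is infeasible

    def layer_lengths(self) -> list[int]:
        """Spatial length after each conv(+pool) layer, starting from the input."""
        lengths = [self.input_length]
        for i, layer in enumerate(self.conv_layers):
            try:
                lengths.append(layer.output_length(lengths[-1]))
            except ConfigurationError as exc:
                raise ConfigurationError(f"conv layer {i + 1}: {exc}") from None
        return lengths

    def flattened_size(self) -> int:
        return self.layer_lengths()[-1] * self.conv_layers[-1].n_filters

    def architecture_string(self) -> str:
        return " / ".join(
            f"{l.n_filters}, {l.filter_length}, {l.pool_size}" for l in self.conv_layers
        )

    def n_parameters(self) -> int:
        """Total trainable parameter count."""
        total = 0
        depth = INPUT_DEPTH
        for layer in self.conv_layers:
            total += layer.n_filters * layer.filter_length * depth + layer.n_filters
            depth = layer.n_filters
        total += self.flattened_size() * self.dense_units + self.dense_units
        total += self.dense_units * self.n_classes + self.n_classes
        return total


def parse_architecture(text: str, input_length: int, *, dense_units: int = 128) -> ModelSpec:
    """Parse an "F, L, P / F, L, P ..." architecture string into a ModelSpec."""
    if not text or not text.strip():
        raise ConfigurationError("empty architecture string")
    layers = []
    for li, chunk in enumerate(text.split("/"), 1):
        tokens = [t.strip() for t in chunk.split(",")]
        if len(tokens) != 3:
            raise ConfigurationError(
                f"layer {li} ({chunk.strip()!r}): expected 3 comma-separated integers "
                f"(filters, filter length, pool size), got {len(tokens)} tokens"
            )
        values = []
        for ti, tok in enumerate(tokens, 1):
            try:
                values.append(int(tok))
            except ValueError:
                raise ConfigurationError(
                    f"layer {li}, token {ti}: {tok!r} is not an integer"
                ) from None
        layers.append(ConvLayerSpec(*values))
    return ModelSpec(input_length=input_length, conv_layers=tuple(layers), dense_units=dense_units)


@dataclass
class ModelParameters:
    """Concrete weights for a :class:`ModelSpec`, plus provenance metadata.

    Conv layer i holds weights of shape (n_filters, filter_length, depth)
    and a bias vector (n_filters,); the dense and output layers hold
    ordinary (in, out) weight matrices and bias vectors.
    """

    spec: ModelSpec
    conv_weights: list[np.ndarray]
    conv_biases: list[np.ndarray]
    dense_w: np.ndarray
    dense_b: np.ndarray
    out_w: np.ndarray
    out_b: np.ndarray
    metadata: dict = field(default_factory=dict)

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            spec=self.spec,
            conv_weights=[w.copy() for w in self.conv_weights],
            conv_biases=[b.copy() for b in self.conv_biases],
            dense_w=self.dense_w.copy(),
            dense_b=self.dense_b.copy(),
            out_w=self.out_w.copy(),
            out_b=self.out_b.copy(),
            metadata=dict(self.metadata),
        )

    def arrays(self) -> list[np.ndarray]:
        """All trainable arrays, in a fixed order (shared with training)."""
        return [
            *self.conv_weights,
            *self.conv_biases,
            self.dense_w,
            self.dense_b,
            self.out_w,
            self.out_b,
        ]


def build_model(spec: ModelSpec, seed: int) -> ModelParameters:
    """Initialize untrained parameters for ``spec``.

    He (variance-scaled) initialization for the ReLU conv/dense layers,
    Glorot for the sigmoid output; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    conv_weights, conv_biases = [], []
    depth = INPUT_DEPTH
    for layer in spec.conv_layers:
        fan_in = layer.filter_length * depth
        conv_weights.append(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(layer.n_filters, layer.filter_length, depth))
        )
        conv_biases.append(np.zeros(layer.n_filters))
        depth = layer.n_filters
    flat = spec.flattened_size()
    dense_w = rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, spec.dense_units))
    dense_b = np.zeros(spec.dense_units)
    # Output layer gets a deliberately small Glorot init (gain 0.01): the
    # sigmoid-pair head trained with a categorical loss has a flat saturated
    # region (both neurons near 1) that large initial logits can land in;
    # starting the readout near zero keeps early logits near 0 and the
    # per-class gradients alive.
    glorot = 0.01 * np.sqrt(6.0 / (spec.dense_units + spec.n_classes))
    out_w = rng.uniform(-glorot, glorot, size=(spec.dense_units, spec.n_classes))
    out_b = np.zeros(spec.n_classes)
    return ModelParameters(
        spec=spec,
        conv_weights=conv_weights,
        conv_biases=conv_biases,
        dense_w=dense_w,
        dense_b=dense_b,
        out_w=out_w,
        out_b=out_b,
        metadata={
            "architecture": spec.architecture_string(),
            "input_length": spec.input_length,
            "dense_units": spec.dense_units,
            "init": "he(conv,dense)/glorot*0.01(out)",
            "init_seed": int(seed),
        },
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def conv1d_valid(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid cross-correlation, stride 1: the sliding dot product W·x + b.

    x: (batch, length, depth); weights: (filters, filter_length, depth).
    Returns (batch, length - filter_length + 1, filters).
    """
    L = weights.shape[1]
    # windows: (batch, out_len, depth, L)
    windows = np.lib.stride_tricks.sliding_window_view(x, L, axis=1)
    return np.einsum("bodl,fld->bof", windows, weights, optimize=True) + bias


def max_pool(x: np.ndarray, pool: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max-pooling along axis 1; trailing remainder dropped.

    Returns the pooled array and the within-window argmax (kept for
    gradient routing during training).
    """
    b, n, f = x.shape
    m = n // pool
    trimmed = x[:, : m * pool, :].reshape(b, m, pool, f)
    arg = trimmed.argmax(axis=2)
    pooled = np.take_along_axis(trimmed, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return pooled, arg


def forward(params: ModelParameters, batch: np.ndarray, *, return_cache: bool = False):
    """Run the network on a (batch, input_length, 4) one-hot array.

    Returns the (batch, 2) sigmoid score array; with ``return_cache=True``
    also returns the intermediate activations needed for backpropagation.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim == 2:
        batch = batch[None]
    if batch.ndim != 3 or batch.shape[2] != INPUT_DEPTH:
        raise DataError(f"batch must be (B, n, 4), got shape {batch.shape}")
    if batch.shape[1] != params.spec.input_length:
        raise DataError(
            f"input length {batch.shape[1]} does not match model input length "
            f"{params.spec.input_length}"
        )
    cache = {"inputs": [], "pre_relu": [], "relu": [], "pool_arg": []}
    x = batch
    for layer, W, b in zip(params.spec.conv_layers, params.conv_weights, params.conv_biases):
        cache["inputs"].append(x)
        z = conv1d_valid(x, W, b)
        cache["pre_relu"].append(z)
        a = np.maximum(z, 0.0)
        cache["relu"].append(a)
        if layer.pool_size > 0:
            a, arg = max_pool(a, layer.pool_size)
            cache["pool_arg"].append(arg)
        else:
            cache["pool_arg"].append(None)
        x = a
    flat = x.reshape(x.shape[0], -1)
    cache["flat"] = flat
    dense_z = flat @ params.dense_w + params.dense_b
    cache["dense_z"] = dense_z
    dense_a = np.maximum(dense_z, 0.0)
    cache["dense_a"] = dense_a
    scores = _sigmoid(dense_a @ params.out_w + params.out_b)
    if return_cache:
        return scores, cache
    return scores


def forward_scores(
    params: ModelParameters, batch: Sequence[np.ndarray] | np.ndarray
) -> np.ndarray:
    """Score a batch of one-hot matrices: one (promoter, non-promoter)
    sigmoid pair per input, each in [0, 1]."""
    if not isinstance(batch, np.ndarray):
        batch = np.stack([np.asarray(m) for m in batch])
    return forward(params, batch)


def classify(score_pair: Sequence[float]) -> tuple[int, float]:
    """Map a (promoter, non-promoter) score pair to (class, promoter score).

    Promoter iff the promoter neuron strictly exceeds the non-promoter
    neuron; ties break to non-promoter (conservative).  The reported score
    is always the promoter-neuron output.
    """
    p, q = float(score_pair[PROMOTER_NEURON]), float(score_pair[NONPROMOTER_NEURON])
    return (1 if p > q else 0), p


def predict_classes(params: ModelParameters, batch) -> np.ndarray:
    """Binary class (1 = promoter) per input."""
    scores = forward_scores(params, batch)
    return (scores[:, PROMOTER_NEURON] > scores[:, NONPROMOTER_NEURON]).astype(np.int64)


def build_positional_motif_model(
    input_length: int,
    motifs: Sequence[tuple[str, int]],
    *,
    gain: float = 10.0,
) -> ModelParameters:
    """Hand-construct a network that calls promoter iff every motif matches.

    ``motifs`` is a list of (consensus, start) pairs with 1-based start
    positions; the model classifies a window as promoter exactly when every
    consensus string occupies its stated position (a single mismatched base
    anywhere breaks the call).  Filters are one-hot copies of each
    consensus and the dense layer reads them out at the planted positions
    with an all-must-match threshold.

    This is a diagnostic device with known ground truth — it exercises the
    ordinary forward pass, so substitution profiles and score contracts can
    be checked against exact expectations.
    """
    if not motifs:
        raise ConfigurationError("at least one (consensus, start) pair is required")
    alpha = 2.0
    max_w = max(len(consensus) for consensus, _ in motifs)
    spec = ModelSpec(
        input_length=input_length,
        conv_layers=(ConvLayerSpec(len(motifs), max_w, 0),),
        dense_units=1,
    )
    out_len = input_length - max_w + 1
    from .sequence_io import ALPHABET

    conv_w = np.zeros((len(motifs), max_w, INPUT_DEPTH))
    dense_w = np.zeros((out_len * len(motifs), 1))
    total = 0.0
    for m, (consensus, start) in enumerate(motifs):
        consensus = consensus.upper()
        pos0 = start - 1
        if pos0 < 0 or pos0 >= out_len or pos0 + len(consensus) > input_length:
            raise ConfigurationError(
                f"motif {consensus!r} at start {start} does not fit the "
                f"{input_length}-nt window (filter span {max_w})"
            )
        for i, base in enumerate(consensus):
            if base not in ALPHABET:
                raise ConfigurationError(f"consensus base {base!r} not in {ALPHABET}")
            conv_w[m, i, ALPHABET.index(base)] = alpha
        dense_w[pos0 * len(motifs) + m, 0] = 1.0
        total += alpha * len(consensus)
    params = ModelParameters(
        spec=spec,
        conv_weights=[conv_w],
        conv_biases=[np.zeros(len(motifs))],
        dense_w=dense_w,
        dense_b=np.array([-(total - alpha / 2.0)]),
        out_w=np.array([[gain, -gain]]),
        out_b=np.zeros(2),
        metadata={
            "architecture": spec.architecture_string(),
            "input_length": input_length,
            "dense_units": 1,
            "construction": "positional-motif-conjunction",
            "motifs": [[c, int(s)] for c, s in motifs],
        },
    )
    return params


# ---------------------------------------------------------------------------
# Model files: a zip archive holding a JSON header plus raw .npy arrays.

def save_model(params: ModelParameters, path: str | Path) -> None:
    arrays = {}
    for i, (w, b) in enumerate(zip(params.conv_weights, params.conv_biases)):
        arrays[f"conv{i}_w"] = w
        arrays[f"conv{i}_b"] = b
    arrays["dense_w"] = params.dense_w
    arrays["dense_b"] = params.dense_b
    arrays["out_w"] = params.out_w
    arrays["out_b"] = params.out_b
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "architecture": params.spec.architecture_string(),
        "input_length": params.spec.input_length,
        "dense_units": params.spec.dense_units,
        "metadata": params.metadata,
        "arrays": sorted(arrays),
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1, sort_keys=True))
        for name, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arr))
            zf.writestr(name + ".npy", buf.getvalue())


def load_model(path: str | Path) -> ModelParameters:
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            if header.get("format_version") != MODEL_FORMAT_VERSION:
                raise ModelIOError(
                    f"{path}: unsupported model format version "
                    f"{header.get('format_version')!r} (expected {MODEL_FORMAT_VERSION})"
                )
            arrays = {}
            for name in header["arrays"]:
                arrays[name] = np.load(io.BytesIO(zf.read(name + ".npy")))
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError, ValueError) as exc:
        raise ModelIOError(f"{path}: cannot read model file ({exc})") from exc
    spec = parse_architecture(
        header["architecture"], header["input_length"], dense_units=header["dense_units"]
    )
    n_conv = len(spec.conv_layers)
    try:
        params = ModelParameters(
            spec=spec,
            conv_weights=[arrays[f"conv{i}_w"] for i in range(n_conv)],
            conv_biases=[arrays[f"conv{i}_b"] for i in range(n_conv)],
            dense_w=arrays["dense_w"],
            dense_b=arrays["dense_b"],
            out_w=arrays["out_w"],
            out_b=arrays["out_b"],
            metadata=header.get("metadata", {}),
        )
    except KeyError as exc:
        raise ModelIOError(f"{path}: model file missing array {exc}") from None
    # shape audit against the declared spec
    depth = INPUT_DEPTH
    for i, layer in enumerate(spec.conv_layers):
        expect = (layer.n_filters, layer.filter_length, depth)
        if params.conv_weights[i].shape != expect:
            raise ModelIOError(
                f"{path}: conv layer {i + 1} weights have shape "
                f"{params.conv_weights[i].shape}, expected {expect}"
            )
        depth = layer.n_filters
    if params.dense_w.shape != (spec.flattened_size(), spec.dense_units):
        raise ModelIOError(f"{path}: dense weights shape mismatch")
    return params
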