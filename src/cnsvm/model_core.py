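"""The 1D-Inception backbone: configuration, construction, parameter
accounting and feature extraction.

The classifier takes a window-cropped reflectance spectrum (94 channels by
default), passes it through a stack of 1D inception modules — parallel 1x1 /
1x3 / 1x5 convolutions plus a 3-wide max-pool branch projected by a 1x1
convolution, all same-padded with stride 1, batch-normalised before
activation — concatenates and flattens, then applies a dense head with
dropout before each layer and a single sigmoid output neuron.  The
activations of the last dense layer (50 wide in the reference model) are the
feature map handed to the SVM head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cnsvm.errors import ConfigError, ShapeError
from cnsvm.nnet import (
    Activation,
    Dense,
    Dropout,
    Flatten,
    InceptionModule,
    Network,
    stable_sigmoid,
)
from cnsvm.spectra_io import SignatureSet


def relu(x):
    """Rectified linear unit, max(0, x), elementwise."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def swish(x):
    """Self-gated activation x * sigmoid(x), elementwise and stable for
    large |x|."""
    x = np.asarray(x, dtype=float)
    return x * stable_sigmoid(x)


def lecun_normal_sd(fan_in: int) -> float:
    """Standard deviation sqrt(1/fan_in) of the (truncated) LeCun normal
    weight initialiser."""
    if fan_in < 1:
        raise ConfigError(f"fan_in must be >= 1, got {fan_in}")
    return float(np.sqrt(1.0 / fan_in))


@dataclass(frozen=True)
class InceptionConfig:
    """Per-branch filter counts of one inception module."""

    f1: int
    f3: int
    f5: int
    fp: int

    def __post_init__(self) -> None:
        for name in ("f1", "f3", "f5", "fp"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")

    @property
    def out_channels(self) -> int:
        """Channels after concatenating the four branches."""
        return self.f1 + self.f3 + self.f5 + self.fp


@dataclass(frozen=True)
class NetworkConfig:
    """Complete backbone description, sufficient to count parameters
    deterministically.

    ``dense_widths`` must shrink, but no dense layer may drop below half its
    dense predecessor ("aggressive reduction" with a floor) — the reference
    stack 200/150/100/50 satisfies this.
    """

    input_len: int = 94
    modules: tuple[InceptionConfig, ...] = ()
    dense_widths: tuple[int, ...] = ()
    dropout_rates: tuple[float, ...] = ()
    activation: str = "relu"
    l2_coef: float = 1e-4
    initializer: str = "lecun_normal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(self.modules))
        object.__setattr__(self, "dense_widths", tuple(self.dense_widths))
        object.__setattr__(self, "dropout_rates", tuple(self.dropout_rates))
        if self.input_len < 1:
            raise ConfigError("input_len must be >= 1")
        if len(self.dropout_rates) != len(self.dense_widths):
            raise ConfigError("need one dropout rate per dense layer")
        if any(not 0.0 <= p < 1.0 for p in self.dropout_rates):
            raise ConfigError("dropout rates must lie in [0, 1)")
        if self.l2_coef < 0:
            raise ConfigError("l2_coef must be >= 0")
        if self.activation not in ("relu", "swish"):
            raise ConfigError(f"activation must be relu or swish, got {self.activation!r}")
        if self.initializer != "lecun_normal":
            raise ConfigError(f"unsupported initializer {self.initializer!r}")
        for prev, width in zip(self.dense_widths, self.dense_widths[1:]):
            if width > prev:
                raise ConfigError(
                    f"dense widths must not grow ({prev} -> {width})"
                )
            if width < prev / 2:
                raise ConfigError(
                    f"dense layer of width {width} is less than half its "
                    f"predecessor ({prev}); the reduction floor is half"
                )

    @property
    def feature_dim(self) -> int:
        """Width of the feature map fed to the SVM head: the last dense
        layer, or the flattened convolutional output if no dense head."""
        if self.dense_widths:
            return self.dense_widths[-1]
        channels = self.modules[-1].out_channels if self.modules else 1
        return self.input_len * channels


def reference_config() -> NetworkConfig:
    """The published architecture: two inception modules feeding a
    200/150/100/50 dense head, ~4.9 million trainable parameters."""
    return NetworkConfig(
        input_len=94,
        modules=(InceptionConfig(16, 32, 8, 8), InceptionConfig(64, 128, 32, 32)),
        dense_widths=(200, 150, 100, 50),
        dropout_rates=(0.54, 0.33, 0.10, 0.46),
        activation="relu",
        l2_coef=1e-4,
    )


def compact_config(activation: str = "relu") -> NetworkConfig:
    """Small single-module backbone for quick experiments and tests."""
    return NetworkConfig(
        input_len=94,
        modules=(InceptionConfig(8, 16, 4, 4),),
        dense_widths=(64, 32),
        dropout_rates=(0.2, 0.2),
        activation=activation,
        l2_coef=1e-4,
    )


@dataclass
class ModelHandle:
    """A built (possibly trained) backbone plus the standardisation
    statistics learned from the training partition."""

    config: NetworkConfig
    network: Network = field(repr=False)
    feature_dim: int
    seed: int = 0
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None

    @property
    def is_standardized(self) -> bool:
        return self.scaler_mean is not None


def build_model(cfg: NetworkConfig, seed: int = 0) -> ModelHandle:
    """Instantiate the backbone with seeded truncated-LeCun-normal weights."""
    rng = np.random.default_rng(seed)
    layers = []
    in_channels = 1
    for module in cfg.modules:
        layers.append(
            InceptionModule(
                in_channels, module.f1, module.f3, module.f5, module.fp,
                cfg.activation, rng,
            )
        )
        in_channels = module.out_channels
    layers.append(Flatten())
    width = cfg.input_len * in_channels
    for p, neurons in zip(cfg.dropout_rates, cfg.dense_widths):
        layers.append(Dropout(p))
        layers.append(Dense(width, neurons, rng))
        layers.append(Activation(cfg.activation))
        width = neurons
    output = Dense(width, 1, rng)
    network = Network(layers, output)
    return ModelHandle(config=cfg, network=network, feature_dim=cfg.feature_dim, seed=seed)


def count_parameters(cfg: NetworkConfig) -> int:
    """Exact trainable-parameter count, computed analytically.

    Counts convolution kernels and biases, batch-norm scale/shift, dense
    weights and biases, and the sigmoid output neuron; running batch-norm
    statistics are not trainable.  Agrees with enumerating the weight arrays
    of :func:`build_model`'s network.
    """
    total = 0
    in_channels = 1
    for module in cfg.modules:
        for kernel, filters in ((1, module.f1), (3, module.f3), (5, module.f5), (1, module.fp)):
            total += kernel * in_channels * filters + filters
        total += 2 * module.out_channels  # batch-norm scale + shift
        in_channels = module.out_channels
    width = cfg.input_len * in_channels
    for neurons in cfg.dense_widths:
        total += width * neurons + neurons
        width = neurons
    total += width * 1 + 1  # sigmoid output neuron
    return total


def _as_matrix(s) -> np.ndarray:
    if isinstance(s, SignatureSet):
        return s.reflectance
    return np.asarray(s, dtype=float)


def standardize_inputs(m: ModelHandle, x: np.ndarray) -> np.ndarray:
    """Apply the handle's stored per-channel z-scoring (identity if the
    model was trained on raw percent reflectance)."""
    if m.scaler_mean is None:
        return x
    return (x - m.scaler_mean) / m.scaler_sd


def _prepare(m: ModelHandle, s) -> np.ndarray:
    x = _as_matrix(s)
    if x.ndim != 2 or x.shape[1] != m.config.input_len:
        raise ShapeError(
            f"expected signatures of length {m.config.input_len}, "
            f"got array of shape {x.shape}"
        )
    return standardize_inputs(m, x)[:, :, None]


def extract_features(m: ModelHandle, s) -> np.ndarray:
    """Penultimate-layer activations (post-activation, pre-sigmoid), one row
    per signature.  Dropout off, batch norm in inference mode."""
    x = _prepare(m, s)
    return m.network.forward_features(x, training=False)


def forward_proba(m: ModelHandle, s) -> np.ndarray:
    """Sigmoid output of the backbone, one probability per signature."""
    x = _prepare(m, s)
    return stable_sigmoid(m.network.forward_logits(x, training=False))
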