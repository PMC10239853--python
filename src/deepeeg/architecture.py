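"""The fixed 24-layer 1D convolutional architecture and its shape algebra.

The feature extractor is a five-block convolutional stack over a raw
single-channel epoch: each block is Conv1D (valid padding, stride 1) ->
BatchNorm (channel axis, momentum 0.9) -> ReLU -> MaxPool1D (valid).
Filters run 32/64/128/256/128 with kernels 3/5/13/17/9 and pool sizes
2/4/4/2/2, followed by Flatten -> Dense(64, ReLU, L2 = 0.03) ->
Dropout(0.4) -> Dense(n_classes, softmax).  For a 4,097-sample input the
last pooling layer emits a 23x128 feature map (2,944 values flattened),
which is the tap point for deep-feature extraction.

Everything here is static arithmetic: output shapes follow the valid
convolution/pooling rule ``floor((L - window) / stride) + 1`` and
parameter counts include BatchNorm's four per-channel statistics (scale,
shift, moving mean, moving variance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

LayerKind = Literal[
    "conv1d", "batchnorm", "activation", "maxpool1d", "flatten", "dense", "dropout"
]


class ArchitectureError(ValueError):
    """The architecture is invalid for the requested input length."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the network; only the fields relevant to its kind are set."""

    kind: LayerKind
    name: str = ""
    filters: int = 0
    kernel_size: int = 0
    stride: int = 1
    padding: str = "valid"
    momentum: float = 0.9
    pool_size: int = 0
    units: int = 0
    activation: str = ""
    l2: float = 0.0
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.padding != "valid":
            raise ArchitectureError("only valid padding is supported")
        if self.kind == "dropout" and not (0 <= self.rate < 1):
            raise ArchitectureError("dropout rate must be in [0, 1)")
        if self.kind == "conv1d" and (self.kernel_size < 1 or self.stride < 1):
            raise ArchitectureError("conv kernel and stride must be >= 1")
        if self.kind == "maxpool1d" and (self.pool_size < 1 or self.stride < 1):
            raise ArchitectureError("pool size and stride must be >= 1")


def layer_output_shape(
    in_shape: tuple[int, ...], layer: LayerSpec
) -> tuple[int, ...]:
    """Shape transform of one layer under valid padding.

    ``in_shape`` is (length, channels) before flatten and (features,)
    after.  Raises :class:`ArchitectureError` when a window exceeds the
    temporal length.
    """
    if layer.kind == "conv1d":
        length, _ = in_shape
        if layer.kernel_size > length:
            raise ArchitectureError(
                f"{layer.name or 'conv1d'}: kernel {layer.kernel_size} exceeds "
                f"input length {length}"
            )
        out_len = (length - layer.kernel_size) // layer.stride + 1
        return (out_len, layer.filters)
    if layer.kind == "maxpool1d":
        length, channels = in_shape
        if layer.pool_size > length:
            raise ArchitectureError(
                f"{layer.name or 'maxpool1d'}: pool {layer.pool_size} exceeds "
                f"input length {length}"
            )
        out_len = (length - layer.pool_size) // layer.stride + 1
        return (out_len, channels)
    if layer.kind == "flatten":
        length, channels = in_shape
        return (length * channels,)
    if layer.kind == "dense":
        return (layer.units,)
    # batchnorm / activation / dropout are shape-preserving
    return in_shape


def layer_param_count(layer: LayerSpec, in_shape: tuple[int, ...]) -> int:
    """Parameter count of one layer, counting BatchNorm's moving statistics."""
    if layer.kind == "conv1d":
        in_channels = in_shape[1]
        return layer.kernel_size * in_channels * layer.filters + layer.filters
    if layer.kind == "batchnorm":
        channels = in_shape[-1]
        return 4 * channels
    if layer.kind == "dense":
        return in_shape[0] * layer.units + layer.units
    return 0


def _conv_block(
    index: int, filters: int, kernel: int, pool: int, pool_stride: int
) -> list[LayerSpec]:
    return [
        LayerSpec(kind="conv1d", name=f"conv1d_{index}", filters=filters,
                  kernel_size=kernel),
        LayerSpec(kind="batchnorm", name=f"batchnorm_{index}"),
        LayerSpec(kind="activation", name=f"relu_{index}", activation="relu"),
        LayerSpec(kind="maxpool1d", name=f"maxpool1d_{index}", pool_size=pool,
                  stride=pool_stride),
    ]


@dataclass(frozen=True)
class ArchitectureSpec:
    """The ordered layer list plus input geometry and head size."""

    layers: tuple[LayerSpec, ...]
    input_length: int
    n_classes: int
    input_channels: int = 1

    @property
    def feature_tap_index(self) -> int:
        """Index of the last pooling layer — the deep-feature export point."""
        return max(i for i, l in enumerate(self.layers) if l.kind == "maxpool1d")

    def shape_chain(self) -> list[tuple[int, ...]]:
        """Output shape after every layer; raises if any length collapses below 1."""
        shape: tuple[int, ...] = (self.input_length, self.input_channels)
        chain = []
        for layer in self.layers:
            shape = layer_output_shape(shape, layer)
            if shape[0] < 1:
                raise ArchitectureError(
                    f"{layer.name}: output length {shape[0]} < 1"
                )
            chain.append(shape)
        return chain

    def feature_map_shape(self) -> tuple[int, int]:
        """(T, C) shape of the exported feature map at the tap layer."""
        return self.shape_chain()[self.feature_tap_index]  # type: ignore[return-value]

    def param_counts(self) -> list[int]:
        shape: tuple[int, ...] = (self.input_length, self.input_channels)
        counts = []
        for layer in self.layers:
            counts.append(layer_param_count(layer, shape))
            shape = layer_output_shape(shape, layer)
        return counts

    @property
    def total_params(self) -> int:
        return sum(self.param_counts())


#: (filters, kernel) per conv block and (pool, stride) per pooling layer.
CONV_BLOCKS = ((32, 3), (64, 5), (128, 13), (256, 17), (128, 9))
POOLS = ((2, 2), (4, 4), (4, 4), (2, 2), (2, 2))
DENSE_UNITS = 64
DENSE_L2 = 0.03
DROPOUT_RATE = 0.4


def build_architecture(input_length: int, n_classes: int) -> ArchitectureSpec:
    """Build the fixed 24-layer architecture and validate its shape chain.

    Raises :class:`ArchitectureError` naming the first offending layer when
    the input is too short for the kernel/pool cascade (the canonical
    geometry requires lengths comparable to 4,097 samples; 1,024-sample
    epochs must be zero-padded first, see
    :func:`deepeeg.data.pad_records`, or use
    :func:`build_scaled_architecture`).
    """
    if input_length < 1:
        raise ArchitectureError("input_length must be >= 1")
    if n_classes < 2:
        raise ArchitectureError("n_classes must be >= 2")
    layers: list[LayerSpec] = []
    for i, ((filters, kernel), (pool, stride)) in enumerate(
        zip(CONV_BLOCKS, POOLS), start=1
    ):
        layers.extend(_conv_block(i, filters, kernel, pool, stride))
    layers.append(LayerSpec(kind="flatten", name="flatten"))
    layers.append(
        LayerSpec(kind="dense", name="dense_1", units=DENSE_UNITS,
                  activation="relu", l2=DENSE_L2)
    )
    layers.append(LayerSpec(kind="dropout", name="dropout", rate=DROPOUT_RATE))
    layers.append(
        LayerSpec(kind="dense", name="dense_out", units=n_classes,
                  activation="softmax")
    )
    arch = ArchitectureSpec(
        layers=tuple(layers), input_length=input_length, n_classes=n_classes
    )
    arch.shape_chain()  # validates; raises naming the offending layer
    return arch


def build_scaled_architecture(input_length: int, n_classes: int) -> ArchitectureSpec:
    """Same block structure with kernels/pools shrunk for short epochs.

    Kernels and pool windows are scaled by ``input_length / 4097``
    (floored, minimum kernel 2 / pool 2 where the original pools by 2,
    etc. — pool strides equal pool sizes).  Filter counts and the dense
    head are unchanged.  Intended for quick experiments and for running
    short epochs without zero-padding; the canonical geometry is
    :func:`build_architecture`.
    """
    if n_classes < 2:
        raise ArchitectureError("n_classes must be >= 2")
    factor = input_length / 4097.0
    layers: list[LayerSpec] = []
    for i, ((filters, kernel), (pool, _)) in enumerate(
        zip(CONV_BLOCKS, POOLS), start=1
    ):
        k = max(2, int(round(kernel * factor)))
        layers.extend(_conv_block(i, filters, k, pool, pool))
    layers.append(LayerSpec(kind="flatten", name="flatten"))
    layers.append(
        LayerSpec(kind="dense", name="dense_1", units=DENSE_UNITS,
                  activation="relu", l2=DENSE_L2)
    )
    layers.append(LayerSpec(kind="dropout", name="dropout", rate=DROPOUT_RATE))
    layers.append(
        LayerSpec(kind="dense", name="dense_out", units=n_classes,
                  activation="softmax")
    )
    arch = ArchitectureSpec(
        layers=tuple(layers), input_length=input_length, n_classes=n_classes
    )
    arch.shape_chain()
    return arch


_DISPLAY_NAMES = {
    "conv1d": "1D Convolution",
    "batchnorm": "BatchNorm",
    "activation": "Activation",
    "maxpool1d": "1D MaxPooling",
    "flatten": "Flatten",
    "dense": "Dense",
    "dropout": "Dropout",
}


def summarize(arch: ArchitectureSpec) -> pd.DataFrame:
    """Layer-by-layer summary: name, output shape, parameter count.

    Shapes before flatten are printed ``(L,C)``; from flatten on, a bare
    feature count.
    """
    chain = arch.shape_chain()
    counts = arch.param_counts()
    rows = []
    for i, (layer, shape, count) in enumerate(zip(arch.layers, chain, counts), 1):
        shape_str = f"({shape[0]},{shape[1]})" if len(shape) == 2 else str(shape[0])
        rows.append(
            {
                "no": i,
                "layer_name": _DISPLAY_NAMES[layer.kind],
                "output_shape": shape_str,
                "n_params": count,
            }
        )
    return pd.DataFrame(rows)
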