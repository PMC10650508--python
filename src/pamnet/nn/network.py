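"""Declarative assembly of the 3D reconstruction network.

The network maps a single-channel RF tensor (time, 16, 16) to a cubic
intensity-root volume.  Its body alternates dense blocks (two equal-width
(9,3,3) convolutions with batch normalization and additive skips, dilated
along the time axis) with strided convolutions that halve the time axis, a
transposed convolution that upsamples 16 -> 48 laterally, and two final
valid-padded cubic convolutions that bring every axis to the output size.
All bare kernel sizes in the layer table are cubic 3D kernels; this is the
only reading under which the full-size network reproduces its published
parameter budget exactly.

After the last tabulated convolution an additional single-filter 1x1x1
projection collapses the channel axis to emit a scalar volume, followed by
per-sample max normalization.  The projection is part of the output head:
it is counted in the parameter total but not among the network's
convolutional layers proper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (
    BatchNorm3d,
    Conv3d,
    ConvTranspose3d,
    DenseBlock,
    Layer,
    MaxNorm,
    Parameter,
    ReLU,
)

__all__ = [
    "LayerRow",
    "NetworkSpec",
    "ReconstructionNetwork",
    "build_network",
    "count_parameters",
    "count_convolution_layers",
    "full_network_spec",
    "desk_network_spec",
    "predict",
]


@dataclass(frozen=True)
class LayerRow:
    """One row of the architecture table.

    kind: 'conv' | 'tconv' | 'dense'
    expected_out: (channels, D, H, W) the row must produce, used to validate
    the assembled model against the declared shape ledger.
    """

    kind: str
    out_channels: int
    kernel: tuple[int, int, int]
    expected_out: tuple[int, int, int, int]
    stride: tuple[int, int, int] = (1, 1, 1)
    dilation: tuple[int, int, int] = (1, 1, 1)
    padding: str = "same"
    out_size: tuple[int, int, int] | None = None  # tconv target size


@dataclass(frozen=True)
class NetworkSpec:
    """Input geometry plus the ordered layer rows and output head flags."""

    input_shape: tuple[int, int, int]  # (time, 16, 16)
    rows: tuple[LayerRow, ...]
    channel_projection: bool = True

    @property
    def output_shape(self) -> tuple[int, int, int]:
        return self.rows[-1].expected_out[1:]


class ShapeMismatchError(ValueError):
    """A row's realized output shape deviates from the declared ledger."""


def full_network_spec(input_length: int = 1521) -> NetworkSpec:
    """The full-size architecture: (input_length, 16, 16) -> (41, 41, 41).

    The default input length of 1521 samples is a configuration constant of
    the 612 kHz acquisition; other lengths compatible with five halvings of
    the time axis down to 48 are not supported by the fixed final layers and
    will fail shape validation.
    """
    t = input_length
    t1, t2, t3 = -(-t // 2), -(-t // 4), -(-t // 8)
    t4, t5 = -(-t // 16), -(-t // 32)
    rows = (
        LayerRow("conv", 2, (9, 9, 9), (2, t, 16, 16)),
        LayerRow("dense", 2, (9, 3, 3), (2, t, 16, 16), dilation=(1, 1, 1)),
        LayerRow("conv", 4, (9, 9, 9), (4, t1, 16, 16), stride=(2, 1, 1)),
        LayerRow("dense", 4, (9, 3, 3), (4, t1, 16, 16), dilation=(2, 1, 1)),
        LayerRow("conv", 8, (9, 9, 9), (8, t2, 16, 16), stride=(2, 1, 1)),
        LayerRow("dense", 8, (9, 3, 3), (8, t2, 16, 16), dilation=(4, 1, 1)),
        LayerRow("conv", 8, (5, 5, 5), (8, t3, 16, 16), stride=(2, 1, 1)),
        LayerRow("tconv", 8, (6, 6, 6), (8, t3, 48, 48), stride=(1, 3, 3),
                 out_size=(t3, 48, 48)),
        LayerRow("dense", 8, (9, 3, 3), (8, t3, 48, 48), dilation=(4, 1, 1)),
        LayerRow("conv", 8, (5, 5, 5), (8, t4, 48, 48), stride=(2, 1, 1)),
        LayerRow("dense", 8, (9, 3, 3), (8, t4, 48, 48), dilation=(4, 1, 1)),
        LayerRow("conv", 8, (8, 8, 8), (8, t5, 48, 48), stride=(2, 1, 1)),
        LayerRow("dense", 8, (9, 3, 3), (8, t5, 48, 48), dilation=(4, 1, 1)),
        LayerRow("conv", 8, (5, 5, 5), (8, t5 - 4, 44, 44), padding="valid"),
        LayerRow("conv", 8, (4, 4, 4), (8, t5 - 7, 41, 41), padding="valid"),
    )
    return NetworkSpec(input_shape=(t, 16, 16), rows=rows)


def desk_network_spec(input_length: int = 168) -> NetworkSpec:
    """Width-reduced desk-scale architecture: (input_length, 16, 16) -> (21, 21, 21).

    Three stride-2 stages bring the time axis to 21; a full-padded
    transposed convolution (kernel (1, 8, 8), stride 1) upsamples the
    lateral axes 16 -> 21; two dense blocks refine the volume.
    """
    t = input_length
    t1, t2, t3 = -(-t // 2), -(-t // 4), -(-t // 8)
    rows = (
        LayerRow("conv", 2, (5, 3, 3), (2, t, 16, 16)),
        LayerRow("dense", 2, (5, 3, 3), (2, t, 16, 16), dilation=(1, 1, 1)),
        LayerRow("conv", 4, (5, 1, 1), (4, t1, 16, 16), stride=(2, 1, 1)),
        LayerRow("dense", 4, (5, 3, 3), (4, t1, 16, 16), dilation=(2, 1, 1)),
        LayerRow("conv", 4, (5, 1, 1), (4, t2, 16, 16), stride=(2, 1, 1)),
        LayerRow("dense", 4, (5, 3, 3), (4, t2, 16, 16), dilation=(2, 1, 1)),
        LayerRow("conv", 8, (5, 1, 1), (8, t3, 16, 16), stride=(2, 1, 1)),
        LayerRow("tconv", 8, (1, 8, 8), (8, t3, 21, 21), stride=(1, 1, 1),
                 out_size=(t3, 21, 21)),
        LayerRow("dense", 8, (3, 3, 3), (8, t3, 21, 21), dilation=(1, 1, 1)),
        LayerRow("dense", 8, (3, 3, 3), (8, t3, 21, 21), dilation=(1, 1, 1)),
    )
    return NetworkSpec(input_shape=(t, 16, 16), rows=rows)


class ReconstructionNetwork:
    """Sequential model assembled from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.blocks: list[tuple[str, Layer, Layer | None]] = []  # (kind, layer, activation)
        shape = (1, *spec.input_shape)
        for i, row in enumerate(spec.rows):
            layer = self._make_layer(row, shape[0], rng)
            try:
                out = layer.output_shape(shape)
            except ValueError as exc:
                raise ShapeMismatchError(f"row {i} ({row.kind}): {exc}") from exc
            if out != row.expected_out:
                raise ShapeMismatchError(
                    f"row {i} ({row.kind}) produces {out}, table declares {row.expected_out}"
                )
            act = None if row.kind == "dense" else ReLU()  # dense blocks end in ReLU already
            self.blocks.append((row.kind, layer, act))
            shape = out
        if spec.channel_projection:
            proj = Conv3d(shape[0], 1, (1, 1, 1), rng=rng)
            self.blocks.append(("proj", proj, None))  # final layer: no activation
            shape = (1, *shape[1:])
        self.maxnorm = MaxNorm()
        self.output_shape = shape

    @staticmethod
    def _make_layer(row: LayerRow, in_channels: int, rng) -> Layer:
        if row.kind == "conv":
            return Conv3d(in_channels, row.out_channels, row.kernel,
                          stride=row.stride, dilation=row.dilation,
                          padding=row.padding, rng=rng)
        if row.kind == "tconv":
            return ConvTranspose3d(in_channels, row.out_channels, row.kernel,
                                   stride=row.stride, out_size=row.out_size, rng=rng)
        if row.kind == "dense":
            if row.out_channels != in_channels:
                raise ShapeMismatchError(
                    "dense blocks use additive skips and need equal in/out channels"
                )
            return DenseBlock(in_channels, row.kernel, row.dilation, rng=rng)
        raise ValueError(f"unknown layer kind {row.kind!r}")

    # ---- inference / training API -------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                collect_shapes: list | None = None) -> np.ndarray:
        """x: (B, time, 16, 16) -> (B, *output volume), max-normalized."""
        h = np.asarray(x, dtype=np.float32)[:, None]  # add channel axis
        for kind, layer, act in self.blocks:
            h = layer.forward(h, training)
            if act is not None:
                h = act.forward(h, training)
            if collect_shapes is not None:
                collect_shapes.append(h.shape[1:])
        h = self.maxnorm.forward(h, training)
        return h[:, 0]

    def backward(self, grad: np.ndarray) -> None:
        g = np.asarray(grad, dtype=np.float32)[:, None]
        g = self.maxnorm.backward(g)
        for kind, layer, act in reversed(self.blocks):
            if act is not None:
                g = act.backward(g)
            g = layer.backward(g)

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for _, layer, _ in self.blocks:
            out.extend(layer.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters()]
        for bn in self._batch_norms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state[: len(params)]):
            p.value[...] = v
        rest = state[len(params):]
        for bn, (m, v) in zip(self._batch_norms(), zip(rest[0::2], rest[1::2])):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def _batch_norms(self):
        for _, layer, _ in self.blocks:
            if isinstance(layer, BatchNorm3d):
                yield layer
            elif isinstance(layer, DenseBlock):
                yield layer.bn1
                yield layer.bn2

    # ---- introspection -------------------------------------------------

    def convolution_layers(self) -> list[Layer]:
        """The network's convolutional layers: standalone convs, the
        transposed conv, and both convs of every dense block.  The 1x1x1
        channel-collapse projection belongs to the output head and is not
        included."""
        out = []
        for kind, layer, _ in self.blocks:
            if kind in ("conv", "tconv"):
                out.append(layer)
            elif kind == "dense":
                out.extend(layer.convolutions)
        return out

    def shape_ledger(self) -> list[tuple[int, int, int, int]]:
        """Declared (C, D, H, W) after every tabulated row."""
        return [row.expected_out for row in self.spec.rows]


def build_network(spec: NetworkSpec, seed: int = 0) -> ReconstructionNetwork:
    """Assemble and shape-validate the reconstruction network."""
    return ReconstructionNetwork(spec, seed=seed)


def count_parameters(model: ReconstructionNetwork) -> int:
    """Total trainable scalars (conv weights/biases and BN scale/offset)."""
    return int(sum(p.size for p in model.parameters()))


def count_convolution_layers(model: ReconstructionNetwork) -> int:
    """Convolution-type layers (standard plus transposed), including the two
    inside every dense block; the scalar output projection is excluded."""
    return len(model.convolution_layers())


def predict(model: ReconstructionNetwork, rf_batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode reconstruction of a batch of RF tensors.

    Outputs are max-normalized per volume; an all-nonpositive output is
    returned unscaled with a warning.
    """
    import warnings

    rf_batch = np.asarray(rf_batch, dtype=np.float32)
    if rf_batch.ndim == 3:
        rf_batch = rf_batch[None]
    if rf_batch.shape[1:] != model.spec.input_shape:
        raise ValueError(
            f"expected input shape {model.spec.input_shape}, got {rf_batch.shape[1:]}"
        )
    out = model.forward(rf_batch, training=False)
    if np.any(out.reshape(out.shape[0], -1).max(axis=1) <= 0):
        warnings.warn("degenerate all-nonpositive network output left unnormalized")
    return out
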