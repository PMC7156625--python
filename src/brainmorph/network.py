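"""The morphometry CNN architecture and its exact arithmetic.

Six kernelled layers — three strided 3-D convolutions (boundary-preserving
padding, ReLU) interleaved with three unpadded max-poolings — followed by
three fully connected layers, mapping a 256³ T1-weighted volume to the
165-value morphometry vector:

====== ======== ====== ======= ================ ==========
layer  kernel   stride filters output (edge×ch) activation
====== ======== ====== ======= ================ ==========
conv   11³      3      144     86³ × 144        ReLU
pool   3³       2      —       42³ × 144        —
conv   5³       2      192     21³ × 192        ReLU
pool   3³       2      —       10³ × 192        —
conv   5³       1      192     10³ × 192        ReLU
pool   3³       2      —       4³  × 192        —
fc     —        —      374     374              ReLU
fc     —        —      192     192              —
fc     —        —      165     165              —
====== ======== ====== ======= ================ ==========

The padding convention is forced by the printed output sizes: 256→86 under
stride 3 requires ``ceil(n/s)`` (SAME-padded) convolutions, while 86→42 under
k=3, s=2 requires unpadded pooling.  The receptive field of a unit after the
last pooling layer is 209 voxels per axis.

Shape inference, receptive field and parameter counting are first-class
functions so the architecture bookkeeping is testable without instantiating
weights.  Note the plain per-layer parameter count of this table is
12,956,123 (about 64% convolutional); see docs/methods.md for a discussion
of the count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "default_spec",
    "desk_spec",
    "infer_shapes",
    "receptive_field",
    "count_parameters",
    "build_model",
]


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv3d | maxpool3d | fc
    kernel_edge: int = 0  # cubic kernel edge; 0 for fc
    stride: int = 1
    width: int = 0  # filters (conv) or units (fc); 0 for pool
    activation: str = "none"  # relu | none

    def __post_init__(self):
        if self.kind not in ("conv3d", "maxpool3d", "fc"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind != "fc" and self.kernel_edge < 1:
            raise ValueError("kernelled layers need kernel_edge >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_edge: int = 256
    input_channels: int = 1
    output_width: int = 165

    @property
    def kernelled(self) -> tuple[LayerSpec, ...]:
        return tuple(l for l in self.layers if l.kind != "fc")

    @property
    def fc_layers(self) -> tuple[LayerSpec, ...]:
        return tuple(l for l in self.layers if l.kind == "fc")


def default_spec(
    input_edge: int = 256,
    output_width: int = 165,
    filter_multiplier: float = 1.0,
) -> NetworkSpec:
    """The published architecture; ``filter_multiplier`` scales every conv
    filter bank and hidden FC width (1.0 reproduces the table exactly)."""

    def m(width: int) -> int:
        return max(1, round(width * filter_multiplier))

    layers = (
        LayerSpec("conv3d", 11, 3, m(144), "relu"),
        LayerSpec("maxpool3d", 3, 2),
        LayerSpec("conv3d", 5, 2, m(192), "relu"),
        LayerSpec("maxpool3d", 3, 2),
        LayerSpec("conv3d", 5, 1, m(192), "relu"),
        LayerSpec("maxpool3d", 3, 2),
        LayerSpec("fc", width=m(374), activation="relu"),
        LayerSpec("fc", width=m(192)),
        LayerSpec("fc", width=output_width),
    )
    return NetworkSpec(layers, input_edge=input_edge, output_width=output_width)


def desk_spec(
    input_edge: int = 48,
    output_width: int = 165,
    filter_multiplier: float = 0.25,
) -> NetworkSpec:
    """Scaled-down variant for CPU desk experiments.

    Keeps the convolution stack and kernel/stride pattern of the full
    architecture but drops any pooling layer that would collapse the feature
    map below 2³ (at small input edges the later poolings of the full chain
    would destroy the spatial layout — and with it the object-extent
    information a volume regression needs — or underflow to edge 0).
    """
    full = default_spec(input_edge, output_width, filter_multiplier)
    kept: list[LayerSpec] = []
    edge = input_edge
    for layer in full.kernelled:
        if layer.kind == "conv3d":
            kept.append(layer)
            edge = _nn.conv_same_out_edge(edge, layer.stride)
        else:
            if edge < layer.kernel_edge or _nn.pool_valid_out_edge(
                edge, layer.kernel_edge, layer.stride
            ) < 2:
                continue
            kept.append(layer)
            edge = _nn.pool_valid_out_edge(edge, layer.kernel_edge, layer.stride)
    return NetworkSpec(tuple(kept) + full.fc_layers, input_edge=input_edge,
                       output_width=output_width)


def infer_shapes(spec: NetworkSpec) -> list[tuple[int, int]]:
    """Per-kernelled-layer (spatial edge, channels) under the forced padding
    convention: SAME convs (ceil(n/s)), VALID pools (floor((n-k)/s)+1)."""
    edge = spec.input_edge
    channels = spec.input_channels
    out: list[tuple[int, int]] = []
    for layer in spec.kernelled:
        if layer.kind == "conv3d":
            edge = _nn.conv_same_out_edge(edge, layer.stride)
            channels = layer.width
        else:
            edge = _nn.pool_valid_out_edge(edge, layer.kernel_edge, layer.stride)
        if edge <= 0:
            raise ValueError(
                f"layer {layer.kind}(k={layer.kernel_edge}, s={layer.stride}) "
                f"collapses the spatial edge to {edge}"
            )
        out.append((edge, channels))
    return out


def receptive_field(spec: NetworkSpec) -> int:
    """Receptive-field edge of one unit after the last kernelled layer.

    Standard recurrence: rf ← rf + (k−1)·jump, jump ← jump·stride.
    """
    rf, jump = 1, 1
    for layer in spec.kernelled:
        rf += (layer.kernel_edge - 1) * jump
        jump *= layer.stride
    return rf


def count_parameters(spec: NetworkSpec) -> tuple[int, list[dict]]:
    """Trainable-parameter tally with a per-layer breakdown.

    conv: k³·c_in·c_out + c_out;  fc: n_in·n_out + n_out;  the flattened
    final feature map feeds the first FC.
    """
    breakdown: list[dict] = []
    channels = spec.input_channels
    shapes = infer_shapes(spec)
    for layer, (edge, ch) in zip(spec.kernelled, shapes):
        if layer.kind == "conv3d":
            n = layer.kernel_edge**3 * channels * layer.width + layer.width
            breakdown.append({"layer": f"conv{layer.kernel_edge}^3", "params": n,
                              "out_edge": edge, "channels": ch})
            channels = layer.width
        else:
            breakdown.append({"layer": f"pool{layer.kernel_edge}^3", "params": 0,
                              "out_edge": edge, "channels": ch})
    n_in = shapes[-1][0] ** 3 * channels if shapes else spec.input_edge**3
    for layer in spec.fc_layers:
        n = n_in * layer.width + layer.width
        breakdown.append({"layer": f"fc{layer.width}", "params": n,
                          "out_edge": 0, "channels": layer.width})
        n_in = layer.width
    return sum(b["params"] for b in breakdown), breakdown


def describe(spec: NetworkSpec) -> str:
    """Human-readable shape / receptive-field / parameter report."""
    total, breakdown = count_parameters(spec)
    lines = [f"input: {spec.input_edge}^3 x {spec.input_channels}"]
    for b in breakdown:
        shape = f"{b['out_edge']}^3 x {b['channels']}" if b["out_edge"] else f"{b['channels']}"
        lines.append(f"{b['layer']:>10}  out {shape:>12}  params {b['params']:>12,}")
    lines.append(f"receptive field: {receptive_field(spec)}")
    lines.append(f"total trainable parameters: {total:,}")
    return "\n".join(lines)


def build_model(
    spec: NetworkSpec,
    seed: int = 0,
    fc_init: str = "zero",
    dropout: float = 0.0,
) -> _nn.Sequential:
    """Instantiate a trainable model from a spec.

    Conv weights are Xavier-uniform under ``seed``; all biases are zero.  FC
    weights are zero by default, as published; ``fc_init="xavier"`` enables
    learning from scratch in desk-scale runs, and ``fc_init="xavier_zero_head"``
    uses Xavier hidden FC layers with a zero-initialized output layer, so the
    initial prediction is the output bias regardless of the activation scale
    reaching the head.  Dropout, when non-zero, is applied after each hidden
    FC layer.
    """
    rng = np.random.default_rng(seed)
    if fc_init not in ("zero", "xavier", "xavier_zero_head"):
        raise ValueError(f"unknown fc_init {fc_init!r}")
    layers: list[_nn.Layer] = []
    channels = spec.input_channels
    first_conv = True
    for layer in spec.kernelled:
        if layer.kind == "conv3d":
            layers.append(_nn.Conv3dSame(channels, layer.width, layer.kernel_edge,
                                         layer.stride, rng,
                                         needs_input_grad=not first_conv))
            first_conv = False
            if layer.activation == "relu":
                layers.append(_nn.ReLU())
            channels = layer.width
        else:
            layers.append(_nn.MaxPool3d(layer.kernel_edge, layer.stride))
    layers.append(_nn.Flatten())
    shapes = infer_shapes(spec)
    n_in = shapes[-1][0] ** 3 * channels if shapes else spec.input_edge**3
    fc = spec.fc_layers
    for i, layer in enumerate(fc):
        if fc_init == "xavier_zero_head":
            init = "zero" if i == len(fc) - 1 else "xavier"
        else:
            init = fc_init
        layers.append(_nn.Dense(n_in, layer.width, rng, init=init))
        if layer.activation == "relu":
            layers.append(_nn.ReLU())
        if dropout > 0 and i < len(fc) - 1:
            layers.append(_nn.Dropout(dropout, rng))
        n_in = layer.width
    model = _nn.Sequential(layers)
    model.spec = spec  # type: ignore[attr-defined]
    return model
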