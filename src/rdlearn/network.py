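"""Layered model construction and activation extraction.

A model is described by a ``ModelSpec``: an ordered list of block
descriptors (dicts).  Each block expands to one or more layer primitives
(e.g. a ``conv`` block is Conv2D -> BatchNorm? -> ReLU -> Dropout?), and the
block's *name* refers to the activation at the output of its last primitive
— i.e. after the nonlinearity — which is where auxiliary losses attach and
where activations are extracted for RDM computation.

Supported block kinds:

- ``conv``: kernel, features, stride, pad, nonlinearity, batch_norm, dropout
- ``max_pool`` / ``avg_pool``: kernel, stride, ceil_mode
- ``fc``: features, nonlinearity, dropout (input flattened automatically)
- ``linear_readout``: features (no nonlinearity)
- ``softmax_readout``: features, followed by a softmax

The special layer name ``"input"`` refers to the raw (flattened) pixels.
"""

from __future__ import annotations

import copy
import math
import warnings

import numpy as np

from .layers import (
    AvgPool2D,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    MaxPool2D,
    ReLU,
    Softmax,
)

__all__ = [
    "Network",
    "build_model",
    "extract_activations",
    "mnist_cnn_spec",
    "cifar_nin_spec",
    "toy_cnn_spec",
    "toy_mlp_spec",
    "ARCH_PRESETS",
]


class Network:
    """An ordered stack of layer primitives with named block outputs."""

    def __init__(self, primitives, block_end, spec, input_shape, softmax_output):
        self.primitives: list[Layer] = primitives
        self.block_end: dict[str, int] = block_end  # block name -> primitive index
        self.spec = spec
        self.input_shape = tuple(input_shape)
        self.softmax_output = softmax_output

    # -- shape plumbing -----------------------------------------------------
    def prepare_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        return X.reshape((n,) + self.input_shape)

    @property
    def block_names(self) -> list[str]:
        return list(self.block_end)

    # -- passes -------------------------------------------------------------
    def forward(self, x, train=False, rng=None, capture=()):
        """Run the network; returns (output, {block_name: activation}).

        ``capture`` names blocks whose outputs should be returned; the name
        ``"input"`` captures the raw input.
        """
        captured = {}
        if "input" in capture:
            captured["input"] = x
        end_to_name = {v: k for k, v in self.block_end.items() if k in set(capture)}
        for idx, layer in enumerate(self.primitives):
            x = layer.forward(x, train=train, rng=rng)
            if idx in end_to_name:
                captured[end_to_name[idx]] = x
        return x, captured

    def backward(self, dout, inject=None, start: int | None = None):
        """Backpropagate from primitive index ``start`` (default: last).

        ``inject`` maps block names to auxiliary gradient arrays that are
        added to the backpropagated gradient at that block's output before
        continuing downward.
        """
        inject = inject or {}
        end_to_grads = {}
        for name, g in inject.items():
            end_to_grads.setdefault(self.block_end[name], []).append(g)
        if start is None:
            start = len(self.primitives) - 1
        g = dout
        for idx in range(start, -1, -1):
            for extra in end_to_grads.get(idx, ()):
                g = g + extra
            g = self.primitives[idx].backward(g)
        return g

    def backward_from(self, block_name: str, grad):
        """Backpropagate an activation-space gradient from a named block down
        to the input (used by hint pretraining).  Requires a prior forward."""
        idx = self.block_end[block_name]
        g = grad
        for layer in reversed(self.primitives[: idx + 1]):
            g = layer.backward(g)
        return g

    def logits_start(self) -> int:
        """Index at which to start backward when the loss gradient is given
        with respect to logits (skips a trailing softmax primitive)."""
        last = len(self.primitives) - 1
        if self.softmax_output:
            return last - 1
        return last

    def zero_grads(self):
        for layer in self.primitives:
            layer.zero_grads()

    # -- parameter state ----------------------------------------------------
    def param_layers(self):
        return [p for p in self.primitives if p.params]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.primitives):
            for k, v in layer.params.items():
                state[f"param/{i}/{layer.name}/{k}"] = v.copy()
            for k, v in getattr(layer, "buffers", {}).items():
                state[f"buffer/{i}/{layer.name}/{k}"] = v.copy()
        return state

    def load_state_dict(self, state):
        for key, value in state.items():
            kind, idx, _, pname = key.split("/", 3)
            layer = self.primitives[int(idx)]
            target = layer.params if kind == "param" else layer.buffers
            if target[pname].shape != value.shape:
                raise ValueError(f"shape mismatch loading {key}")
            target[pname] = np.array(value, dtype=float)

    def copy(self) -> "Network":
        clone = build_model(self.spec, self.input_shape, seed=0)
        clone.load_state_dict(self.state_dict())
        return clone


def _block_defaults(block: dict) -> dict:
    b = dict(block)
    b.setdefault("stride", 1)
    b.setdefault("pad", 0)
    b.setdefault("nonlinearity", "relu")
    b.setdefault("batch_norm", False)
    b.setdefault("dropout", 0.0)
    b.setdefault("ceil_mode", False)
    return b


def build_model(spec, input_shape, seed: int = 0) -> "Network":
    """Instantiate a Network from a ModelSpec with deterministic, seeded
    fan-in-scaled uniform initialisation."""
    rng = np.random.default_rng(seed)
    spec = [
        _block_defaults(b) for b in copy.deepcopy(list(spec))
    ]
    input_shape = tuple(int(s) for s in input_shape)
    shape = input_shape
    primitives: list[Layer] = []
    block_end: dict[str, int] = {}
    softmax_output = False
    names = [b.get("name") for b in spec]
    if len(set(names)) != len(names) or None in names:
        raise ValueError("every block needs a unique 'name'")

    def add(layer):
        layer.init(rng)
        primitives.append(layer)

    for b in spec:
        kind, name = b["kind"], b["name"]
        if kind == "conv":
            if len(shape) != 3:
                raise ValueError(f"conv block {name!r} needs a spatial input")
            conv = Conv2D(name, shape[0], b["features"], b["kernel"],
                          stride=b["stride"], pad=b["pad"])
            new_shape = conv.out_shape(shape)
            if min(new_shape[1:]) < 1:
                raise ValueError(f"block {name!r} collapses spatial size: {new_shape}")
            add(conv)
            shape = new_shape
            if b["batch_norm"]:
                add(BatchNorm(f"{name}.bn", shape[0]))
            if b["nonlinearity"] == "relu":
                add(ReLU(f"{name}.relu"))
            if b["dropout"] > 0:
                add(Dropout(f"{name}.drop", b["dropout"]))
        elif kind in ("max_pool", "avg_pool"):
            cls = MaxPool2D if kind == "max_pool" else AvgPool2D
            pool = cls(name, b["kernel"], stride=b.get("stride") or b["kernel"],
                       ceil_mode=b["ceil_mode"])
            shape = pool.out_shape(shape)
            if min(shape[1:]) < 1:
                raise ValueError(f"block {name!r} collapses spatial size: {shape}")
            add(pool)
        elif kind in ("fc", "linear_readout", "softmax_readout"):
            if len(shape) > 1:
                add(Flatten(f"{name}.flatten"))
                shape = (int(np.prod(shape)),)
            add(Dense(name, shape[0], b["features"]))
            shape = (b["features"],)
            if kind == "fc" and b["nonlinearity"] == "relu":
                add(ReLU(f"{name}.relu"))
            if kind == "fc" and b["dropout"] > 0:
                add(Dropout(f"{name}.drop", b["dropout"]))
            if kind == "softmax_readout":
                add(Softmax(f"{name}.softmax"))
                softmax_output = True
        elif kind == "softmax":
            if len(shape) > 1:
                add(Flatten(f"{name}.flatten"))
                shape = (int(np.prod(shape)),)
            add(Softmax(name))
            softmax_output = True
        else:
            raise ValueError(f"unknown block kind {kind!r}")
        block_end[name] = len(primitives) - 1

    return Network(primitives, block_end, spec, input_shape, softmax_output)


def extract_activations(net: Network, X, layer_name: str) -> np.ndarray:
    """Activations at the output of a named block, flattened to n x K,
    computed in inference mode (dropout off, normalisation using running
    statistics)."""
    if layer_name != "input" and layer_name not in net.block_end:
        raise KeyError(
            f"unknown layer {layer_name!r}; available: {['input'] + net.block_names}"
        )
    x = net.prepare_input(X)
    if layer_name == "input":
        return x.reshape(x.shape[0], -1)
    _, captured = net.forward(x, train=False, capture=(layer_name,))
    act = captured[layer_name]
    return act.reshape(act.shape[0], -1)


# ---------------------------------------------------------------------------
# Architecture presets

def mnist_cnn_spec(n_classes: int = 10):
    """The 28x28 digit-classification CNN: two conv/max-pool stages, a
    dropout-regularised fully connected layer, and a linear softmax readout."""
    return [
        dict(kind="conv", name="conv1", features=32, kernel=5, stride=1),
        dict(kind="max_pool", name="pool1", kernel=3, stride=3),
        dict(kind="conv", name="conv2", features=64, kernel=5, stride=1),
        dict(kind="max_pool", name="pool2", kernel=2, stride=2),
        dict(kind="fc", name="fc1", features=200, dropout=0.5),
        dict(kind="softmax_readout", name="output", features=n_classes),
    ]


def cifar_nin_spec(n_classes: int = 100):
    """Network-in-Network for 32x32 colour images: three stages of a 5x5
    conv followed by two 1x1 MLPConv layers, batch-normalised, with dropout
    on the later 5x5 convs and a global average-pool readout."""
    bn = dict(batch_norm=True)
    return [
        dict(kind="conv", name="conv1", features=192, kernel=5, pad=2, **bn),
        dict(kind="conv", name="mlpconv1_1", features=160, kernel=1, **bn),
        dict(kind="conv", name="mlpconv1_2", features=96, kernel=1, **bn),
        dict(kind="max_pool", name="pool1", kernel=3, stride=2, ceil_mode=True),
        dict(kind="conv", name="conv2", features=192, kernel=5, pad=2, dropout=0.5, **bn),
        dict(kind="conv", name="mlpconv2_1", features=192, kernel=1, **bn),
        dict(kind="conv", name="mlpconv2_2", features=192, kernel=1, **bn),
        dict(kind="avg_pool", name="pool2", kernel=3, stride=2, ceil_mode=True),
        dict(kind="conv", name="conv3", features=192, kernel=5, pad=2, dropout=0.5, **bn),
        dict(kind="conv", name="mlpconv3_1", features=192, kernel=1, **bn),
        dict(kind="conv", name="mlpconv3_2", features=n_classes, kernel=1, **bn),
        dict(kind="avg_pool", name="pool3", kernel=8, stride=8),
        dict(kind="softmax", name="output"),
    ]


def toy_cnn_spec(n_classes: int = 5):
    """Desk-scale CNN for small synthetic images: conv -> max-pool -> fc ->
    softmax readout, with attachment-friendly named blocks."""
    return [
        dict(kind="conv", name="conv1", features=8, kernel=3, stride=1),
        dict(kind="max_pool", name="pool1", kernel=2, stride=2),
        dict(kind="fc", name="fc1", features=32),
        dict(kind="softmax_readout", name="output", features=n_classes),
    ]


def toy_mlp_spec(n_classes: int = 5):
    """Minimal fully connected model for unit tests."""
    return [
        dict(kind="fc", name="fc1", features=16),
        dict(kind="softmax_readout", name="output", features=n_classes),
    ]


ARCH_PRESETS = {
    "mnist_cnn": mnist_cnn_spec,
    "cifar_nin": cifar_nin_spec,
    "toy_cnn": toy_cnn_spec,
    "toy_mlp": toy_mlp_spec,
}
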