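"""Comparison regimes: weight-copy finetuning, deep supervision, and
hint-based (FitNet-style) representational pretraining.

Each regime reduces to plain supervised training when its transfer
mechanism is disabled (no copy, alpha = 0, or a skipped pretraining stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layers import BatchNorm, Dense
from .network import Network
from .training import Attachment, SGD, TrainingConfig

__all__ = [
    "ShapeMismatchError",
    "finetune_init",
    "deep_supervision_attach",
    "HintAdapter",
    "hints_pretrain",
]


class ShapeMismatchError(ValueError):
    """Teacher and student hidden layers are not shape-compatible."""


def finetune_init(student: Network, teacher: Network) -> Network:
    """Initialise the student's weights from the teacher's, in place.

    Parameters are paired layer by layer (in order).  A trailing mismatch —
    a replaced readout for a different number of classes, or an extra
    readout appended to the student — is left freshly initialised; any
    mismatch in hidden layers raises, listing the offending layers.
    """
    s_layers = student.param_layers()
    t_layers = teacher.param_layers()
    n_common = min(len(s_layers), len(t_layers))
    if abs(len(s_layers) - len(t_layers)) > 1:
        raise ShapeMismatchError(
            f"architectures differ by more than a readout: "
            f"{len(s_layers)} vs {len(t_layers)} parameterised layers"
        )
    mismatches = []
    for i, (s, t) in enumerate(zip(s_layers, t_layers)):
        shapes_s = {k: v.shape for k, v in s.params.items()}
        shapes_t = {k: v.shape for k, v in t.params.items()}
        if shapes_s != shapes_t:
            mismatches.append((i, s.name, shapes_s, t.name, shapes_t))
    # only the final paired layer (a replaced readout) may disagree
    tail_ok = all(i == n_common - 1 for i, *_ in mismatches)
    if mismatches and not tail_ok:
        detail = "; ".join(
            f"layer {i} {sn}{ss} vs {tn}{ts}" for i, sn, ss, tn, ts in mismatches
        )
        raise ShapeMismatchError(f"incompatible hidden layers: {detail}")
    skip = {mismatches[0][0]} if mismatches else set()
    for i, (s, t) in enumerate(zip(s_layers, t_layers)):
        if i in skip:
            continue
        for k in s.params:
            s.params[k] = t.params[k].copy()
        if isinstance(s, BatchNorm) and isinstance(t, BatchNorm):
            for k in s.buffers:
                s.buffers[k] = t.buffers[k].copy()
    return student


def deep_supervision_attach(net: Network, layer_names) -> list[Attachment]:
    """Deep-supervision attachments: a linear softmax classifier on the
    flattened output of each named layer, weighted by the multiplicative
    alpha schedule during training."""
    for name in layer_names:
        if name not in net.block_end:
            raise KeyError(f"unknown layer {name!r}")
    return [Attachment(student_layer=name, kind="dsn") for name in layer_names]


@dataclass
class HintAdapter:
    """Linear map from a student layer's activation space to a teacher
    layer's, used only during hint pretraining and discarded afterwards."""

    dense: Dense

    @property
    def weights(self) -> np.ndarray:
        return self.dense.params["W"]

    def predict(self, acts2d: np.ndarray) -> np.ndarray:
        return self.dense.forward(acts2d)


def hints_pretrain(
    student: Network,
    teacher: Network,
    pair: Attachment,
    config: TrainingConfig,
    X,
    epochs: int | None = None,
) -> tuple[HintAdapter, pd.DataFrame]:
    """Stage-1 hint pretraining: drive a linear adapter on the student's
    hint layer to predict the teacher's corresponding layer activations
    (mean squared error), updating the adapter jointly with the student
    layers up to and including the hint layer.

    Returns the (frozen) adapter and a per-epoch loss history.  Stage 2 —
    ordinary supervised training of the full student — is run separately.
    """
    if pair.student_layer not in student.block_end:
        raise KeyError(f"unknown student layer {pair.student_layer!r}")
    t_layer = pair.teacher_layer or pair.student_layer
    if t_layer not in teacher.block_end:
        raise KeyError(f"unknown teacher layer {t_layer!r}")
    X = np.asarray(X, dtype=float)
    xall = student.prepare_input(X)
    n = xall.shape[0]
    epochs = config.epochs if epochs is None else epochs

    ss = np.random.SeedSequence(config.seed)
    shuffle_rng, dropout_rng, _, init_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # probe shapes once to size the adapter
    _, scap = student.forward(xall[:1], train=False, capture=(pair.student_layer,))
    _, tcap = teacher.forward(
        teacher.prepare_input(X[:1]), train=False, capture=(t_layer,)
    )
    k_s = int(np.prod(scap[pair.student_layer].shape[1:]))
    k_t = int(np.prod(tcap[t_layer].shape[1:]))
    adapter = Dense(f"hint@{pair.student_layer}", k_s, k_t)
    adapter.init(init_rng)

    hint_idx = student.block_end[pair.student_layer]
    lower = [
        p for p in student.primitives[: hint_idx + 1] if p.params
    ]
    opt = SGD(lower + [adapter], momentum=config.momentum)

    history = []
    for t in range(epochs):
        order = shuffle_rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            bidx = order[start : start + config.batch_size]
            xb = xall[bidx]
            student.zero_grads()
            adapter.zero_grads()
            _, scap = student.forward(
                xb, train=True, rng=dropout_rng, capture=(pair.student_layer,)
            )
            act = scap[pair.student_layer]
            act2d = act.reshape(act.shape[0], -1)
            _, tcap = teacher.forward(
                teacher.prepare_input(xb.reshape(xb.shape[0], -1)),
                train=False,
                capture=(t_layer,),
            )
            tact = tcap[t_layer].reshape(act.shape[0], -1)
            pred = adapter.forward(act2d)
            resid = pred - tact
            losses.append(float(np.mean(resid**2)))
            dpred = 2.0 * resid / resid.size
            dact = adapter.backward(dpred)
            student.backward_from(pair.student_layer, dact.reshape(act.shape))
            opt.step(config.lr)
        history.append({"epoch": t, "hint_loss": float(np.mean(losses))})
    return HintAdapter(adapter), pd.DataFrame(history)
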