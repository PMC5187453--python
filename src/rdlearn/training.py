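"""SGD training harness with auxiliary error functions at internal layers.

The total gradient at an attachment layer is the backpropagated output-loss
gradient plus alpha(t) times the auxiliary gradient (representational
distance matching against a teacher, or a deep-supervision linear softmax
classifier), injected mid-backpropagation so earlier layers receive the
combined signal.  alpha is updated once per epoch from the configured decay
schedule.

Randomness is split into independent streams (data shuffling, dropout
masks, pair subsampling, auxiliary-classifier initialisation) derived from
the single config seed, so that disabling the auxiliary term (alpha0 = 0)
leaves the baseline trajectory bit-for-bit unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .layers import Dense
from .loss import (
    AlphaSchedule,
    alpha_at,
    all_pairs,
    rdl_error,
    rdl_gradient_subsampled,
    sample_pairs,
)
from .network import Network
from .rdm import compute_rdm

__all__ = [
    "TrainingConfig",
    "Attachment",
    "TrainingDivergence",
    "train",
    "evaluate",
    "SGD",
    "softmax_cross_entropy",
]


class TrainingDivergence(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one SGD training run.

    ``lr_halve_every`` halves the learning rate at that epoch period
    (applied at epoch boundaries); ``output_loss_weight`` scales the output
    cross-entropy term (0 trains purely from auxiliary errors).
    """

    lr: float = 0.05
    momentum: float = 0.9
    batch_size: int = 25
    epochs: int = 20
    lr_halve_every: int | None = None
    shuffle: bool = True
    output_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("lr, batch_size, epochs must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")


@dataclass(frozen=True)
class Attachment:
    """An auxiliary error function attached to a student layer.

    kind 'rdl' pulls the layer's RDM toward the teacher's RDM at
    ``teacher_layer``; kind 'dsn' attaches a linear softmax classifier
    trained against the labels; kind 'hint' marks the layer pair used by
    hint pretraining (no gradient during the main run).
    """

    student_layer: str
    kind: str = "rdl"
    teacher_layer: str | None = None
    dissimilarity: str = "squared_euclidean_sum"
    pair_fraction: float = 1.0
    pair_count: int | None = None

    def __post_init__(self):
        if self.kind not in ("rdl", "dsn", "hint"):
            raise ValueError(f"unknown attachment kind {self.kind!r}")
        if self.kind == "rdl" and self.teacher_layer is None:
            object.__setattr__(self, "teacher_layer", self.student_layer)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray, n_classes: int):
    """Mean cross-entropy and its gradient with respect to the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = y.shape[0]
    loss = -logp[np.arange(n), y].mean()
    p = np.exp(logp)
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


class SGD:
    """Momentum SGD over a collection of (layer, param-name) slots."""

    def __init__(self, layers, momentum: float = 0.9):
        self.slots = [(lay, k) for lay in layers for k in lay.params]
        self.momentum = momentum
        self.velocity = [np.zeros_like(lay.params[k]) for lay, k in self.slots]

    def step(self, lr: float):
        for v, (lay, k) in zip(self.velocity, self.slots):
            v *= self.momentum
            v -= lr * lay.grads[k]
            lay.params[k] += v


def _probs_from_logits(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def evaluate(net: Network, X, y, batch_size: int = 512):
    """Per-item correctness vector and error rate, in inference mode."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty dataset")
    x = net.prepare_input(np.asarray(X, dtype=float))
    preds = []
    for start in range(0, x.shape[0], batch_size):
        out, _ = net.forward(x[start : start + batch_size], train=False)
        preds.append(out.argmax(axis=1))
    correct = np.concatenate(preds) == y
    return correct, float(1.0 - correct.mean())


def train(
    net: Network,
    X,
    y,
    config: TrainingConfig,
    attachments=(),
    teacher: Network | None = None,
    alpha_schedule: AlphaSchedule | None = None,
    X_test=None,
    y_test=None,
    n_classes: int | None = None,
):
    """Train ``net`` in place; returns a per-epoch history DataFrame.

    History columns: epoch, lr, alpha, output_loss, aux_loss/<layer> for
    each rdl/dsn attachment, train_error, test_error (NaN when no test set
    is given).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_classes = int(n_classes if n_classes is not None else y.max() + 1)
    attachments = list(attachments)
    active = [a for a in attachments if a.kind in ("rdl", "dsn")]
    if any(a.kind == "rdl" for a in active) and teacher is None:
        raise ValueError("rdl attachments require a teacher network")
    for a in active:
        if a.student_layer not in net.block_end:
            raise KeyError(f"student layer {a.student_layer!r} not in model")
        if a.kind == "rdl" and a.teacher_layer not in teacher.block_end:
            raise KeyError(f"teacher layer {a.teacher_layer!r} not in teacher")

    ss = np.random.SeedSequence(config.seed)
    shuffle_rng, dropout_rng, pair_rng, aux_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # deep-supervision companion classifiers (linear, discarded after training)
    dsn_clf: dict[str, Dense] = {}
    for a in active:
        if a.kind == "dsn":
            k = _flat_width(net, a.student_layer, X)
            clf = Dense(f"dsn@{a.student_layer}", k, n_classes)
            clf.init(aux_rng)
            dsn_clf[a.student_layer] = clf

    opt = SGD(net.param_layers() + list(dsn_clf.values()), momentum=config.momentum)

    xall = net.prepare_input(X)
    n = xall.shape[0]
    idx_all = np.arange(n)
    history = []
    for t in range(config.epochs):
        alpha = alpha_at(alpha_schedule, t) if alpha_schedule is not None else 0.0
        lr = config.lr
        if config.lr_halve_every:
            lr = config.lr * 0.5 ** (t // config.lr_halve_every)
        order = shuffle_rng.permutation(n) if config.shuffle else idx_all
        out_losses, aux_losses = [], {a.student_layer: [] for a in active}
        for start in range(0, n, config.batch_size):
            bidx = order[start : start + config.batch_size]
            xb, yb = xall[bidx], y[bidx]
            capture = tuple({a.student_layer for a in active})
            net.zero_grads()
            out, captured = net.forward(
                xb, train=True, rng=dropout_rng, capture=capture
            )
            if net.softmax_output:
                # forward output is probabilities; gradient taken w.r.t. the
                # pre-softmax logits (backward starts below the softmax)
                loss, dlogits = _softmax_output_loss(net, out, yb)
            else:
                loss, dlogits = softmax_cross_entropy(out, yb, n_classes)
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite output loss at epoch {t}, batch start {start}"
                )
            out_losses.append(loss)
            w = config.output_loss_weight
            inject = {}
            for a in active:
                act = captured[a.student_layer]
                act2d = act.reshape(act.shape[0], -1)
                if a.kind == "rdl":
                    if act2d.shape[0] < 2:
                        warnings.warn(
                            "batch of size < 2: RDL term skipped", RuntimeWarning
                        )
                        continue
                    g2d, aux = _rdl_batch_gradient(
                        teacher, a, xb, act2d, pair_rng
                    )
                else:  # dsn
                    g2d, aux = _dsn_batch_gradient(
                        dsn_clf[a.student_layer], act2d, yb, n_classes, alpha
                    )
                if not np.isfinite(aux):
                    raise TrainingDivergence(
                        f"non-finite auxiliary loss at {a.student_layer}, epoch {t}"
                    )
                aux_losses[a.student_layer].append(aux)
                prev = inject.get(a.student_layer, 0.0)
                inject[a.student_layer] = prev + alpha * g2d.reshape(act.shape)
            net.backward(w * dlogits, inject=inject, start=net.logits_start())
            opt.step(lr)
        _, train_err = evaluate(net, X, y)
        if X_test is not None:
            _, test_err = evaluate(net, X_test, y_test)
        else:
            test_err = np.nan
        row = {
            "epoch": t,
            "lr": lr,
            "alpha": alpha,
            "output_loss": float(np.mean(out_losses)),
            "train_error": train_err,
            "test_error": test_err,
        }
        for a in active:
            vals = aux_losses[a.student_layer]
            row[f"aux_loss/{a.student_layer}"] = float(np.mean(vals)) if vals else np.nan
        history.append(row)
    return pd.DataFrame(history)


def _flat_width(net: Network, layer_name: str, X) -> int:
    x1 = net.prepare_input(np.asarray(X, dtype=float)[:1])
    _, cap = net.forward(x1, train=False, capture=(layer_name,))
    return int(np.prod(cap[layer_name].shape[1:]))


def _softmax_output_loss(net: Network, probs, yb):
    n = yb.shape[0]
    eps = np.finfo(float).tiny
    loss = float(-np.log(np.maximum(probs[np.arange(n), yb], eps)).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), yb] -= 1.0
    return loss, dlogits / n


def _rdl_batch_gradient(teacher, a: Attachment, xb, act2d, pair_rng):
    t_in = teacher.prepare_input(xb.reshape(xb.shape[0], -1))
    _, tcap = teacher.forward(t_in, train=False, capture=(a.teacher_layer,))
    tact = tcap[a.teacher_layer]
    target = compute_rdm(
        tact.reshape(tact.shape[0], -1), dissimilarity=a.dissimilarity
    )
    n = act2d.shape[0]
    if a.pair_fraction >= 1.0 and a.pair_count is None:
        pairs = all_pairs(n)
    else:
        pairs = sample_pairs(n, a.pair_fraction, seed=pair_rng,
                             pair_count=a.pair_count)
    g = rdl_gradient_subsampled(act2d, target, pairs, dissimilarity=a.dissimilarity)
    aux = rdl_error(act2d, target, dissimilarity=a.dissimilarity)
    return g, aux


def _dsn_batch_gradient(clf: Dense, act2d, yb, n_classes, alpha):
    logits = clf.forward(act2d)
    loss, dlogits = softmax_cross_entropy(logits, yb, n_classes)
    dact = clf.backward(dlogits)
    # companion-classifier parameters learn under the same alpha weighting
    for k in clf.grads:
        clf.grads[k] *= alpha
    return dact, loss
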