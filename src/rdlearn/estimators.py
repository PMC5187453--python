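"""Scikit-learn-style estimator for classifiers trained under the five
regimes: baseline, finetune, deep supervision (dsn), hints, and
representational distance learning (rdl).

``NetworkClassifier`` follows the sklearn contract — constructor stores
hyperparameters verbatim, ``fit`` validates and trains, fitted state lives
in trailing-underscore attributes — so it composes with pipelines, cloning
and model selection.  The lower-level engine functions it wraps
(:func:`rdlearn.training.train`, :mod:`rdlearn.baselines`) remain available
for direct use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .baselines import deep_supervision_attach, finetune_init, hints_pretrain
from .loss import AlphaSchedule
from .network import ARCH_PRESETS, Network, build_model, extract_activations
from .training import Attachment, TrainingConfig, evaluate, train

__all__ = ["NetworkClassifier"]

REGIMES = ("baseline", "finetune", "dsn", "hints", "rdl")


class NetworkClassifier(BaseEstimator, ClassifierMixin):
    """A layered neural-network classifier trained with SGD + momentum,
    optionally under a representational transfer regime.

    Parameters
    ----------
    arch : str or list of dict
        Architecture preset name (``toy_mlp``, ``toy_cnn``, ``mnist_cnn``,
        ``cifar_nin``) or an explicit block-spec list.
    input_shape : tuple or None
        Shape of one input, e.g. ``(1, 12, 12)``; flat ``(n_features,)``
        inferred when None.
    regime : str
        One of ``baseline``, ``finetune``, ``dsn``, ``hints``, ``rdl``.
    teacher : NetworkClassifier or Network, optional
        Frozen teacher model (required for finetune/hints/rdl).
    attachments : list, optional
        Attachment objects or dicts; defaults per regime: rdl attaches at
        every pooling and fully connected block, dsn after pooling blocks,
        hints at the middle block.
    alpha0 : float
        Initial auxiliary-loss weight; decays linearly to 0 over training
        for rdl and multiplicatively for dsn.
    pair_fraction : float
        Fraction of the n(n-1) ordered batch pairs used per update by rdl.
    dissimilarity : str
        RDM dissimilarity used by rdl attachments.
    output_loss_weight : float
        Weight of the output cross-entropy (0 gives an rdl-only objective).
    hint_epochs : int or None
        Length of the hint pretraining stage (defaults to ``epochs``).

    Attributes
    ----------
    classes_ : ndarray of class labels.
    net_ : the trained Network.
    history_ : per-epoch DataFrame (losses, alpha, lr, errors).
    hint_history_ : stage-1 DataFrame (hints regime only).
    """

    def __init__(
        self,
        arch="toy_mlp",
        input_shape=None,
        regime="baseline",
        teacher=None,
        attachments=None,
        alpha0=1.0,
        pair_fraction=1.0,
        pair_count=None,
        dissimilarity="squared_euclidean_sum",
        lr=0.05,
        momentum=0.9,
        batch_size=25,
        epochs=20,
        lr_halve_every=None,
        output_loss_weight=1.0,
        hint_epochs=None,
        random_state=0,
    ):
        self.arch = arch
        self.input_shape = input_shape
        self.regime = regime
        self.teacher = teacher
        self.attachments = attachments
        self.alpha0 = alpha0
        self.pair_fraction = pair_fraction
        self.pair_count = pair_count
        self.dissimilarity = dissimilarity
        self.lr = lr
        self.momentum = momentum
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_halve_every = lr_halve_every
        self.output_loss_weight = output_loss_weight
        self.hint_epochs = hint_epochs
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _teacher_net(self) -> Network | None:
        if self.teacher is None:
            return None
        if isinstance(self.teacher, Network):
            return self.teacher
        if isinstance(self.teacher, NetworkClassifier):
            check_is_fitted(self.teacher)
            return self.teacher.net_
        raise TypeError("teacher must be a Network or fitted NetworkClassifier")

    def _build_spec(self, n_classes: int):
        if isinstance(self.arch, str):
            if self.arch not in ARCH_PRESETS:
                raise ValueError(
                    f"unknown arch {self.arch!r}; presets: {sorted(ARCH_PRESETS)}"
                )
            return ARCH_PRESETS[self.arch](n_classes=n_classes)
        return self.arch

    def _default_attachments(self, net: Network):
        if self.regime == "rdl":
            names = [
                b["name"] for b in net.spec
                if b["kind"] in ("max_pool", "avg_pool", "fc")
            ]
            return [
                Attachment(n, kind="rdl", teacher_layer=n,
                           dissimilarity=self.dissimilarity,
                           pair_fraction=self.pair_fraction,
                           pair_count=self.pair_count)
                for n in names
            ]
        if self.regime == "dsn":
            names = [
                b["name"] for b in net.spec if b["kind"] in ("max_pool", "avg_pool")
            ]
            return deep_supervision_attach(net, names)
        if self.regime == "hints":
            names = [
                b["name"] for b in net.spec
                if b["kind"] in ("max_pool", "avg_pool", "fc")
            ]
            mid = names[len(names) // 2] if names else net.block_names[0]
            return [Attachment(mid, kind="hint", teacher_layer=mid)]
        return []

    def _coerce_attachments(self, net: Network):
        if self.attachments is None:
            return self._default_attachments(net)
        out = []
        for a in self.attachments:
            if isinstance(a, Attachment):
                out.append(a)
            else:
                d = dict(a)
                d.setdefault("kind", "rdl" if self.regime == "rdl" else self.regime)
                if d["kind"] == "rdl":
                    d.setdefault("dissimilarity", self.dissimilarity)
                    d.setdefault("pair_fraction", self.pair_fraction)
                    d.setdefault("pair_count", self.pair_count)
                out.append(Attachment(**d))
        return out

    # ------------------------------------------------------------------
    def fit(self, X, y, X_test=None, y_test=None):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        X = np.asarray(X, dtype=float)
        if X.ndim > 2:
            X = X.reshape(X.shape[0], -1)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        self.n_features_in_ = X.shape[1]
        input_shape = (
            tuple(self.input_shape) if self.input_shape is not None
            else (X.shape[1],)
        )
        if int(np.prod(input_shape)) != X.shape[1]:
            raise ValueError(
                f"input_shape {input_shape} does not match {X.shape[1]} features"
            )

        teacher_net = self._teacher_net()
        if self.regime in ("finetune", "hints", "rdl") and teacher_net is None:
            raise ValueError(f"regime {self.regime!r} requires a teacher")

        seed = int(self.random_state or 0)
        net = build_model(self._build_spec(n_classes), input_shape, seed=seed)
        attachments = self._coerce_attachments(net)
        config = TrainingConfig(
            lr=self.lr,
            momentum=self.momentum,
            batch_size=self.batch_size,
            epochs=self.epochs,
            lr_halve_every=self.lr_halve_every,
            output_loss_weight=self.output_loss_weight,
            seed=seed,
        )

        schedule = None
        if self.regime == "rdl":
            schedule = AlphaSchedule(self.alpha0, max(1, self.epochs), "linear_rdl")
        elif self.regime == "dsn":
            schedule = AlphaSchedule(
                self.alpha0, max(1, self.epochs), "multiplicative_dsn"
            )

        if self.regime == "finetune":
            finetune_init(net, teacher_net)
        if self.regime == "hints":
            hint_pairs = [a for a in attachments if a.kind == "hint"]
            if not hint_pairs:
                raise ValueError("hints regime needs a hint attachment")
            _, self.hint_history_ = hints_pretrain(
                net, teacher_net, hint_pairs[0], config, X,
                epochs=self.hint_epochs,
            )

        self.history_ = train(
            net, X, y_enc, config,
            attachments=attachments,
            teacher=teacher_net,
            alpha_schedule=schedule,
            X_test=X_test, y_test=(
                None if y_test is None
                else np.searchsorted(self.classes_, np.asarray(y_test))
            ),
            n_classes=n_classes,
        )
        self.net_ = net
        self.attachments_ = attachments
        return self

    # ------------------------------------------------------------------
    def predict_proba(self, X):
        check_is_fitted(self)
        X = np.asarray(X, dtype=float).reshape(len(X), -1)
        x = self.net_.prepare_input(X)
        out, _ = self.net_.forward(x, train=False)
        if self.net_.softmax_output:
            return out
        z = out - out.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def correctness(self, X, y) -> np.ndarray:
        """Per-item correctness vector (the McNemar test input)."""
        return self.predict(X) == np.asarray(y)

    def error_rate(self, X, y) -> float:
        return float(1.0 - self.correctness(X, y).mean())

    def layer_activations(self, X, layer_name: str) -> np.ndarray:
        """Flattened inference-mode activations at a named block."""
        check_is_fitted(self)
        X = np.asarray(X, dtype=float).reshape(len(X), -1)
        return extract_activations(self.net_, X, layer_name)
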