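"""Transfer baselines: weight-copy finetuning, deep supervision companion
classifiers, and hint pretraining."""

import numpy as np
import pytest

from rdlearn.baselines import (
    ShapeMismatchError,
    deep_supervision_attach,
    finetune_init,
    hints_pretrain,
)
from rdlearn.layers import Dense
from rdlearn.network import build_model, extract_activations, toy_cnn_spec
from rdlearn.training import Attachment, TrainingConfig, train


def test_finetune_identical_architecture_copies_exactly():
    teacher = build_model(toy_cnn_spec(5), (1, 12, 12), seed=7)
    student = build_model(toy_cnn_spec(5), (1, 12, 12), seed=8)
    finetune_init(student, teacher)
    x = np.random.default_rng(0).normal(size=(3, 1, 12, 12))
    np.testing.assert_array_equal(teacher.forward(x)[0], student.forward(x)[0])


def test_finetune_replaced_readout_keeps_body():
    teacher = build_model(toy_cnn_spec(5), (1, 12, 12), seed=7)
    student = build_model(toy_cnn_spec(10), (1, 12, 12), seed=8)
    fresh_readout = {
        k: v.copy() for k, v in student.param_layers()[-1].params.items()
    }
    finetune_init(student, teacher)
    for s, t in zip(student.param_layers()[:-1], teacher.param_layers()[:-1]):
        for k in s.params:
            np.testing.assert_array_equal(s.params[k], t.params[k])
    for k, v in student.param_layers()[-1].params.items():
        np.testing.assert_array_equal(v, fresh_readout[k])


def test_finetune_incompatible_hidden_layers_listed():
    teacher = build_model(toy_cnn_spec(5), (1, 12, 12), seed=7)
    wider = [dict(kind="conv", name="conv1", features=16, kernel=3),
             dict(kind="max_pool", name="pool1", kernel=2, stride=2),
             dict(kind="fc", name="fc1", features=32),
             dict(kind="softmax_readout", name="output", features=5)]
    student = build_model(wider, (1, 12, 12), seed=8)
    with pytest.raises(ShapeMismatchError, match="conv1"):
        finetune_init(student, teacher)


def test_deep_supervision_attachments_and_alpha_zero_reduction(tiny_dataset):
    ds = tiny_dataset
    X = ds.X_train.reshape(len(ds.y_train), -1)
    net = build_model(toy_cnn_spec(3), ds.input_shape, seed=3)
    atts = deep_supervision_attach(net, ["pool1"])
    assert [a.kind for a in atts] == ["dsn"]
    with pytest.raises(KeyError):
        deep_supervision_attach(net, ["nope"])

    from rdlearn.loss import AlphaSchedule

    cfg = TrainingConfig(lr=0.02, epochs=5, seed=3)
    h_dsn = train(build_model(toy_cnn_spec(3), ds.input_shape, seed=3),
                  X, ds.y_train, cfg, attachments=atts,
                  alpha_schedule=AlphaSchedule(0.0, 5, "multiplicative_dsn"),
                  n_classes=3)
    h_base = train(build_model(toy_cnn_spec(3), ds.input_shape, seed=3),
                   X, ds.y_train, cfg, n_classes=3)
    np.testing.assert_array_equal(h_dsn.output_loss, h_base.output_loss)


def test_deep_supervision_total_gradient_finite_differences(tiny_dataset):
    """Companion-classifier gradient at the attachment propagates correctly
    into the layer below (total loss = CE_out + alpha * CE_aux)."""
    ds = tiny_dataset
    n, alpha = 6, 0.5
    x = ds.X_train.reshape(len(ds.y_train), -1)[:n]
    y = ds.y_train[:n]
    net = build_model(toy_cnn_spec(3), ds.input_shape, seed=4)
    k_pool = extract_activations(net, x, "pool1").shape[1]
    clf = Dense("aux", k_pool, 3)
    clf.init(np.random.default_rng(0))

    def ce(logits, y):
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return float(-logp[np.arange(len(y)), y].mean())

    def total_loss():
        xin = net.prepare_input(x)
        out, cap = net.forward(xin, train=False, capture=("pool1",))
        acts = cap["pool1"].reshape(n, -1)
        out_ce = float(-np.log(out[np.arange(n), y]).mean())
        return out_ce + alpha * ce(clf.forward(acts), y)

    xin = net.prepare_input(x)
    out, cap = net.forward(xin, train=False, capture=("pool1",))
    dlogits = out.copy()
    dlogits[np.arange(n), y] -= 1.0
    acts = cap["pool1"]
    aux_logits = clf.forward(acts.reshape(n, -1))
    p = np.exp(aux_logits - aux_logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    daux = p.copy()
    daux[np.arange(n), y] -= 1.0
    dact = clf.backward(daux / n)
    net.zero_grads()
    net.backward(dlogits / n, inject={"pool1": alpha * dact.reshape(acts.shape)},
                 start=net.logits_start())

    conv = net.param_layers()[0]
    h = 1e-6
    rng = np.random.default_rng(5)
    for k, W in conv.params.items():
        for f in rng.choice(W.size, size=min(4, W.size), replace=False):
            ix = np.unravel_index(f, W.shape)
            orig = W[ix]
            W[ix] = orig + h
            lp = total_loss()
            W[ix] = orig - h
            lm = total_loss()
            W[ix] = orig
            assert conv.grads[k][ix] == pytest.approx((lp - lm) / (2 * h),
                                                      rel=1e-4, abs=1e-7)


def test_hint_adapter_dimensions_and_identity_case(tiny_dataset):
    ds = tiny_dataset
    X = ds.X_train.reshape(len(ds.y_train), -1)
    student = build_model(toy_cnn_spec(3), ds.input_shape, seed=6)
    teacher = student.copy()
    adapter, hist = hints_pretrain(
        student, teacher, Attachment("fc1", kind="hint"),
        TrainingConfig(lr=0.0005, epochs=3, seed=6), X,
    )
    assert adapter.weights.shape == (32, 32)
    # identical layers + identity adapter -> zero hint loss
    acts = extract_activations(teacher, X, "fc1")
    ident = acts @ np.eye(32)
    assert np.mean((ident - acts) ** 2) == 0.0


def test_hint_loss_decreases_on_average(tiny_dataset):
    ds = tiny_dataset
    X = ds.X_train.reshape(len(ds.y_train), -1)
    student = build_model(toy_cnn_spec(3), ds.input_shape, seed=9)
    teacher = build_model(toy_cnn_spec(3), ds.input_shape, seed=10)
    _, hist = hints_pretrain(
        student, teacher, Attachment("fc1", kind="hint"),
        TrainingConfig(lr=0.005, epochs=12, seed=9), X,
    )
    first = hist.hint_loss.iloc[:3].mean()
    last = hist.hint_loss.iloc[-3:].mean()
    assert last < first
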