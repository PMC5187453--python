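"""Canned synthetic transfer experiments at desk scale.

These functions define the package's reference study conditions: a teacher
trained on a large, augmented variant of a class-prototype image task, and
a student with the same small architecture trained on a small clean sample
of the same classes.  They are used both by the test suite and by the
acceptance script; all sizes are chosen to run in minutes on one CPU.

Conditions (see docs/methods.md for rationale): 5 classes of 12x12
single-channel images, prototype pixel scale 1.0, sample noise sd 3.0
(a hard, noise-dominated task); student 6 train / 60 test images per class;
teacher 150 train images per class with translation (+-2 px) and smooth
deformation (1 px) augmentation.  Both models are the small conv ->
max-pool -> fc -> softmax architecture; SGD with lr 0.02, momentum 0.9,
batch 25.  RDL attaches at the pooling and fully connected layers with the
correlation-distance dissimilarity (scale-free, so the student matches the
teacher's representational geometry rather than its absolute activation
magnitudes), 25% of ordered batch pairs (batches here are a quarter of the
size typical for full-scale training, so a denser pair sample keeps the
per-update pair count comparable), and alpha decaying linearly from 1 to 0.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .analysis import rdm_compare
from .datasets import SyntheticSpec, generate_dataset
from .estimators import NetworkClassifier
from .network import build_model, extract_activations
from .rdm import compute_rdm
from .training import Attachment

__all__ = [
    "student_spec",
    "teacher_spec",
    "train_toy_teacher",
    "rdm_convergence_experiment",
    "transfer_benefit_experiment",
]

ARCH = "toy_cnn"
RDL_LAYERS = ("pool1", "fc1")
DISSIMILARITY = "correlation_distance"
PAIR_FRACTION = 0.25
ALPHA0 = 1.0
LR = 0.02
BATCH = 25
TEACHER_EPOCHS = 30
STUDENT_EPOCHS = 30


def student_spec(seed: int, prototype_seed: int = 7) -> SyntheticSpec:
    """Small clean training sample of the shared class prototypes."""
    return SyntheticSpec(
        n_classes=5, n_train_per_class=6, n_test_per_class=60, side=12,
        prototype_scale=1.0, noise_sd=3.0,
        seed=seed, prototype_seed=prototype_seed,
    )


def teacher_spec(seed: int, prototype_seed: int = 7) -> SyntheticSpec:
    """Large augmented sample of the same prototypes (the teacher's
    different-but-related data)."""
    return SyntheticSpec(
        n_classes=5, n_train_per_class=150, n_test_per_class=40, side=12,
        prototype_scale=1.0, noise_sd=3.0,
        max_translation=2, deformation_amplitude=1.0,
        seed=seed, prototype_seed=prototype_seed,
    )


def _seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def train_toy_teacher(base_seed: int = 0, prototype_seed: int = 7):
    """Fit the reference teacher; returns (teacher classifier, its dataset)."""
    tseed, dseed = _seeds(base_seed ^ 0x7EAC, 2)
    ds = generate_dataset(teacher_spec(dseed, prototype_seed))
    teacher = NetworkClassifier(
        arch=ARCH, input_shape=ds.input_shape, regime="baseline",
        lr=LR, batch_size=BATCH, epochs=TEACHER_EPOCHS, random_state=tseed,
    )
    teacher.fit(ds.X_train.reshape(len(ds.y_train), -1), ds.y_train)
    return teacher, ds


def _rdl_student(teacher, ds, seed, output_loss_weight=1.0, epochs=STUDENT_EPOCHS):
    attachments = [
        Attachment(n, kind="rdl", teacher_layer=n,
                   dissimilarity=DISSIMILARITY, pair_fraction=PAIR_FRACTION)
        for n in RDL_LAYERS
    ]
    return NetworkClassifier(
        arch=ARCH, input_shape=ds.input_shape, regime="rdl",
        teacher=teacher, attachments=attachments, alpha0=ALPHA0,
        dissimilarity=DISSIMILARITY, pair_fraction=PAIR_FRACTION,
        lr=LR, batch_size=BATCH, epochs=epochs,
        output_loss_weight=output_loss_weight, random_state=seed,
    )


def rdm_convergence_experiment(
    base_seed: int = 0, epochs: int = STUDENT_EPOCHS, probe_size: int = 50
) -> pd.DataFrame:
    """Train a student with an RDL-only objective (output loss weight 0) and
    measure the correlation distance between student and teacher RDMs at
    each attachment layer, on a held-out probe batch, before and after
    training.

    Returns a DataFrame indexed by layer with columns ``initial`` and
    ``final``.
    """
    teacher, tds = train_toy_teacher(base_seed)
    sseed, dseed = _seeds(base_seed ^ 0x5D01, 2)
    ds = generate_dataset(student_spec(dseed))
    probe = ds.X_test[:probe_size].reshape(probe_size, -1)

    student = _rdl_student(teacher, ds, sseed, output_loss_weight=0.0,
                           epochs=epochs)
    n_classes = ds.spec.n_classes
    init_net = build_model(
        student._build_spec(n_classes), ds.input_shape, seed=sseed
    )

    def layer_distance(net, layer):
        s_rdm = compute_rdm(
            extract_activations(net, probe, layer), dissimilarity=DISSIMILARITY
        )
        t_acts = teacher.layer_activations(probe, layer)
        t_rdm = compute_rdm(t_acts, dissimilarity=DISSIMILARITY)
        return rdm_compare(s_rdm, t_rdm, metric="correlation_distance")

    initial = {layer: layer_distance(init_net, layer) for layer in RDL_LAYERS}
    student.fit(ds.X_train.reshape(len(ds.y_train), -1), ds.y_train)
    final = {layer: layer_distance(student.net_, layer) for layer in RDL_LAYERS}
    return pd.DataFrame(
        {"initial": pd.Series(initial), "final": pd.Series(final)}
    )


def transfer_benefit_experiment(
    base_seed: int = 0, n_seeds: int = 5
) -> pd.DataFrame:
    """Across ``n_seeds`` independent student data draws and initialisations,
    train a baseline student and an RDL student on the same small dataset
    and record their test errors against a common trained teacher.

    Returns a DataFrame with one row per seed and columns ``baseline_error``
    and ``rdl_error`` (test-set error rates in [0, 1])."""
    teacher, _ = train_toy_teacher(base_seed)
    rows = []
    for k, seed in enumerate(_seeds(base_seed ^ 0x3FE2, n_seeds)):
        ds = generate_dataset(student_spec(seed))
        Xtr = ds.X_train.reshape(len(ds.y_train), -1)
        Xte = ds.X_test.reshape(len(ds.y_test), -1)
        baseline = NetworkClassifier(
            arch=ARCH, input_shape=ds.input_shape, regime="baseline",
            lr=LR, batch_size=BATCH, epochs=STUDENT_EPOCHS, random_state=seed,
        ).fit(Xtr, ds.y_train)
        rdl = _rdl_student(teacher, ds, seed).fit(Xtr, ds.y_train)
        rows.append(
            {
                "seed": seed,
                "baseline_error": baseline.error_rate(Xte, ds.y_test),
                "rdl_error": rdl.error_rate(Xte, ds.y_test),
            }
        )
    return pd.DataFrame(rows)
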