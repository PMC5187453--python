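"""Seeded generators for class-structured synthetic image data and toy
teacher networks.

Each class is defined by a fixed random prototype image (smoothed Gaussian
noise at a chosen amplitude); samples are the prototype plus i.i.d. pixel
noise, optionally passed through integer-pixel translations and smoothed
random displacement fields that emulate the pseudo-random deformations and
translations of extended handwritten-digit sets.  Generation is a pure
function of the spec, so datasets are hash-stable test fixtures.

A teacher/student experiment uses two specs sharing ``prototype_seed`` (the
same classes) but different sample seeds, sizes, and augmentation — the
teacher sees a large augmented variant of the task, the student a small
clean one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, shift as nd_shift

__all__ = ["SyntheticSpec", "Dataset", "generate_dataset", "make_toy_teacher",
           "save_dataset", "load_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic image-classification dataset.

    prototype_scale is the pixel standard deviation of the class prototypes
    (the signal); noise_sd the per-pixel sample noise (dimensionless
    activation units).  max_translation is in pixels; deformation_amplitude
    is the displacement-field amplitude in pixels, smoothed with a Gaussian
    of width deformation_smoothness.
    """

    n_classes: int = 5
    n_train_per_class: int = 15
    n_test_per_class: int = 60
    side: int = 12
    channels: int = 1
    prototype_scale: float = 1.0
    noise_sd: float = 0.7
    max_translation: int = 0
    deformation_amplitude: float = 0.0
    deformation_smoothness: float = 2.0
    seed: int = 0
    prototype_seed: int | None = None

    def __post_init__(self):
        if min(self.n_classes, self.n_train_per_class, self.n_test_per_class,
               self.side, self.channels) < 1:
            raise ValueError("sizes must be positive")
        if self.noise_sd < 0 or self.prototype_scale <= 0:
            raise ValueError("prototype_scale must be > 0 and noise_sd >= 0")
        if self.max_translation < 0 or self.deformation_amplitude < 0:
            raise ValueError("augmentation amplitudes must be nonnegative")


@dataclass(frozen=True)
class Dataset:
    X_train: np.ndarray  # (n, C, H, W)
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    prototypes: np.ndarray  # (n_classes, C, H, W)
    spec: SyntheticSpec

    @property
    def input_shape(self):
        return self.X_train.shape[1:]


def _prototypes(spec: SyntheticSpec) -> np.ndarray:
    seed = spec.seed if spec.prototype_seed is None else spec.prototype_seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1009]))
    raw = rng.normal(
        0.0, 1.0, size=(spec.n_classes, spec.channels, spec.side, spec.side)
    )
    smooth = gaussian_filter(raw, sigma=(0, 0, 1.0, 1.0))
    # rescale so the prototype pixel sd equals prototype_scale
    sd = smooth.std(axis=(1, 2, 3), keepdims=True)
    return spec.prototype_scale * smooth / sd


def _deform(img: np.ndarray, rng: np.random.Generator, spec: SyntheticSpec):
    c, h, w = img.shape
    out = img
    if spec.deformation_amplitude > 0:
        disp = rng.normal(0.0, 1.0, size=(2, h, w))
        disp = gaussian_filter(disp, sigma=(0, spec.deformation_smoothness,
                                            spec.deformation_smoothness))
        for axis in range(2):
            m = np.abs(disp[axis]).max()
            if m > 0:
                disp[axis] *= spec.deformation_amplitude / m
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.stack([yy + disp[0], xx + disp[1]])
        out = np.stack(
            [map_coordinates(ch, coords, order=1, mode="nearest") for ch in out]
        )
    if spec.max_translation > 0:
        dy, dx = rng.integers(-spec.max_translation, spec.max_translation + 1, size=2)
        out = np.stack(
            [nd_shift(ch, (dy, dx), order=0, mode="constant", cval=0.0) for ch in out]
        )
    return out


def _sample_split(spec, protos, rng, n_per_class, offset_ids=0):
    imgs, labels = [], []
    for cls in range(spec.n_classes):
        for _ in range(n_per_class):
            img = protos[cls] + rng.normal(0.0, spec.noise_sd, size=protos[cls].shape)
            if spec.deformation_amplitude > 0 or spec.max_translation > 0:
                img = _deform(img, rng, spec)
            imgs.append(img)
            labels.append(cls)
    X = np.stack(imgs)
    y = np.array(labels, dtype=np.intp)
    order = rng.permutation(len(y))
    return X[order], y[order]


def generate_dataset(spec: SyntheticSpec) -> Dataset:
    """Generate balanced train/test splits; deterministic given the spec."""
    protos = _prototypes(spec)
    rng_train = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    rng_test = np.random.default_rng(np.random.SeedSequence([spec.seed, 3]))
    X_train, y_train = _sample_split(spec, protos, rng_train, spec.n_train_per_class)
    X_test, y_test = _sample_split(spec, protos, rng_test, spec.n_test_per_class)
    return Dataset(X_train, y_train, X_test, y_test, protos, spec)


def save_dataset(path, ds: Dataset) -> None:
    """Keyed-array container plus a JSON echo of the generating spec."""
    np.savez(
        path,
        X_train=ds.X_train, y_train=ds.y_train,
        X_test=ds.X_test, y_test=ds.y_test,
        prototypes=ds.prototypes,
        spec_json=np.array(json.dumps(asdict(ds.spec))),
    )


def load_dataset(path) -> Dataset:
    with np.load(path, allow_pickle=False) as d:
        spec = SyntheticSpec(**json.loads(str(d["spec_json"])))
        return Dataset(d["X_train"], d["y_train"], d["X_test"], d["y_test"],
                       d["prototypes"], spec)


def make_toy_teacher(
    spec: SyntheticSpec,
    arch: str | list = "toy_cnn",
    epochs: int = 25,
    seed: int = 0,
    probe_size: int = 40,
    dissimilarity: str = "squared_euclidean_mean",
    rdm_layers=None,
    lr: float = 0.05,
):
    """Train a toy teacher on (typically augmented) synthetic data and
    export its per-layer RDMs on a probe batch from its test split.

    Returns (teacher Network, {layer: RDM}, history DataFrame, dataset).
    """
    from .network import ARCH_PRESETS, build_model, extract_activations
    from .rdm import compute_rdm
    from .training import TrainingConfig, TrainingDivergence, train

    ds = generate_dataset(spec)
    if isinstance(arch, str):
        spec_list = ARCH_PRESETS[arch](n_classes=spec.n_classes)
    else:
        spec_list = arch
    net = build_model(spec_list, input_shape=ds.input_shape, seed=seed)
    config = TrainingConfig(lr=lr, epochs=epochs, seed=seed)
    history = train(
        net,
        ds.X_train.reshape(len(ds.y_train), -1),
        ds.y_train,
        config,
        X_test=ds.X_test.reshape(len(ds.y_test), -1),
        y_test=ds.y_test,
        n_classes=spec.n_classes,
    )
    probe = ds.X_test[:probe_size].reshape(min(probe_size, len(ds.y_test)), -1)
    if rdm_layers is None:
        rdm_layers = [n for n in net.block_names if n != "output"]
    rdms = {
        name: compute_rdm(
            extract_activations(net, probe, name), dissimilarity=dissimilarity
        )
        for name in rdm_layers
    }
    return net, rdms, history, ds
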