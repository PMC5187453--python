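import numpy as np
import pytest

from rdlearn.datasets import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small, easily separable 3-class image task for fast training tests."""
    spec = SyntheticSpec(
        n_classes=3, n_train_per_class=8, n_test_per_class=15, side=8,
        prototype_scale=1.0, noise_sd=0.5, seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def toy_teacher():
    """Reference teacher trained under the package's study conditions."""
    from rdlearn.experiments import train_toy_teacher

    teacher, ds = train_toy_teacher(base_seed=0)
    return teacher, ds
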