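"""Shared fixtures: tiny fast networks and small synthetic datasets.

The expensive fixture is ``trained_csn_study``: one scaled-down Siamese
training run (10 species x 24 images at 64x64) shared by the end-to-end
learning and transfer tests.
"""

import numpy as np
import pytest

from leafsiam.data_io import make_split
from leafsiam.model import ArchitectureSpec, build_embedding_network
from leafsiam.synthetic_leaves import GeneratorConfig, generate_samples
from leafsiam.training import TrainingConfig, train_csn

#: reduced architecture for oracle tests: fits 20x20 inputs, ~1k parameters
TINY_SPEC = ArchitectureSpec(input_height=20, input_width=20,
                             conv_blocks=((4, 5, True), (8, 3, False)),
                             embedding_dim=16)

#: the paper-shaped trunk at the smallest practical input
SMALL_SPEC = ArchitectureSpec(input_height=48, input_width=48)

STUDY_SEED = 1
STUDY_GEN = GeneratorConfig(n_species=10, images_per_species=24,
                            image_size=64, seed=STUDY_SEED)
#: scaled-down training profile: short epoch budget, larger Adam step
STUDY_TRAIN = TrainingConfig(epochs=30, learning_rate=1e-3, seed=STUDY_SEED)


@pytest.fixture
def tiny_net():
    return build_embedding_network(TINY_SPEC, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_images(n, size=20, seed=0):
    return np.random.default_rng(seed).random((n, size, size)).astype(np.float32)


def tiny_class_index(n_classes=3, per_class=4, size=20, seed=0):
    imgs = tiny_images(n_classes * per_class, size=size, seed=seed)
    return {f"sp{c}": [imgs[c * per_class + i] for i in range(per_class)]
            for c in range(n_classes)}


@pytest.fixture(scope="session")
def study_samples():
    return generate_samples(STUDY_GEN)


@pytest.fixture(scope="session")
def study_split(study_samples):
    return make_split(study_samples, n_test_per_species=4, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def trained_csn_study(study_split):
    """The scaled-down study training run (takes a few minutes once)."""
    net = build_embedding_network(
        ArchitectureSpec(input_height=64, input_width=64), seed=STUDY_SEED)
    net, history = train_csn(net, study_split.T, study_split.V, STUDY_TRAIN)
    return net, history
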