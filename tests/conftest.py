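import numpy as np
import pytest

from embow import (LabeledGroupSet, SyntheticSpec, build_codebook,
                   default_term_catalog, generate_group_set, make_layout,
                   sample_descriptors)


@pytest.fixture(scope="session")
def catalog():
    return default_term_catalog()


@pytest.fixture(scope="session")
def clean_spec(catalog):
    """Noise-free spec with the four localized default patterns."""
    return SyntheticSpec(patterns=catalog, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_spec(catalog):
    return SyntheticSpec(patterns=catalog, noise_sd=20.0, jitter_sd=0.02)


@pytest.fixture(scope="session")
def small_group_set(noisy_spec, catalog) -> LabeledGroupSet:
    """24 groups x 2 images: enough for split/train/evaluate round trips."""
    return generate_group_set(noisy_spec, 24, 2, list(catalog),
                              {t: 0.5 for t in catalog}, seed=7)


@pytest.fixture(scope="session")
def layout():
    return make_layout(192, 96, radius=16, stride=16)


@pytest.fixture(scope="session")
def small_codebook(small_group_set, layout):
    sample = sample_descriptors(small_group_set, layout, fraction=0.25, seed=7)
    return build_codebook(sample, c=16, seed=7, n_restarts=3, max_iter=50)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
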