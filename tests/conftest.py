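"""Shared fixtures: ground-truth parameters and one synthetic dataset.

The synthetic dataset (full three-phase protocol, noise-free) is
session-scoped: several test modules exercise different stages of the
pipeline against the same ground truth.
"""

import numpy as np
import pytest

from clotrheo.parameters import default_parameters
from clotrheo.synthetic import generate_dataset


@pytest.fixture(scope="session")
def truth_params():
    return default_parameters()


@pytest.fixture(scope="session")
def clean_dataset(truth_params):
    return generate_dataset(truth_params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
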