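import numpy as np
import pytest

from varcog.scoring import AMINO_ACIDS, default_score_model


@pytest.fixture(scope="session")
def model():
    return default_score_model()


@pytest.fixture(scope="session")
def score_dict(model):
    """Plain nested-dict view of the scores for independent-oracle arithmetic."""
    return {
        a: {b: model.matrix[i, j] for j, b in enumerate(AMINO_ACIDS)}
        for i, a in enumerate(AMINO_ACIDS)
    }


@pytest.fixture(scope="session")
def freq_dict(model):
    return {a: model.background[i] for i, a in enumerate(AMINO_ACIDS)}


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
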