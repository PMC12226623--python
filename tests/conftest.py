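import numpy as np
import pytest

from psilopred.lexicon import DEFAULT_LABELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def labels8():
    return DEFAULT_LABELS


class MockBackend:
    """Backend returning fixed weights regardless of text."""

    def __init__(self, weights):
        self._weights = list(weights)

    def weights(self, text, candidate_labels):
        return self._weights[: len(candidate_labels)]


@pytest.fixture
def mock_backend():
    return MockBackend
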