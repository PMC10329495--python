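import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def blob_modalities(rng):
    """Two small cell-matched modalities with 3 well-separated groups."""
    sizes = (20, 18, 22)
    labels = np.repeat(np.arange(3), sizes)
    centers1 = rng.standard_normal((3, 8)) * 8.0
    centers2 = rng.standard_normal((3, 5)) * 8.0
    X1 = centers1[labels] + 0.3 * rng.standard_normal((sum(sizes), 8))
    X2 = centers2[labels] + 0.3 * rng.standard_normal((sum(sizes), 5))
    return [X1, X2], labels
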