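import numpy as np
import pytest

from ecgconvit.synthetic import SyntheticDatasetSpec, generate_beats


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_beats():
    """Noise-free, jitter-free beats: 4 per class, perfectly separable."""
    spec = SyntheticDatasetSpec({c: 4 for c in "FNQSV"},
                                noise_sd=0.0, jitter_sd=0.0, seed=0)
    return generate_beats(spec)


@pytest.fixture(scope="session")
def noisy_beats():
    """Small realistic beat set: 12 per class with noise and jitter."""
    spec = SyntheticDatasetSpec({c: 12 for c in "FNQSV"},
                                noise_sd=0.05, jitter_sd=1.0, seed=7)
    return generate_beats(spec)
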