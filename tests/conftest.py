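import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small planted dataset shared by pipeline-level tests."""
    from hganlda import SyntheticSpec, generate_dataset

    spec = SyntheticSpec(
        n_lnc=30, n_dis=24, n_mir=16, n_blocks=4, seq_len_range=(40, 60), seed=7
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_similarities(tiny_dataset):
    from hganlda.io import compute_similarities

    return compute_similarities(tiny_dataset)
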