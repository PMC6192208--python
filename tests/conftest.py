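import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model_v4():
    from cyclebayes import build_model

    return build_model(4)


@pytest.fixture(scope="session")
def truth_v4(model_v4):
    from cyclebayes.synth import preset_truth

    return preset_truth(model_v4)


@pytest.fixture(scope="session")
def reduced_problem():
    """Reduced single-gene posterior with both channels (preset truth, seed 1)."""
    from cyclebayes.synth import reduced_benchmark

    post, truth, design = reduced_benchmark(seed=1)
    return post, truth, design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)
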