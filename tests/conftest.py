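import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230921)


@pytest.fixture(scope="session")
def default_study():
    """One realization of the default two-species synthetic study."""
    from stomapattern import default_design, generate_study

    return generate_study(default_design(), seed=11)


@pytest.fixture(scope="session")
def default_study_stats(default_study):
    from stomapattern import window_stats_table

    patterns, _ = default_study
    return window_stats_table(patterns)
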