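import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from termvib import (
    GeneratorConfig,
    events_frame_from_truth,
    generate_study,
    mixture_cohort,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_study(default_cfg):
    """One 13-colony, 4-treatment synthetic study (ground truth only)."""
    return generate_study(default_cfg, n_colonies=13,
                          rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def truth_events(default_study):
    return events_frame_from_truth(default_study)


@pytest.fixture(scope="session")
def mixture_run():
    """2000 mixture-drawn events pushed through the full pipeline."""
    return mixture_cohort(2000, seed=202)
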