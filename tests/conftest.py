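import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctorigin import SynthRefConfig, build_panel, generate_reference

settings.register_profile(
    "suite",
    settings(
        max_examples=30,
        deadline=None,
        derandomize=True,
        suppress_health_check=[HealthCheck.too_slow],
    ),
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_ref():
    """A compact synthetic study system: 3 tumor classes, 300 clusters."""
    return generate_reference(
        SynthRefConfig(
            T=3,
            K_total=300,
            frac_informative=0.7,
            separation=0.4,
            pool_size=40,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_panel(small_ref):
    """Panel fitted on the full small_ref pools (no partition)."""
    return build_panel(small_ref.pools, 0.25, 5, small_ref.class_names)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
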