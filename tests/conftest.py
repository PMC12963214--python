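import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spectherm import ExpansionParams, PhantomConfig


@pytest.fixture
def liver_params():
    """Thermal-expansion parameters of the swine-liver EDW(T) model."""
    return ExpansionParams(edw_t0=104.0, t0=37.0, b=0.0, c=7.9e-6, d=9.6e-5)


@pytest.fixture
def small_config():
    """A coarse, fast phantom for unit tests: 32^3 grid, 6 scans, 4 sensors."""
    return PhantomConfig(
        shape=(32, 32, 32),
        spacing=(1.5, 1.5, 1.5),
        probe_tip_mm=(24.0, 24.0, 12.0),
        probe_direction=(0.0, 0.0, -1.0),
        thermocouple_tips_mm=(
            (27.0, 24.0, 27.0),
            (24.0, 30.0, 27.0),
            (36.0, 24.0, 25.0),
            (24.0, 6.0, 27.0),
        ),
        scan_times_s=tuple(60.0 * i for i in range(6)),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
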