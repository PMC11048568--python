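import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trpchain as tc

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference_rates() -> tc.RateConstants:
    """The ChCry4 reference rate constants."""
    return tc.chcry4_rates()


@pytest.fixture(scope="session")
def reference_taus() -> dict[str, float]:
    return dict(tc.CHCRY4_TIME_CONSTANTS_PS)


@pytest.fixture(scope="session")
def ps_grid() -> np.ndarray:
    """The study sampling grid: 0..1000 ps at 1 ps."""
    return np.arange(0.0, 1001.0)


@pytest.fixture(scope="session")
def reference_trace(reference_rates, ps_grid) -> tc.OccupationTrace:
    """Noiseless master-equation solution at the reference rates."""
    return tc.propagate(reference_rates, ps_grid)
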