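import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def simple_cv():
    """A tiny triangular CV trace with a hand-built peak in each segment."""
    from voltities import Voltammogram

    E_f = np.linspace(0.0, 0.4, 41)
    E_b = np.linspace(0.4, 0.0, 41)[1:]
    I_f = np.exp(-((E_f - 0.2) ** 2) / 0.004)
    I_b = -np.exp(-((E_b - 0.15) ** 2) / 0.004)
    return Voltammogram(
        potential=np.concatenate([E_f, E_b]),
        current=np.concatenate([I_f, I_b]),
        scan_rate=0.02,
        technique="CV",
        segments=np.array(["forward"] * 41 + ["backward"] * 40),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One noiseless reversible CV at the default grid (session-cached)."""
    from voltities import SimulationConfig, simulate_cv_reversible

    return simulate_cv_reversible(SimulationConfig(area=1.331))
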