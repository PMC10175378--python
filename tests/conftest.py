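import numpy as np
import pytest

from ballastrisk.data_io import MONTHS, PortEnvProfile
from ballastrisk.synthetic_data import ScenarioConfig, generate_scenario


def make_profile(port_id="P", T=None, S=None):
    """Profile helper with sensible defaults (constant 10 degC / 30 psu)."""
    T = np.full(12, 10.0) if T is None else np.asarray(T, dtype=float)
    S = np.full(12, 30.0) if S is None else np.asarray(S, dtype=float)
    return PortEnvProfile(
        port_id=port_id, T=T, S=S, matched_grid_point=(0.0, 0.0), match_distance_km=0.0
    )


def sinusoid_profile(port_id="P", base=10.0, amp=5.0, peak_month=7, S=30.0):
    T = [base + amp * np.cos(2 * np.pi * (m - peak_month) / 12) for m in MONTHS]
    return make_profile(port_id, T=T, S=np.full(12, S))


@pytest.fixture(scope="session")
def default_scenario():
    """One default synthetic world shared across tests (read-only)."""
    return generate_scenario(ScenarioConfig(seed=7))
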