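import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from h2oflux import DEFAULT_ISOTOPES, default_panel

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def patterns():
    """Isotope patterns as plain (shift, abundance) pair lists for the oracles."""
    return {
        el: list(zip(pat.shifts, pat.abundances))
        for el, pat in DEFAULT_ISOTOPES.items()
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20250407)
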