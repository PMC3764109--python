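import pytest
from hypothesis import settings

from hourglass import deterministic_map, make_grid

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fine_dmap():
    """Deterministic sweep at the production mesh 0.0025 (80,000 points)."""
    return deterministic_map(make_grid(0.0025))


@pytest.fixture(scope="session")
def coarse_dmap():
    """Cheap sweep at mesh 0.05 for structural tests."""
    return deterministic_map(make_grid(0.05))
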