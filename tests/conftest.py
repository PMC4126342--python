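import pytest
from hypothesis import settings

from ribostall import PolymerModel, SimulationParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def model() -> PolymerModel:
    return PolymerModel()


@pytest.fixture
def params() -> SimulationParams:
    """Study-condition generator parameters."""
    return SimulationParams()


@pytest.fixture
def fast_params() -> SimulationParams:
    """Shorter traces for unit tests that only need the mechanics."""
    return SimulationParams(baseline_duration=8.0, max_duration=90.0,
                            mrna_codons=40)
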