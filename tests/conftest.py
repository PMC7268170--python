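import pytest
from hypothesis import HealthCheck, settings

from nitroforage import LayerFlags, ModelParameters, run_mutant_table, run_split_root

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def ladder_summaries():
    """Split-root summaries for every model-ladder preset (WT, defaults)."""
    return {
        preset: run_split_root(LayerFlags.preset(preset))
        for preset in ("L0", "L1", "L2", "L3", "L5", "L6", "L7")
    }


@pytest.fixture(scope="session")
def mutant_table():
    """Full-model split-root summary for WT and the three mutants."""
    return run_mutant_table().set_index("plant")
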