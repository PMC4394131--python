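import matplotlib
import pytest

matplotlib.use("Agg")

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "gliomir",
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("gliomir")
except ImportError:  # pragma: no cover
    pass

from gliomir import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_bundle():
    """One full synthetic input bundle at the default study geometry."""
    return simulate_all(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A reduced geometry for fast per-module tests."""
    return SimulationConfig(
        seed=11,
        n_mirna=200,
        n_shared_platform=150,
        n_prognostic=20,
        n_tumors=120,
        n_mrna=400,
        n_de_mrna=60,
        n_target_pairs=500,
    )
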