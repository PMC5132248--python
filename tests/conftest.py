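import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run():
    """A short driven 7-site simulation shared by pipeline-level tests."""
    from porestate import synthetic_data as syn

    model = syn.seven_site_model()
    frames, truth = syn.simulate(model, 5000, seed=7)
    return model, frames, truth


@pytest.fixture(scope="session")
def small_states(small_run):
    """Axial trace + discretized states for the shared short run."""
    from porestate import pore_projection as pp
    from porestate import site_model as sm

    model, frames, truth = small_run
    records = pp.project_trajectory(iter(frames), model.selections())
    states = sm.discretize_trajectory(records, model.site_model())
    return model, records, states, truth
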