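import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crowded_state():
    """Small crowded box (~120 spheres at ~30% occupancy) shared by the
    force/phi oracle tests."""
    import crowdbd as cb

    st = cb.make_crowded_state(n_proteins=40, occupied_fraction=0.30, seed=21)
    st.assign_dilute_diffusion(298.15, 0.891)
    return st


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
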