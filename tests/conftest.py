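import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermotouch as tt

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme():
    return tt.stehfest_weights(10)


@pytest.fixture(scope="session")
def problem():
    """Repository-default slab problem (unfrozen tissue, phi=100, 7 mm)."""
    return tt.default_problem()


@pytest.fixture(scope="session")
def quiescent_problem():
    """Zero-forcing problem: phi=0, Q=0, T_ar=T_i=37 (equilibrium)."""
    return tt.SlabProblem(
        tissue=tt.UNFROZEN_TUMOR_TISSUE,
        blood=tt.BloodPerfusion(perfusion_rate=0.5, arterial_temperature=37.0),
        sources=tt.SourceTerms(metabolic_heat=0.0, surface_flux=0.0),
        geometry=tt.SlabGeometry(thickness=0.007),
        initial_temperature=37.0,
    )


@pytest.fixture(scope="session")
def sphere():
    """10 mm radius icosphere at the origin with the default slab."""
    return tt.make_sphere_surface(radius=0.01)
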