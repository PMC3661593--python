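import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study (12 sites x 2 configurations), shared."""
    from pollinet.simulate import default_presets, generate_study

    return generate_study(default_presets(seed=1))


@pytest.fixture(scope="session")
def default_webs(default_study):
    from pollinet.matrices import build_all_networks

    records, sites = default_study
    return build_all_networks(records, sites)


@pytest.fixture
def rng():
    return np.random.default_rng(20230501)


@pytest.fixture
def random_matrix_factory(rng):
    """Random 5-plant x 9-morphotype webs with canonical labels."""
    from pollinet.matrices import InteractionMatrix, Provenance
    from pollinet.records import MORPHOTYPES, PLANTS

    def make(density: float = 0.6, max_count: int = 50) -> "InteractionMatrix":
        counts = rng.integers(1, max_count + 1, size=(5, 9))
        counts[rng.random((5, 9)) > density] = 0
        return InteractionMatrix(
            plant_labels=list(PLANTS),
            morphotype_labels=list(MORPHOTYPES),
            counts=counts,
            provenance=Provenance(site_id="T1", spatial_config="systematic"),
        )

    return make
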