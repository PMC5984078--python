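import numpy as np
import pytest

from dtimeta import GeneratorConfig, generate_multisite
from dtimeta.skeleton import make_default_atlas
from dtimeta.synthetic import ClinicalParams

FULL_AVAILABILITY = {
    k: 1.0 for k in ("onset", "cpz", "panss", "sans", "saps", "smoker", "med_class")
}


@pytest.fixture(scope="session")
def small_config():
    """3 modest sites with every clinical moderator recorded."""
    return GeneratorConfig(
        n_sites=3,
        n_controls=(40, 80),
        n_patients=(40, 80),
        clinical=ClinicalParams(availability=dict(FULL_AVAILABILITY)),
        seed=20260921,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_multisite(small_config)


@pytest.fixture(scope="session")
def atlas():
    return make_default_atlas(2000)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
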