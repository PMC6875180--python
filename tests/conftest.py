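import numpy as np
import pytest

from netscale import (
    CohortSpec,
    generate_atlas,
    generate_cohort,
    subdivide_atlas,
)


@pytest.fixture(scope="session")
def tiny_atlas():
    """Small ellipsoid atlas with 4 parent regions."""
    return generate_atlas((10, 10, 10), 4, seed=7)


@pytest.fixture(scope="session")
def effect_cohort(tiny_atlas):
    """Two-group cohort with a strong planted effect in regions 1 and 2."""
    spec = CohortSpec(
        n_patients=15,
        n_controls=15,
        n_timepoints=200,
        effect_regions={1, 2},
        effect_size=0.4,
        seed=11,
    )
    return generate_cohort(tiny_atlas, spec)


@pytest.fixture(scope="session")
def tiny_parcellation(tiny_atlas):
    return subdivide_atlas(tiny_atlas, 12, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
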