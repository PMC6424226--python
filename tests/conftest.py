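import numpy as np
import pytest

from cfcpet import LesionSpec, PolarGeometry, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def geometry():
    return PolarGeometry()


@pytest.fixture(scope="session")
def uniform_map(geometry):
    """Uniform normally-perfused map (no lesion, no noise)."""
    return generate_phantom(LesionSpec(core_fraction=0.0,
                                       border_fractions=(0.0, 0.0)),
                            noise_cov=0.0)


@pytest.fixture(scope="session")
def lesion_map(geometry):
    """Noise-free target-pattern phantom: 10% severe core, 10%+10% borders."""
    return generate_phantom(LesionSpec(), noise_cov=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded mid-size cohort shared by the survival-analysis tests."""
    cohort, truth = generate_cohort(8000, seed=123)
    return cohort, truth
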