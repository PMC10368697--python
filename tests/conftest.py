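import numpy as np
import pytest

from skelpatch.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """A compact noisy phantom used across suites."""
    return PhantomSpec(
        volume_shape=(64, 64, 64),
        spacing_mm=(0.3, 0.3, 0.3),
        n_vessels=2,
        vessel_radius_range_mm=(0.6, 1.0),
        n_aneurysms=1,
        aneurysm_diameter_range_mm=(2.5, 4.5),
        rician_sigma=10.0,
        bias_amplitude=0.15,
        curviness=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_spec(small_spec):
    """Noise- and bias-free variant: ground truth is exact."""
    import dataclasses

    return dataclasses.replace(small_spec, rician_sigma=0.0, bias_amplitude=0.0)


@pytest.fixture(scope="session")
def clean_case(clean_spec):
    return generate_phantom(clean_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
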