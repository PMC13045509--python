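import numpy as np
import pytest

from coroquant import PhantomSpec, StenosisSpec, generate_vessel


@pytest.fixture(scope="session")
def lesion_spec() -> PhantomSpec:
    """Small single-slice phantom with one 60% stenosis."""
    return PhantomSpec(
        seed=7,
        n_slices=1,
        shape=(256, 256),
        stenoses=[StenosisSpec(center_mm=45.0, length_mm=12.0, severity_pct=60.0)],
    )


@pytest.fixture(scope="session")
def lesion_phantom(lesion_spec):
    return generate_vessel(lesion_spec)


@pytest.fixture(scope="session")
def clean_spec() -> PhantomSpec:
    """Small phantom with no lesion."""
    return PhantomSpec(seed=11, n_slices=1, shape=(256, 256))


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return generate_vessel(clean_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
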