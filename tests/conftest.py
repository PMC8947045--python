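import numpy as np
import pytest

from vncamarrow.phantom import MarrowDistributionParams, PhantomSpec, calibrate_distribution
from vncamarrow.reference import packaged_reference


@pytest.fixture(scope="session")
def reference_table():
    return packaged_reference()


@pytest.fixture(scope="session")
def female_41_60_max_params():
    """Mixture calibrated to the (female, 41-60, maximum suppression) cell."""
    return calibrate_distribution((-467.5, -382.5, -317.5, -212.5))


@pytest.fixture(scope="session")
def known_mixture():
    return MarrowDistributionParams(mu1=-350.0, sigma1=90.0, mu2=-520.0, sigma2=140.0, weight=0.7)


@pytest.fixture()
def small_phantom_spec(female_41_60_max_params):
    return PhantomSpec(
        n_vertebrae=5,
        body_size_mm=(16.0, 16.0, 12.0),
        marrow={"maximum": female_41_60_max_params},
        seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220309)
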