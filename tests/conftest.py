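import numpy as np
import pytest

from hp13c.synthetic_data import AcquisitionGeometry, BolusModel, KineticModelParams


@pytest.fixture(scope="session")
def default_geometry():
    """Full study geometry: 20 frames / 4 s, 128x128 recon, 5 slices, 8 coils."""
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Reduced spatial grid for phantom-level tests (temporal axis unchanged)."""
    return AcquisitionGeometry(acq_matrix=(16, 16), recon_matrix=(32, 32),
                               n_slices=1, n_coils=2)


@pytest.fixture(scope="session")
def bolus():
    return BolusModel()


@pytest.fixture(scope="session")
def ccrcc_params():
    """Median ccRCC exchange rate with the default effective relaxation."""
    return KineticModelParams(k_pl=0.0065, t1_eff=30.0)


@pytest.fixture(scope="session")
def noiseless_courses(default_geometry, bolus, ccrcc_params):
    from hp13c.synthetic_data import simulate_two_site_exchange

    return simulate_two_site_exchange(ccrcc_params, bolus, default_geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
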