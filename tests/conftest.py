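import numpy as np
import pytest

from mppqtl.ibd import calibrate_junction_density, ibd_posteriors
from mppqtl.simulate import default_map, simulate_study


@pytest.fixture(scope="session")
def study_map():
    return default_map()


@pytest.fixture(scope="session")
def diallel_study():
    """One full diallel replicate at study scale (N=300, 5% missing)."""
    rng = np.random.default_rng(2024)
    return simulate_study("diallel", rng)


@pytest.fixture(scope="session")
def diallel_tensor(study_map, diallel_study):
    plan, founders, arch, mosaics, genotypes, trait = diallel_study
    rho = calibrate_junction_density(
        plan, study_map, 100, np.random.default_rng(2025)
    )
    return ibd_posteriors(plan, founders, genotypes, rho, 0.005)
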