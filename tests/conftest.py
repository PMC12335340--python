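"""Shared fixtures: acquisition defaults and simulated basis sets.

Basis simulation is deterministic but not free, so the full 15-metabolite
bases at TE 40/120 ms and the fitted healthy grid are session-scoped and
shared between unit and acceptance tests.
"""

import pytest

from mrsiglx.lcm_fit import FitConfig, fit_grid
from mrsiglx.spin_sim import (
    AcquisitionParams,
    DEFAULT_BASIS_METABOLITES,
    make_basis_set,
)
from mrsiglx.subregions import exclude_voi_edge
from mrsiglx.synthetic_data import NoiseModel, generate_mrsi_grid, make_healthy_scene


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def basis_small(acq):
    """Glu/Gln/Cr basis at TE 120 ms (phantom-1 metabolites)."""
    return make_basis_set(["Glu", "Gln", "Cr"], 120.0, acq)


@pytest.fixture(scope="session")
def basis_te40(acq):
    return make_basis_set(DEFAULT_BASIS_METABOLITES, 40.0, acq)


@pytest.fixture(scope="session")
def basis_te120(acq):
    return make_basis_set(DEFAULT_BASIS_METABOLITES, 120.0, acq)


@pytest.fixture(scope="session")
def healthy_scene():
    """16x16 healthy-brain scene with the 12x12 VOI (100 interior voxels)."""
    return make_healthy_scene()


@pytest.fixture(scope="session")
def interior_mask(healthy_scene):
    return exclude_voi_edge(healthy_scene.voi_mask)


@pytest.fixture(scope="session")
def fitted_healthy_te120(healthy_scene, basis_te120, interior_mask):
    """Interior-voxel fits of one healthy grid at TE 120, SNR ~27."""
    grid = generate_mrsi_grid(healthy_scene, basis_te120, NoiseModel(), seed=11,
                              target_snr=27.0)
    return fit_grid(grid, basis_te120, FitConfig(), mask=interior_mask), grid


@pytest.fixture(scope="session")
def fitted_healthy_te40(healthy_scene, basis_te40, interior_mask):
    """Interior-voxel fits of the same scene at TE 40 (same seed)."""
    grid = generate_mrsi_grid(healthy_scene, basis_te40, NoiseModel(), seed=11,
                              target_snr=27.0)
    return fit_grid(grid, basis_te40, FitConfig(), mask=interior_mask), grid
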