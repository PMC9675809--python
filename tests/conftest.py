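import numpy as np
import pytest

from meg_seqmem.megsim import (CohortConfig, cohort_geometry, compute_lead_field,
                               make_sensor_array, make_source_grid)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Very small geometry for fast simulation-based tests."""
    return CohortConfig(n_subjects=3, n_sensor_positions=8, grid_spacing_mm=24.0,
                        grid_radius_mm=76.0, seed=123)


@pytest.fixture(scope="session")
def tiny_geometry(tiny_cfg):
    return cohort_geometry(tiny_cfg)


@pytest.fixture(scope="session")
def desk_geometry():
    """Reduced analysis geometry: 64 sensor positions, 12-mm source grid."""
    sensors = make_sensor_array(64)
    grid = make_source_grid(12.0, 76.0)
    lead = compute_lead_field(grid, sensors)
    return sensors, grid, lead


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
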