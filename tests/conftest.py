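import numpy as np
import pytest

import diffusekit as dk


@pytest.fixture(scope="session")
def toy_cell():
    return dk.Lattice(18.0, 18.0, 24.0, laue_group="P4/m")


@pytest.fixture(scope="session")
def au(toy_cell):
    return dk.make_toy_asymmetric_unit(6, 8.0, seed=11, cell=toy_cell)


@pytest.fixture(scope="session")
def unit_model(au):
    return dk.expand_p41(au)


@pytest.fixture(scope="session")
def supercell_model(unit_model):
    return dk.build_supercell(unit_model, (2, 2, 2))


@pytest.fixture(scope="session")
def unit_grid(unit_model):
    return dk.ReciprocalGrid.for_model(unit_model, d_min=2.5)


@pytest.fixture(scope="session")
def super_grid(supercell_model):
    return dk.ReciprocalGrid.for_model(supercell_model, d_min=2.5)


@pytest.fixture
def random_map(unit_grid):
    """Factory for random measured maps on the unit-cell toy grid."""

    def make(seed=0, positive=False):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal(unit_grid.shape)
        if positive:
            vals = np.abs(vals) + 0.1
        return dk.DiffuseMap(
            grid=unit_grid,
            values=vals,
            measured=unit_grid.in_sphere.copy(),
            provenance="synthetic",
        )

    return make


@pytest.fixture(scope="session")
def detector_geometry():
    return dk.DetectorGeometry(
        distance_mm=80.0,
        pixel_mm=0.3,
        wavelength=1.54,
        shape=(128, 128),
        beam_center=(63.5, 63.5),
    )
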