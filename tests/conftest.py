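import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bdgrid as bg

settings.register_profile(
    "default", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def solvent_5mm():
    return bg.SolventModel.monovalent(0.005)


@pytest.fixture(scope="session")
def solvent_300mm():
    return bg.SolventModel.monovalent(0.300)


@pytest.fixture(scope="session")
def sphere_system_small(solvent_5mm):
    """Two +3/+3 test spheres with a small (40 Å) analytic grid: cheap to
    build, keeps the grid/DH switch radius at ~14 Å."""
    return bg.make_sphere_system(3.0, 3.0, solvent_5mm, grid_side=40.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def dh_sphere_solute(z: float, stokes_radius: float) -> bg.Solute:
    """Grid-free point solute for the analytic DH-sphere engine path."""
    atoms = bg.AtomSet(np.zeros((1, 3)), np.array([float(z)]),
                       np.array([stokes_radius]))
    return bg.Solute(atoms, stokes_radius=stokes_radius)
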