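import numpy as np
import pytest

from rudimorph.poro import BiphasicSolver, BoundaryConditions, LoadProgram, PoroMaterial
from rudimorph.synthetic import LimbSpec, make_humerus_mesh, make_limb_surface


@pytest.fixture(scope="session")
def default_spec():
    return LimbSpec()


@pytest.fixture(scope="session")
def limb_surface(default_spec):
    return make_limb_surface(default_spec, resolution=96)


@pytest.fixture(scope="session")
def humerus_mesh(default_spec):
    return make_humerus_mesh(default_spec)


@pytest.fixture(scope="session")
def material():
    return PoroMaterial()


@pytest.fixture(scope="session")
def cycle_history(humerus_mesh, material):
    bc = BoundaryConditions.humerus(humerus_mesh)
    solver = BiphasicSolver(humerus_mesh, material, bc)
    return solver.solve_cycle(LoadProgram())


@pytest.fixture(scope="session")
def humerus_bc(humerus_mesh):
    return BoundaryConditions.humerus(humerus_mesh)
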