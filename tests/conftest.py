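import numpy as np
import pytest
from hypothesis import settings

from scaffoldsim.geometry import UnitDesign, VoxelDomain, voxelize
from scaffoldsim.kinetics import KineticParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def params():
    return KineticParams()


@pytest.fixture
def improved_design():
    """Best single-cultured-fiber design from the first campaign."""
    return UnitDesign(r=100.0, delta_y=7.0, delta_z=90.0)


@pytest.fixture
def reference_design():
    """All four fibers inscribed: D1 = D2 = 200 um."""
    return UnitDesign(r=100.0, delta_y=100.0, delta_z=100.0)


@pytest.fixture
def small_domain(improved_design):
    return voxelize(improved_design, 16)


def empty_duct(nx, ny, nz, Lx_um=200.0, Ly_um=200.0, Lz_um=200.0):
    """Open rectangular duct with flat no-slip walls."""
    labels = np.zeros((nx, ny, nz), dtype=np.int8)
    return VoxelDomain(labels=labels,
                       spacing_um=(Lx_um / nx, Ly_um / ny, Lz_um / nz))
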