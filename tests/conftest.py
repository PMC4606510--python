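import numpy as np
import pytest

from sigdiff.geometry import CellGeometrySpec, build_cell_mesh
from sigdiff.verification import generate_fixture


@pytest.fixture(scope="session")
def annulus2d():
    """Coarse 2D annulus (outer circle tag 1, inner circle tag 2)."""
    return build_cell_mesh(
        CellGeometrySpec(kind="sphere_shell", outer=2.0, nucleus=1.0,
                         target_h=0.4, dim=2)
    )


@pytest.fixture(scope="session")
def sphere_shell_coarse():
    """Coarse 3D sphere shell at cell scale (R=5, nucleus 3)."""
    return build_cell_mesh(
        CellGeometrySpec(kind="sphere_shell", outer=5.0, nucleus=3.0, target_h=1.5)
    )


@pytest.fixture(scope="session")
def box_shell_coarse():
    return build_cell_mesh(
        CellGeometrySpec(kind="box_shell", outer=(30, 20, 10), nucleus=(10, 8, 6),
                         target_h=2.5)
    )


@pytest.fixture(scope="session")
def lattice_center_secreter():
    """3x3x3 lattice with exactly one secreting cell at the centroid."""
    return generate_fixture("lattice_case", seed=1, grid=(3, 3, 3), target_h=2.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20151014)
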