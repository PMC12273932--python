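import numpy as np
import pytest

from myofat import SynthGeomParams, generate_synthetic_ta, mesh_box, promote_to_quadratic


@pytest.fixture(scope="session")
def coarse_params():
    """Coarse discretisation of the default muscle used throughout the
    solver-level tests (quadratic promotion lands in the mid-thousands of
    degrees of freedom)."""
    return SynthGeomParams(nx=4, ny=4, nz=10)


@pytest.fixture(scope="session")
def coarse_ta(coarse_params):
    return generate_synthetic_ta(coarse_params)


@pytest.fixture(scope="session")
def default_ta():
    return generate_synthetic_ta(SynthGeomParams())


@pytest.fixture(scope="session")
def bar_quadratic():
    """10 x 10 x 20 mm bar of quadratic tets with box facet sets."""
    return promote_to_quadratic(mesh_box(10, 10, 20, 1, 1, 2))


@pytest.fixture(scope="session")
def study():
    """The coarse fixed-end contraction batch (runs once per session); the
    expensive shared input of the whole-pipeline checks."""
    from myofat.pipeline import coarse_study

    return coarse_study(seed=0)


def bar_axial_bc(mesh):
    """Ends fixed axially, rigid modes pinned; lateral surfaces free."""
    from myofat.solver import BoundarySpec

    c = mesh.node_coords
    n000 = int(np.flatnonzero((np.abs(c) < 1e-9).all(axis=1))[0])
    n100 = int(np.flatnonzero((np.abs(c - [10, 0, 0]) < 1e-9).all(axis=1))[0])
    return BoundarySpec(
        fixed={"z0": (False, False, True), "z1": (False, False, True)},
        fixed_nodes=[([n000], (True, True, False)), ([n100], (False, True, False))],
    )
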