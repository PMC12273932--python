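"""FE solver: assembly consistency, closed-form bar oracles, invariances.

These tests run on small bar meshes (seconds); the whole-muscle contraction
behaviour is covered by the acceptance suite.
"""

import numpy as np
import pytest

from myofat import mesh_box, promote_to_quadratic
from myofat.materials import MuscleFatParams
from myofat.solver import BoundarySpec, FEProblem, SolverConfig, solve_contraction

from conftest import bar_axial_bc


@pytest.fixture(scope="module")
def bar_problem(bar_quadratic):
    n = bar_quadratic.n_elems
    fib = np.tile([0.0, 0.0, 1.0], (n, 1))
    return FEProblem(bar_quadratic, fib, np.zeros(n), bc=bar_axial_bc(bar_quadratic))


def test_zero_residual_at_reference(bar_problem):
    u = np.zeros((bar_problem.mesh.n_nodes, 3))
    r = bar_problem.residual(u, activation=0.0)
    assert np.abs(r).max() == pytest.approx(0.0, abs=1e-14)


def test_residual_is_energy_gradient(bar_problem):
    """Global residual equals the finite difference of total energy."""
    rng = np.random.default_rng(0)
    u = 0.02 * rng.standard_normal((bar_problem.mesh.n_nodes, 3))
    r = bar_problem.residual(u, activation=0.3)
    h = 1e-7
    for node, comp in [(5, 0), (12, 2), (20, 1)]:
        up = u.copy()
        up[node, comp] += h
        um = u.copy()
        um[node, comp] -= h
        fd = (bar_problem.energy(up, 0.3) - bar_problem.energy(um, 0.3)) / (2 * h)
        assert r[node, comp] == pytest.approx(fd, rel=1e-6)


def test_tangent_residual_consistency(bar_problem):
    """Taylor test: the first-order remainder shrinks linearly in epsilon
    (slope 2 of the error in the step)."""
    rng = np.random.default_rng(1)
    n = bar_problem.mesh.n_nodes
    u = 0.02 * rng.standard_normal((n, 3))
    r0 = bar_problem.residual(u, 0.4).ravel()
    K = bar_problem.tangent(u, 0.4)
    v = rng.standard_normal(3 * n)
    v /= np.linalg.norm(v)
    errs = []
    for eps in (1e-2, 1e-3):
        r1 = bar_problem.residual(u + eps * v.reshape(-1, 3), 0.4).ravel()
        errs.append(np.linalg.norm(r1 - r0 - eps * (K @ v)))
    assert errs[1] < 0.02 * errs[0]  # quadratic remainder


def test_homogeneous_state_is_equilibrium(bar_problem):
    """Patch consistency: a homogeneous deformation has zero residual at
    every interior node."""
    mesh = bar_problem.mesh
    F = np.array([[1.02, 0.01, 0.0], [0.0, 0.99, 0.0], [0.0, 0.01, 1.03]])
    u = mesh.node_coords @ (F - np.eye(3)).T
    r = bar_problem.residual(u, activation=0.0)
    from myofat.mesh import boundary_face_pairs

    bnodes = mesh.face_nodes(boundary_face_pairs(mesh.corners))
    interior = np.setdiff1d(np.arange(mesh.n_nodes), bnodes)
    assert interior.size > 0
    assert np.abs(r[interior]).max() < 1e-10 * np.abs(r).max()


@pytest.fixture(scope="module")
def solves(bar_quadratic):
    """Fixed-end bar contractions at three fat levels (shared oracle runs)."""
    n = bar_quadratic.n_elems
    fib = np.tile([0.0, 0.0, 1.0], (n, 1))
    bc = bar_axial_bc(bar_quadratic)
    cfg = SolverConfig(n_steps=5)
    out = {}
    for xf in (0.0, 50.0, 100.0):
        out[xf] = solve_contraction(bar_quadratic, fib, np.full(n, xf), bc=bc, cfg=cfg)
    return out


class TestFixedEndBar:
    """Closed-form oracle: a bar with fibers along its axis, ends fixed
    axially and free laterally, transmits the specific tension at full
    activation (nominal traction sigma_max f_active(1) = 0.3 MPa)."""

    def test_nominal_traction_matches_specific_tension(self, solves):
        res = solves[0.0]
        assert res.converged
        traction = res.reactions["z1"][-1][2] / 100.0  # 10x10 mm section
        assert traction == pytest.approx(0.3, rel=0.01)

    def test_mixture_traction_linear_in_fat(self, solves):
        f0 = solves[0.0].reactions["z1"][-1][2]
        f50 = solves[50.0].reactions["z1"][-1][2]
        assert f50 / f0 == pytest.approx(0.5, rel=0.01)

    def test_full_fat_inert(self, solves):
        res = solves[100.0]
        assert res.converged
        assert np.abs(res.displacements).max() < 1e-9
        assert res.force < 1e-6

    def test_reactions_balance(self, solves):
        res = solves[0.0]
        total = res.reactions["z0"][-1] + res.reactions["z1"][-1]
        assert np.linalg.norm(total) < 1e-6 * np.linalg.norm(res.reactions["z1"][-1])

    def test_force_monotone_in_activation(self, solves):
        fz = solves[0.0].reactions["z1"][:, 2]
        assert np.all(np.diff(fz) > -1e-9)

    def test_rotated_problem_rotates_reactions(self, bar_quadratic, solves):
        """Rotating mesh + fibers rotates the reaction; magnitude invariant."""
        from scipy.spatial.transform import Rotation

        Q = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        mesh = bar_quadratic
        rot = promote_to_quadratic(mesh_box(10, 10, 20, 1, 1, 2))
        rot.node_coords = mesh.node_coords @ Q.T
        rot.long_axis = Q @ mesh.long_axis
        n = rot.n_elems
        fib = np.tile(Q @ [0.0, 0.0, 1.0], (n, 1))
        # axis-aligned component masks cannot express rotated pins, so both
        # problems clamp the end faces fully
        ref = solve_contraction(
            mesh, np.tile([0.0, 0.0, 1.0], (n, 1)), np.zeros(n),
            bc=BoundarySpec(fixed={"z0": (True, True, True), "z1": (True, True, True)}),
            cfg=SolverConfig(n_steps=5),
        )
        rotres = solve_contraction(
            rot, fib, np.zeros(n),
            bc=BoundarySpec(fixed={"z0": (True, True, True), "z1": (True, True, True)}),
            cfg=SolverConfig(n_steps=5),
        )
        Fref = ref.reactions["z1"][-1]
        Frot = rotres.reactions["z1"][-1]
        assert np.linalg.norm(Frot) == pytest.approx(np.linalg.norm(Fref), rel=1e-6)
        assert np.allclose(Frot, Q @ Fref, atol=1e-6 * np.linalg.norm(Fref))


def test_sensitivity_sweep_constant_without_fat(bar_quadratic):
    """With no fat anywhere the fat modulus cannot matter."""
    from myofat.solver import sensitivity_sweep_Gf

    n = bar_quadratic.n_elems
    fib = np.tile([0.0, 0.0, 1.0], (n, 1))
    bc = bar_axial_bc(bar_quadratic)
    table = sensitivity_sweep_Gf(
        bar_quadratic, fib, np.zeros(n), values_mpa=[0.001, 0.015, 0.5],
        bc=bc, cfg=SolverConfig(n_steps=3),
    )
    assert table["converged"].all()
    assert table["force_N"].std() < 1e-9 * table["force_N"].mean()
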