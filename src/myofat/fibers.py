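"""Fiber directions from a Laplace potential solve.

The fiber architecture is generated by solving a Laplace problem on the
tet mesh with Dirichlet value 1 on the fiber-origin (inlet) surfaces and 0
on the fiber-insertion (outlet) surfaces, zero natural flux elsewhere.
For incompressible irrotational flow the velocity field is the potential
gradient, so this reproduces the streamline topology of a pressure-driven
slip-wall flow between the same surfaces while staying on the mechanics
mesh: per (linear) element the fiber direction is the normalised negative
potential gradient.

For the muscle domain the inlet is the proximal aponeurosis interface
plus the tibial origin strip and the outlet is the muscle surface of the
central aponeurosis; for the central aponeurosis the inlet/outlet are its
proximal/distal ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .mesh import (
    CENTRAL_APONEUROSIS,
    MUSCLE,
    PROXIMAL_APONEUROSIS,
    MeshError,
    TetMesh,
)

__all__ = ["PotentialField", "FiberField", "solve_laplace", "fiber_directions", "ta_fiber_field"]


@dataclass
class PotentialField:
    """Nodal solution of the Laplace problem on a mesh subdomain."""

    node_values: np.ndarray  # (n_nodes,), NaN outside the subdomain
    elems: np.ndarray  # element indices of the subdomain
    inlet_nodes: np.ndarray
    outlet_nodes: np.ndarray
    _K: sp.csr_matrix = field(repr=False, default=None)  # subdomain stiffness
    _nodes: np.ndarray = field(repr=False, default=None)  # subdomain node ids

    def flux(self, nodes: np.ndarray) -> float:
        """Total discrete flux through the given Dirichlet nodes
        (sum of stiffness-residual entries; inlet and outlet balance)."""
        local = {int(n): i for i, n in enumerate(self._nodes)}
        idx = [local[int(n)] for n in np.atleast_1d(nodes) if int(n) in local]
        r = self._K @ self.node_values[self._nodes]
        return float(r[idx].sum())


@dataclass
class FiberField:
    """Per-element unit fiber directions (zeros outside the solved domain)."""

    directions: np.ndarray  # (n_elems, 3)
    elems: np.ndarray
    filled_from_neighbor: np.ndarray  # element ids whose gradient vanished

    def merge(self, other: "FiberField") -> "FiberField":
        d = self.directions.copy()
        d[other.elems] = other.directions[other.elems]
        return FiberField(
            directions=d,
            elems=np.union1d(self.elems, other.elems),
            filled_from_neighbor=np.union1d(self.filled_from_neighbor, other.filled_from_neighbor),
        )


def _resolve_nodes(mesh: TetMesh, selector) -> np.ndarray:
    """Facet-set name(s) or explicit node arrays -> unique node ids."""
    if isinstance(selector, str):
        selector = [selector]
    parts = []
    for s in selector:
        if isinstance(s, str):
            parts.append(mesh.facet_set_nodes(s))
        else:
            parts.append(np.asarray(s, dtype=np.int64).ravel())
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(parts))


def _p1_gradients(coords: np.ndarray, conn: np.ndarray):
    """Constant shape-function gradients and volumes of linear tets."""
    x = coords[conn[:, :4]]
    d = x[:, 1:] - x[:, :1]  # (n, 3, 3) rows = edge vectors
    vol = np.linalg.det(d) / 6.0
    dinv = np.linalg.inv(d)
    g123 = np.transpose(dinv, (0, 2, 1))  # gradients of N1..N3
    g0 = -g123.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g123], axis=1), vol  # (n, 4, 3), (n,)


def solve_laplace(
    mesh: TetMesh,
    inlet,
    outlet,
    domain: int | list[int] | None = None,
    tol: float = 1e-12,
) -> PotentialField:
    """P1 finite-element Laplace solve with Dirichlet 1 on ``inlet`` and 0
    on ``outlet`` node sets (facet-set names or node arrays); natural
    zero-flux conditions on every other surface."""
    if domain is None:
        elems = np.arange(mesh.n_elems)
    else:
        domain = [domain] if np.isscalar(domain) else list(domain)
        elems = np.flatnonzero(np.isin(mesh.elem_domain, domain))
    if elems.size == 0:
        raise MeshError("empty domain for Laplace solve")
    conn = mesh.corners[elems]
    nodes = np.unique(conn)
    local = -np.ones(mesh.n_nodes, dtype=np.int64)
    local[nodes] = np.arange(nodes.size)
    lconn = local[conn]

    grads, vol = _p1_gradients(mesh.node_coords, conn)
    ke = np.einsum("e,eai,ebi->eab", vol, grads, grads)
    rows = np.repeat(lconn, 4, axis=1).ravel()
    cols = np.tile(lconn, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(nodes.size, nodes.size)).tocsr()

    inlet_nodes = _resolve_nodes(mesh, inlet)
    outlet_nodes = _resolve_nodes(mesh, outlet)
    inlet_nodes = inlet_nodes[local[inlet_nodes] >= 0]
    outlet_nodes = outlet_nodes[local[outlet_nodes] >= 0]
    if inlet_nodes.size == 0 or outlet_nodes.size == 0:
        raise MeshError("inlet and outlet node sets must be non-empty on the domain")
    if np.intersect1d(inlet_nodes, outlet_nodes).size:
        raise MeshError("inlet and outlet node sets overlap")

    u = np.zeros(nodes.size)
    u[local[inlet_nodes]] = 1.0
    fixed = np.zeros(nodes.size, dtype=bool)
    fixed[local[inlet_nodes]] = True
    fixed[local[outlet_nodes]] = True
    free = ~fixed
    rhs = -K[free][:, fixed] @ u[fixed]
    Kff = K[free][:, free]
    try:
        u_free = spla.spsolve(Kff.tocsc(), rhs)
    except Exception as exc:  # singular system
        raise MeshError(f"singular Laplace system (disconnected domain?): {exc}") from exc
    if not np.all(np.isfinite(u_free)):
        raise MeshError("singular Laplace system: solver returned non-finite values")
    u[free] = u_free
    res = np.linalg.norm((K @ u)[free])
    if res > max(tol, 1e-9 * np.linalg.norm(K @ u)):
        raise MeshError(f"Laplace residual {res:.2e} above tolerance")

    full = np.full(mesh.n_nodes, np.nan)
    full[nodes] = u
    return PotentialField(
        node_values=full,
        elems=elems,
        inlet_nodes=inlet_nodes,
        outlet_nodes=outlet_nodes,
        _K=K,
        _nodes=nodes,
    )


def fiber_directions(
    mesh: TetMesh,
    potential: PotentialField,
    flip_reference: np.ndarray | None = None,
    zero_tol: float = 1e-12,
) -> FiberField:
    """Per-element unit directions = normalised negative potential gradient.

    Elements whose gradient norm (relative to the field scale) falls below
    ``zero_tol`` inherit the direction of the nearest resolved element and
    are reported in ``filled_from_neighbor``.  The sign is chosen so
    ``dot(direction, flip_reference) >= 0`` (default reference: the
    distal-pointing long axis).
    """
    elems = potential.elems
    conn = mesh.corners[elems]
    grads, _ = _p1_gradients(mesh.node_coords, conn)
    u = potential.node_values[conn]
    g = -np.einsum("ea,eai->ei", u, grads)
    norms = np.linalg.norm(g, axis=1)
    scale = norms.max()
    if scale <= 0:
        raise MeshError("potential gradient vanishes on the whole domain")
    ok = norms > zero_tol * scale
    d = np.zeros_like(g)
    d[ok] = g[ok] / norms[ok][:, None]
    filled = elems[~ok]
    if filled.size:
        cen = mesh.node_coords[conn].mean(axis=1)
        tree = cKDTree(cen[ok])
        _, j = tree.query(cen[~ok])
        d[~ok] = d[np.flatnonzero(ok)[j]]

    ref = (
        np.asarray(flip_reference, dtype=float)
        if flip_reference is not None
        else -mesh.long_axis
    )
    flip = d @ ref < 0
    d[flip] *= -1.0

    directions = np.zeros((mesh.n_elems, 3))
    directions[elems] = d
    return FiberField(directions=directions, elems=elems, filled_from_neighbor=filled)


def ta_fiber_field(mesh: TetMesh) -> tuple[FiberField, dict[str, PotentialField]]:
    """Fiber directions for all domains of a synthetic/imported TA mesh.

    Muscle: inlet = proximal aponeurosis interface + tibial origin, outlet
    = central aponeurosis interface.  Central aponeurosis: inlet = its
    proximal (interior) end, outlet = distal end.  Proximal aponeurosis
    extrusion: inlet = its proximal face, outlet = the muscle interface.
    """
    pots: dict[str, PotentialField] = {}
    pot_m = solve_laplace(
        mesh,
        inlet=["proximal_apo_inlet", "tibial_origin"],
        outlet=["muscle_insertion_interface"],
        domain=MUSCLE,
    )
    pots["muscle"] = pot_m
    fibers = fiber_directions(mesh, pot_m)

    # central aponeurosis: proximal (interior) sheet end by length coordinate
    capo = np.flatnonzero(mesh.elem_domain == CENTRAL_APONEUROSIS)
    capo_nodes = np.unique(mesh.corners[capo])
    s = (mesh.node_coords[capo_nodes] - mesh.distal_point) @ mesh.long_axis
    top = capo_nodes[s >= s.max() - 1e-6 * mesh.muscle_length()]
    pot_c = solve_laplace(mesh, inlet=[top], outlet=["distal_apo_end"], domain=CENTRAL_APONEUROSIS)
    pots["central_aponeurosis"] = pot_c
    fibers = fibers.merge(fiber_directions(mesh, pot_c))

    if (mesh.elem_domain == PROXIMAL_APONEUROSIS).any():
        pot_p = solve_laplace(
            mesh,
            inlet=["proximal_apo_end"],
            outlet=["proximal_apo_inlet"],
            domain=PROXIMAL_APONEUROSIS,
        )
        pots["proximal_aponeurosis"] = pot_p
        fibers = fibers.merge(fiber_directions(mesh, pot_p))
    return fibers, pots
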