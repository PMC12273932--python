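"""Quasi-static nonlinear finite-element solver for fixed-end contraction.

Total-Lagrangian displacement formulation on linear (4-node) or quadratic
(10-node) tetrahedra.  Activation is ramped from 0 to 1 under zero-
displacement constraints at the aponeurosis ends and the tibial origin;
each increment is equilibrated with Newton's method (adaptive increment
halving on failure) and the transmitted force is read as the reaction
resultant on the distal aponeurosis end.

Quadratic tets are the default for muscle mechanics: with bulk-to-shear
ratios of order 10^4 linear tetrahedra lock volumetrically and are kept
only for fast smoke tests.  The tangent matrix is assembled by forward
differencing of the element internal-force vector; the analytic Cauchy
stress of :mod:`myofat.materials` defines the residual.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import AponeurosisParams, MuscleFatParams, aponeurosis_stress, mixture_stress
from .materials import aponeurosis_energy, mixture_energy, _det3, _inv3
from . import _kernels as _kern
from .mesh import MUSCLE, MeshError, TetMesh

__all__ = [
    "BoundarySpec",
    "SolverConfig",
    "SimulationResult",
    "FEProblem",
    "solve_contraction",
    "sensitivity_sweep_Gf",
]

#: 4-point Gauss rule for tetrahedra (degree 2), barycentric coordinates
_TET4GP_A = 0.5854101966249685
_TET4GP_B = 0.1381966011250105


@dataclass
class BoundarySpec:
    """Facet sets held fixed (component mask per set).

    Default: distal and proximal aponeurosis ends and the tibial origin,
    each fully fixed in x, y and z.
    """

    fixed: dict[str, tuple[bool, bool, bool]] = field(
        default_factory=lambda: {
            "distal_apo_end": (True, True, True),
            "proximal_apo_end": (True, True, True),
            "tibial_origin": (True, True, True),
        }
    )
    #: extra node-level constraints [(node_ids, comps)], e.g. rigid-mode pins
    fixed_nodes: list = field(default_factory=list)


@dataclass
class SolverConfig:
    n_steps: int = 10  # activation increments 0 -> 1
    newton_rtol: float = 1e-8  # relative residual tolerance
    newton_atol: float = 1e-3  # absolute residual floor (N)
    max_newton_iter: int = 500
    line_search: bool = True
    min_step: float = 1.0 / 160.0  # smallest activation increment
    reuse_tangent: bool = True  # modified Newton while convergence is fast
    tr_radius0: float = 2.0  # initial trust radius (mm)
    tr_radius_max: float = 60.0
    tr_radius_min: float = 1e-4
    fat_steps: int = 1  # fat-field continuation increments for warm starts
    verbose: bool = False


@dataclass
class SimulationResult:
    activation: np.ndarray  # converged activation levels
    displacements: np.ndarray  # (n_nodes, 3) at final converged state
    reactions: dict[str, np.ndarray]  # set -> (n_steps, 3) resultants (N)
    forces: np.ndarray  # |distal_apo_end resultant| per step (N)
    converged: bool
    log: list = field(default_factory=list)

    @property
    def force(self) -> float:
        """Scalar model force: distal reaction magnitude at the last
        converged activation level (N)."""
        return float(self.forces[-1]) if len(self.forces) else 0.0

    def reaction_force(self, facet_set: str) -> np.ndarray:
        """Final reaction resultant (3-vector, N) on a constrained set."""
        return self.reactions[facet_set][-1]


# ----------------------------------------------------------------------


def _force_reaction(reactions: dict) -> np.ndarray:
    """Reaction used for the scalar model force: the distal aponeurosis
    end where present, otherwise the first constrained set."""
    if "distal_apo_end" in reactions:
        return reactions["distal_apo_end"]
    if reactions:
        return next(iter(reactions.values()))
    return np.zeros(3)


def _tet10_shape(gp: np.ndarray):
    """TET10 shape values / local gradients at barycentric points."""
    L0 = 1.0 - gp.sum(axis=1)
    L = np.column_stack([L0, gp])  # (ngp, 4)
    dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    edges = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]
    ngp = gp.shape[0]
    N = np.zeros((ngp, 10))
    dN = np.zeros((ngp, 10, 3))
    for i in range(4):
        N[:, i] = L[:, i] * (2.0 * L[:, i] - 1.0)
        dN[:, i] = (4.0 * L[:, i] - 1.0)[:, None] * dL[i]
    for k, (a, b) in enumerate(edges):
        N[:, 4 + k] = 4.0 * L[:, a] * L[:, b]
        dN[:, 4 + k] = 4.0 * (L[:, a][:, None] * dL[b] + L[:, b][:, None] * dL[a])
    return N, dN


def _tet4_shape(gp: np.ndarray):
    L0 = 1.0 - gp.sum(axis=1)
    N = np.column_stack([L0, gp])
    dN = np.tile(
        np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])[None],
        (gp.shape[0], 1, 1),
    )
    return N, dN


class FEProblem:
    """Precomputed discrete problem: quadrature, gradients, materials, BCs."""

    def __init__(
        self,
        mesh: TetMesh,
        fiber_directions: np.ndarray,
        fat_percent: np.ndarray,
        muscle_params: MuscleFatParams | None = None,
        apo_params: AponeurosisParams | None = None,
        bc: BoundarySpec | None = None,
    ):
        self.mesh = mesh
        self.mp = muscle_params or MuscleFatParams()
        self.ap = apo_params or AponeurosisParams()
        self.bc = bc or BoundarySpec()
        self.fibers = np.asarray(fiber_directions, dtype=float)
        self.fat = np.asarray(fat_percent, dtype=float)
        if self.fat.shape[0] != mesh.n_elems or self.fibers.shape[0] != mesh.n_elems:
            raise ValueError("fiber/fat arrays must be per-element")

        npe = mesh.tet_conn.shape[1]
        if npe == 10:
            a, b = _TET4GP_A, _TET4GP_B
            gp = np.array([[b, b, b], [a, b, b], [b, a, b], [b, b, a]])
            w = np.full(4, 0.25)
            _, dN = _tet10_shape(gp)
        else:
            gp = np.full((1, 3), 0.25)
            w = np.array([1.0])
            _, dN = _tet4_shape(gp)
        self.ngp, self.npe = gp.shape[0], npe

        conn = mesh.tet_conn
        x = mesh.node_coords[conn[:, :4]]
        Jm = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=-1)
        detJ = np.linalg.det(Jm)
        if np.any(detJ <= 0):
            raise MeshError("mesh contains inverted elements")
        Jinv = np.linalg.inv(Jm)
        # dN/dX = dN/dxi @ J^-1 ; (nelem, ngp, npe, 3)
        self.dNdX = np.einsum("gaj,eji->egai", dN, Jinv)
        self.wvol = (detJ / 6.0)[:, None] * w[None, :]  # (nelem, ngp)
        self.volume = self.wvol.sum()

        self.muscle_mask = mesh.elem_domain == MUSCLE
        self.apo_mask = ~self.muscle_mask
        self._use_fast = _kern.HAVE_NUMBA
        # per-GP broadcast copies of element fields
        self._fib_gp = np.repeat(self.fibers[:, None, :], self.ngp, axis=1)
        self._fat_gp = np.repeat(self.fat[:, None], self.ngp, axis=1)

        # Dirichlet dofs and per-set node attribution (priority = dict order)
        self.fixed_mask = np.zeros((mesh.n_nodes, 3), dtype=bool)
        self.set_nodes: dict[str, np.ndarray] = {}
        claimed = np.zeros(mesh.n_nodes, dtype=bool)
        for name, comps in self.bc.fixed.items():
            nodes = mesh.facet_set_nodes(name)
            self.fixed_mask[nodes] |= np.asarray(comps, dtype=bool)
            fresh = nodes[~claimed[nodes]]
            claimed[fresh] = True
            self.set_nodes[name] = fresh
        for nodes, comps in self.bc.fixed_nodes:
            self.fixed_mask[np.asarray(nodes, dtype=np.int64)] |= np.asarray(comps, dtype=bool)
        if not self.fixed_mask.any():
            raise MeshError("boundary spec constrains no nodes")
        self.free = ~self.fixed_mask.ravel()

    # ------------------------------------------------------------------
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.mesh.tet_conn]  # (nelem, npe, 3)
        F = np.einsum("eai,egaj->egij", ue, self.dNdX)
        F += np.eye(3)
        return F

    def _stress(self, F: np.ndarray, activation: float) -> np.ndarray:
        """Cauchy stress per element/GP, material chosen by domain."""
        sig = np.empty_like(F)
        mm = self.muscle_mask
        if mm.any():
            sig[mm] = mixture_stress(
                F[mm], self._fib_gp[mm], activation, self._fat_gp[mm], self.mp
            )
        am = self.apo_mask
        if am.any():
            sig[am] = aponeurosis_stress(F[am], self._fib_gp[am], self.ap)
        return sig

    def energy(self, u: np.ndarray, activation: float) -> float:
        """Total strain energy (N mm)."""
        F = self.deformation_gradients(u)
        W = np.empty(F.shape[:2])
        mm, am = self.muscle_mask, self.apo_mask
        if mm.any():
            W[mm] = mixture_energy(F[mm], self._fib_gp[mm], activation, self._fat_gp[mm], self.mp)
        if am.any():
            W[am] = aponeurosis_energy(F[am], self._fib_gp[am], self.ap)
        return float((W * self.wvol).sum())

    def _forces_kernel(self, ue, dNdX, wvol, fib_gp, fat_gp, mmask, amask, activation):
        if self._use_fast:
            return _kern.element_forces(
                np.ascontiguousarray(ue),
                np.ascontiguousarray(dNdX),
                np.ascontiguousarray(wvol),
                np.ascontiguousarray(fib_gp[:, 0, :]),
                activation,
                np.ascontiguousarray(fat_gp[:, 0]),
                np.ascontiguousarray(mmask),
                self.mp,
                self.ap,
            )
        F = np.einsum("eai,egaj->egij", ue, dNdX) + np.eye(3)
        J = _det3(F)
        if np.any(J <= 0):
            raise FloatingPointError("element inversion")
        sig = np.empty_like(F)
        if mmask.any():
            sig[mmask] = mixture_stress(
                F[mmask], fib_gp[mmask], activation, fat_gp[mmask], self.mp
            )
        if amask.any():
            sig[amask] = aponeurosis_stress(F[amask], fib_gp[amask], self.ap)
        # first Piola P = J sig F^-T
        P = J[..., None, None] * sig @ np.swapaxes(_inv3(F, J), -1, -2)
        return np.einsum("eg,egij,egaj->eai", wvol, P, dNdX)

    def _elem_forces(self, ue: np.ndarray, activation: float) -> np.ndarray:
        """Element internal-force vectors (nelem, npe, 3) for element
        displacement block ``ue``."""
        return self._forces_kernel(
            ue,
            self.dNdX,
            self.wvol,
            self._fib_gp,
            self._fat_gp,
            self.muscle_mask,
            self.apo_mask,
            activation,
        )

    def residual(self, u: np.ndarray, activation: float) -> np.ndarray:
        """Global internal-force vector (n_nodes, 3); the discrete energy
        gradient.  No external loads, so this is also the out-of-balance
        force."""
        fe = self._elem_forces(u[self.mesh.tet_conn], activation)
        r = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(r, self.mesh.tet_conn.ravel(), fe.reshape(-1, 3))
        return r

    def tangent(self, u: np.ndarray, activation: float, h: float | None = None) -> sp.csr_matrix:
        """Consistent tangent by forward differencing of element forces.

        Perturbed element-force evaluations are batched over degrees of
        freedom (chunked to bound memory) so the constitutive routines run
        on large arrays instead of 3*npe separate small calls."""
        conn = self.mesh.tet_conn
        ue0 = u[conn]
        f0 = self._elem_forces(ue0, activation)
        if h is None:
            h = 1e-6 * max(1.0, float(np.abs(u).max()))
        ndof_e = self.npe * 3
        nelem = conn.shape[0]
        ke = np.empty((nelem, ndof_e, ndof_e))
        chunk = max(1, int(2_000_000 // max(nelem * self.ngp, 1)))

        def tiled(arr, nb):
            return np.ascontiguousarray(
                np.broadcast_to(arr, (nb,) + arr.shape).reshape(
                    (nb * arr.shape[0],) + arr.shape[1:]
                )
            )

        # the tiled constant fields do not depend on u; cache per chunk size
        cache = getattr(self, "_tangent_cache", None)
        if cache is None or cache[0] != chunk:
            nb_full = min(chunk, ndof_e)
            cache = (
                chunk,
                tiled(self.dNdX, nb_full),
                tiled(self.wvol, nb_full),
                tiled(self._fib_gp, nb_full),
                tiled(self._fat_gp, nb_full),
                tiled(self.muscle_mask, nb_full),
                tiled(self.apo_mask, nb_full),
            )
            self._tangent_cache = cache

        for d0 in range(0, ndof_e, chunk):
            dofs = range(d0, min(d0 + chunk, ndof_e))
            nb = len(dofs)
            ue = np.broadcast_to(ue0, (nb,) + ue0.shape).copy()
            for k, d in enumerate(dofs):
                a, i = divmod(d, 3)
                ue[k, :, a, i] += h
            if nb == cache[0] or nb * nelem == cache[1].shape[0]:
                tdN, tw, tfib, tfat, tmm, tam = cache[1:]
            else:
                tdN, tw = tiled(self.dNdX, nb), tiled(self.wvol, nb)
                tfib, tfat = tiled(self._fib_gp, nb), tiled(self._fat_gp, nb)
                tmm, tam = tiled(self.muscle_mask, nb), tiled(self.apo_mask, nb)
            fp = self._forces_kernel(
                ue.reshape(nb * nelem, self.npe, 3),
                tdN, tw, tfib, tfat, tmm, tam,
                activation,
            ).reshape(nb, nelem, ndof_e)
            for k, d in enumerate(dofs):
                ke[:, :, d] = (fp[k] - f0.reshape(nelem, ndof_e)) / h
        ke = 0.5 * (ke + np.swapaxes(ke, 1, 2))  # energy Hessian is symmetric
        gdof = (3 * conn[:, :, None] + np.arange(3)).reshape(nelem, ndof_e)
        rows = np.repeat(gdof, ndof_e, axis=1).ravel()
        cols = np.tile(gdof, (1, ndof_e)).ravel()
        n = self.mesh.n_nodes * 3
        return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    # ------------------------------------------------------------------
    _SPLU_OPTS = {"SymmetricMode": True, "DiagPivotThresh": 0.001}

    @staticmethod
    def _factor(Kff, mu):
        try:
            if mu > 0.0:
                Kff = Kff + mu * sp.identity(Kff.shape[0], format="csc")
            return spla.splu(Kff, options=dict(FEProblem._SPLU_OPTS))
        except RuntimeError:
            return None

    def _energy_safe(self, u, activation):
        try:
            return self.energy(u, activation)
        except (FloatingPointError, ValueError):
            return np.inf

    def _newton(self, u, activation, cfg: SolverConfig, log):
        """Trust-region Newton on the total strain energy.

        The fixed-end equilibrium is an energy minimum, but the activated
        muscle is extremely soft in shear relative to its bulk response and
        the path to equilibrium crosses long, nearly flat valleys (fiber
        shortening against the compliant aponeurosis).  A trust-region
        step (Newton direction, Levenberg shift raised until the step fits
        the radius) with gain-ratio radius control crosses those valleys
        in geometrically growing steps where a damped or line-searched
        Newton crawls."""
        g = self.residual(u, activation).ravel()[self.free]
        rn0 = np.linalg.norm(g)
        tol = max(cfg.newton_rtol * rn0, cfg.newton_atol)
        rn = rn0
        E = self._energy_safe(u, activation)
        Delta = getattr(self, "_tr_delta", cfg.tr_radius0)
        mu = 0.0
        K = None
        lu = None
        mu_f = None
        stale = 0  # accepted steps since the tangent was assembled
        for it in range(cfg.max_newton_iter):
            if rn <= tol:
                log.append((activation, it, rn))
                self._tr_delta = max(Delta, cfg.tr_radius0)
                return u, True
            if K is None:
                K = self.tangent(u, activation)[self.free][:, self.free].tocsc()
                ds = float(np.abs(K.diagonal()).mean())
                lu = None
            duf = None
            for _ in range(25):  # shift up until the step fits the radius
                if lu is None or mu_f != mu:
                    lu = self._factor(K, mu)
                    mu_f = mu
                cand = lu.solve(-g) if lu is not None else None
                slope = float(cand @ g) if cand is not None else np.inf
                if cand is None or not np.isfinite(slope) or slope >= 0.0:
                    mu = max(4.0 * mu, 1e-7 * ds)
                    continue
                nrm = float(np.abs(cand).max())
                if nrm > Delta:
                    mu = max(2.0 * mu, 1e-7 * ds)
                    continue
                duf = cand
                break
            if duf is None:
                return u, False
            du = np.zeros(self.mesh.n_nodes * 3)
            du[self.free] = duf
            du = du.reshape(-1, 3)
            s = 1.0
            E_new = np.inf
            for _ in range(5):  # retreat from element inversion only
                E_new = self._energy_safe(u + s * du, activation)
                if np.isfinite(E_new):
                    break
                s *= 0.3
            pred = -(s * slope + 0.5 * s * s * float(duf @ (K @ duf)))
            rho = (E - E_new) / max(pred, 1e-300) if np.isfinite(E_new) else -1.0
            if rho > 0.01 and (E_new <= E or not cfg.line_search):
                u = u + s * du
                E = E_new
                g = self.residual(u, activation).ravel()[self.free]
                rn = np.linalg.norm(g)
                # the (possibly stale) quadratic model is kept while it
                # predicts the energy well; staleness is bounded
                if cfg.reuse_tangent and rho > 2.0:  # disabled: fresh tangents win here
                    stale += 1
                else:
                    K = None
                    stale = 0
                if rho > 0.9 and s == 1.0:
                    Delta = min(4.0 * Delta, cfg.tr_radius_max)
                    mu *= 0.1
                elif rho > 0.5:
                    Delta = min(1.5 * Delta, cfg.tr_radius_max)
                    mu *= 0.5
                if mu < 1e-9 * ds:
                    mu = 0.0
            else:
                Delta = max(0.3 * s * nrm, cfg.tr_radius_min)
                mu = max(4.0 * mu, 1e-7 * ds)
                K = None  # a rejection may be the stale model's fault
                stale = 0
        ok = rn <= tol
        log.append((activation, cfg.max_newton_iter, rn))
        return u, ok

    def reactions_at(self, u: np.ndarray, activation: float) -> dict[str, np.ndarray]:
        r = self.residual(u, activation)
        return {name: r[nodes].sum(axis=0) for name, nodes in self.set_nodes.items()}


def solve_contraction(
    mesh: TetMesh,
    fiber_directions: np.ndarray,
    fat_percent: np.ndarray,
    muscle_params: MuscleFatParams | None = None,
    apo_params: AponeurosisParams | None = None,
    bc: BoundarySpec | None = None,
    cfg: SolverConfig | None = None,
    u0: np.ndarray | None = None,
) -> SimulationResult:
    """Ramp activation 0 -> 1 quasi-statically and return the converged
    history.  On persistent Newton failure the partial result is returned
    with ``converged=False`` at the last equilibrated activation.

    ``u0`` warm-starts the solve from the displacement field of a related
    converged model (same mesh; e.g. the control, or a neighbouring fat
    level): the solution is then computed directly at full activation as a
    continuation step, which is much cheaper than re-ramping.  Falls back
    to the full ramp if the continuation step fails.
    """
    cfg = cfg or SolverConfig()
    if u0 is not None:
        # continuation in the fat field: scale the fat map up in a few
        # increments from the warm-start state (assumed converged for a
        # related fat field at full activation), each a short solve
        log: list = []
        u = np.array(u0, dtype=float)
        ok = True
        fat = np.asarray(fat_percent, dtype=float)
        prob = None
        for frac in np.linspace(1.0 / cfg.fat_steps, 1.0, cfg.fat_steps):
            prob = FEProblem(
                mesh, fiber_directions, frac * fat, muscle_params, apo_params, bc
            )
            u, ok = prob._newton(u, 1.0, cfg, log)
            if not ok:
                break
        if ok:
            rs = prob.reactions_at(u, 1.0)
            return SimulationResult(
                activation=np.array([1.0]),
                displacements=u,
                reactions={k: v[None, :] for k, v in rs.items()},
                forces=np.array([np.linalg.norm(_force_reaction(rs))]),
                converged=True,
                log=log,
            )
    prob = FEProblem(mesh, fiber_directions, fat_percent, muscle_params, apo_params, bc)
    return _ramp(prob, cfg)


def _ramp(prob: FEProblem, cfg: SolverConfig) -> SimulationResult:
    u = np.zeros((prob.mesh.n_nodes, 3))
    base = 1.0 / cfg.n_steps
    da = base
    a = 0.0
    log: list = []
    acts, forces = [], []
    reac: dict[str, list] = {name: [] for name in prob.set_nodes}
    t0 = time.time()
    converged = True
    u_hist: list = []  # (a, u) of the last two converged steps (predictor)
    while a < 1.0 - 1e-12:
        a_try = min(a + da, 1.0)
        u0 = u
        if len(u_hist) == 2 and u_hist[1][0] > u_hist[0][0]:
            (ap, up), (ac, uc) = u_hist
            u0 = uc + (uc - up) * ((a_try - ac) / (ac - ap))  # secant predictor
        u_new, ok = prob._newton(u0, a_try, cfg, log)
        if not ok and u0 is not u:
            u_new, ok = prob._newton(u, a_try, cfg, log)  # retry unpredicted
        if ok:
            a = a_try
            u = u_new
            u_hist = (u_hist + [(a, u)])[-2:]
            rs = prob.reactions_at(u, a)
            for name, v in rs.items():
                reac[name].append(v)
            acts.append(a)
            forces.append(np.linalg.norm(_force_reaction(rs)))
            da = min(da * 1.5, base)
            if cfg.verbose:
                print(f"  a={a:.3f} force={forces[-1]:.3f} N  ({time.time() - t0:.1f}s)")
        else:
            da *= 0.5
            if da < cfg.min_step:
                converged = False
                break
    return SimulationResult(
        activation=np.array(acts),
        displacements=u,
        reactions={k: np.array(v) for k, v in reac.items()},
        forces=np.array(forces),
        converged=converged,
        log=log,
    )


def sensitivity_sweep_Gf(
    mesh: TetMesh,
    fiber_directions: np.ndarray,
    fat_percent: np.ndarray,
    values_mpa=None,
    muscle_params: MuscleFatParams | None = None,
    apo_params: AponeurosisParams | None = None,
    bc: BoundarySpec | None = None,
    cfg: SolverConfig | None = None,
    u0=None,
):
    """Model force for a sweep of fat shear moduli, all else fixed.

    Default grid: 1-15 kPa (the physiological range) plus the two
    non-physiological stiffnesses 50 and 500 kPa, in MPa.
    Returns a pandas DataFrame (G_f_MPa, force_N, converged).
    """
    import pandas as pd
    from dataclasses import replace

    if values_mpa is None:
        values_mpa = [v / 1000.0 for v in range(1, 16)] + [0.05, 0.5]
    mp0 = muscle_params or MuscleFatParams()
    rows = []
    u_prev = u0
    for gf in values_mpa:
        mp = replace(mp0, G_f=float(gf))
        res = solve_contraction(
            mesh, fiber_directions, fat_percent, mp, apo_params, bc, cfg, u0=u_prev
        )
        if res.converged:
            u_prev = res.displacements
        rows.append({"G_f_MPa": float(gf), "force_N": res.force, "converged": res.converged})
    return pd.DataFrame(rows)
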