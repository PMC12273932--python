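"""End-to-end coarse contraction study on the synthetic muscle.

One entry point builds the geometry, solves the Laplace fiber problem,
runs the fixed-end contraction batch (control, uniform fat levels, the
pseudo-map schemes, the fat-modulus sensitivity sweep) and collects the
comparison quantities.  Both the test suite and the reproduction script
drive the pipeline through this module so the numbers they report are
produced by one code path.

Problem sizes are chosen for a single desk CPU: the default batch runs a
coarse discretisation of the default muscle (quadratic tets, a few
thousand degrees of freedom), ramps the control in a handful of
activation increments, and warm-starts the fat-mapped solves from related
converged states (continuation in the fat field), chaining up each
scheme's fat ladder.  The full 8 x 10 sweep of the pseudo schemes remains
available through :func:`myofat.analysis.pseudo_sweep`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fatmap import PseudoScheme, pseudo_map
from .fibers import ta_fiber_field
from .geometry import SynthGeomParams, generate_synthetic_ta
from .mesh import MUSCLE, promote_to_quadratic
from .solver import SolverConfig, sensitivity_sweep_Gf, solve_contraction

__all__ = ["CoarseStudyResult", "coarse_study", "LENGTH_REGIONS", "CROSS_REGIONS"]

LENGTH_REGIONS = ("distal_third", "middle_third", "proximal_third", "proximal_distal")
CROSS_REGIONS = ("medial", "lateral", "anterior", "posterior")


@dataclass
class CoarseStudyResult:
    control_force: float  # N
    control_forces_per_step: np.ndarray  # activation ramp history
    control_activation: np.ndarray
    normalized: dict  # (region, gamma) -> normalized force
    converged: dict  # (region, gamma) -> bool
    uniform30_normalized: float
    uniform100_normalized: float
    gf_table: pd.DataFrame  # fat-modulus sensitivity at uniform 30% fat
    mesh: object = field(repr=False, default=None)
    fibers: object = field(repr=False, default=None)
    j_within_2pct: float = float("nan")  # volume-ratio check at control


def coarse_study(
    params: SynthGeomParams | None = None,
    cfg: SolverConfig | None = None,
    seed: int = 0,
    gammas_length=(50, 100),
    gammas_cross=(100,),
    gf_values=(0.001, 0.015, 0.5),
    cross_regions=CROSS_REGIONS,
    verbose: bool = False,
) -> CoarseStudyResult:
    """Run the standard coarse contraction batch and return its metrics."""
    import time

    t_start = time.time()

    def note(msg):
        if verbose:
            print(f"[coarse_study {time.time() - t_start:6.0f}s] {msg}", flush=True)

    params = params or SynthGeomParams(nx=4, ny=4, nz=10)
    cfg = cfg or SolverConfig(n_steps=4, newton_atol=1e-2)
    mesh = generate_synthetic_ta(params)
    fib, _ = ta_fiber_field(mesh)
    meshq = promote_to_quadratic(mesh)
    muscle = mesh.elem_domain == MUSCLE
    nel = mesh.n_elems
    rng = np.random.default_rng(seed)
    base_seed = int(rng.integers(0, 2**31 - 10))

    control = solve_contraction(meshq, fib.directions, np.zeros(nel), cfg=cfg)
    if not control.converged:
        raise RuntimeError("control model failed to converge")
    Fc = control.force
    u_ctrl = control.displacements
    note(f"control converged, F = {Fc:.1f} N")
    cfg_warm = SolverConfig(
        n_steps=cfg.n_steps, newton_atol=cfg.newton_atol,
        max_newton_iter=150, fat_steps=2,
    )
    # predicted starts get a long budget: one sustained trust-region solve
    # beats failing over to a fresh activation ramp on the hard fat states
    cfg_pred = SolverConfig(
        n_steps=cfg.n_steps, newton_atol=cfg.newton_atol, max_newton_iter=350
    )

    normalized: dict = {}
    converged: dict = {}
    for region in LENGTH_REGIONS + tuple(cross_regions):
        gammas = gammas_length if region in LENGTH_REGIONS else gammas_cross
        ladder = [(0.0, u_ctrl)]  # (gamma, displacements) up the fat ladder
        for k, g in enumerate(gammas):
            fat = pseudo_map(
                mesh, PseudoScheme(region=region, gamma=g, seed=base_seed + k)
            ).values
            # secant predictor in the fat level from the last two states
            g1, u1 = ladder[-1]
            if len(ladder) >= 2:
                g0, u0p = ladder[-2]
                u_start = u1 + (u1 - u0p) * ((g - g1) / (g1 - g0))
                cfg_run = cfg_pred  # predicted start: solve the target directly
            else:
                u_start = u1
                cfg_run = cfg_warm if region in LENGTH_REGIONS else cfg_pred
            res = solve_contraction(meshq, fib.directions, fat, cfg=cfg_run, u0=u_start)
            if res.converged:
                ladder.append((float(g), res.displacements))
            normalized[(region, g)] = res.force / Fc
            converged[(region, g)] = bool(res.converged)
            note(f"{region}:{g} -> {res.force / Fc:.3f} ({'ok' if res.converged else 'FAILED'})")

    fat30 = np.where(muscle, 30.0, 0.0)
    r30 = solve_contraction(meshq, fib.directions, fat30, cfg=cfg_warm, u0=u_ctrl)
    note(f"uniform 30% -> {r30.force / Fc:.3f}")
    gf_table = sensitivity_sweep_Gf(
        meshq, fib.directions, fat30, values_mpa=list(gf_values),
        cfg=cfg_warm, u0=r30.displacements if r30.converged else None,
    )
    note("fat-modulus sweep done")
    r100 = solve_contraction(meshq, fib.directions, np.where(muscle, 100.0, 0.0), cfg=cfg)
    note(f"uniform 100% -> {r100.force / Fc:.4f}")

    # near-incompressibility check at the converged control state
    from .solver import FEProblem

    prob = FEProblem(meshq, fib.directions, np.zeros(nel))
    J = np.linalg.det(prob.deformation_gradients(u_ctrl))
    j_ok = float((np.abs(J - 1.0) < 0.02).mean())

    return CoarseStudyResult(
        control_force=Fc,
        control_forces_per_step=control.forces,
        control_activation=control.activation,
        normalized=normalized,
        converged=converged,
        uniform30_normalized=r30.force / Fc,
        uniform100_normalized=r100.force / Fc,
        gf_table=gf_table,
        mesh=mesh,
        fibers=fib,
        j_within_2pct=j_ok,
    )
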