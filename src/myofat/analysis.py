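"""Batch post-processing: normalized forces, scheme sweeps, statistics.

The central comparison quantity is the normalized force: the force of a
fat-mapped model divided by the force of its control (the identical
geometry, fibers and boundary conditions with all fat removed).  Sweeps
over the eight pseudo regions at increasing regional fat levels expose how
the *location* of fat, not only its amount, modulates force-generating
capacity; simulated ultrasound-like measurements (cross-sectional area and
mean fat fraction at 60% of muscle length from the distal end) connect the
3-D models to 2-D clinical imaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fatmap import (
    ElementFatField,
    PseudoScheme,
    lean_volume,
    pseudo_map,
    volumetric_fat_fraction,
)
from .geometry import cross_section
from .mesh import TetMesh
from .solver import BoundarySpec, SolverConfig, solve_contraction

__all__ = [
    "ModelRecord",
    "RegressionSummary",
    "normalized_force",
    "ultrasound_sim",
    "correlate",
    "plot_normalized_force_curves",
    "run_model",
    "pseudo_sweep",
    "scheme_comparison",
]


@dataclass
class ModelRecord:
    """One simulated model in a comparison batch."""

    model_id: str
    scheme: str
    gamma: float | None  # target regional mean for pseudo maps (percent)
    volumetric_fat: float  # percent
    force: float  # N
    control_force: float  # N
    normalized_force: float
    muscle_volume_cm3: float
    lean_volume_cm3: float
    csa_60_cm2: float
    midbelly_fat: float  # percent
    converged: bool
    seed: int | None = None


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    p_value: float
    n: int


def normalized_force(force: float, control_force: float) -> float:
    """Force relative to the fat-free control of the same geometry."""
    if control_force <= 0:
        raise ValueError("control force must be > 0")
    return force / control_force


def ultrasound_sim(mesh: TetMesh, fat: ElementFatField | None = None):
    """Simulated ultrasound measurements at the 60% cross-section (from the
    distal end): (CSA in cm^2, mean fat fraction in percent)."""
    cs = cross_section(mesh, 0.60, fat.values if fat is not None else None)
    return cs.area / 100.0, cs.mean_fat_fraction


def correlate(x, y) -> RegressionSummary:
    """Pearson correlation + simple linear regression with pairwise
    deletion of non-finite entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    r, p = stats.pearsonr(x, y)
    reg = stats.linregress(x, y)
    return RegressionSummary(
        slope=reg.slope,
        intercept=reg.intercept,
        r2=reg.rvalue**2,
        pearson_r=r,
        p_value=p,
        n=int(x.size),
    )


# ----------------------------------------------------------------------
# batch simulation helpers


def run_model(
    mesh: TetMesh,
    fibers: np.ndarray,
    fat: ElementFatField,
    control_force: float,
    model_id: str = "synthetic",
    muscle_params=None,
    apo_params=None,
    bc: BoundarySpec | None = None,
    cfg: SolverConfig | None = None,
    u0=None,
    return_result: bool = False,
):
    """Solve one fat-mapped contraction and collect its summary record.

    ``u0`` (e.g. the control solution) warm-starts the solve; with
    ``return_result`` the full :class:`SimulationResult` is also returned
    (useful for chaining warm starts across related runs)."""
    from .geometry import element_volumes
    from .mesh import MUSCLE

    res = solve_contraction(mesh, fibers, fat.values, muscle_params, apo_params, bc, cfg, u0=u0)
    vols = element_volumes(mesh)
    mv = vols[mesh.elem_domain == MUSCLE].sum()
    csa, mb = ultrasound_sim(mesh, fat)
    record = ModelRecord(
        model_id=model_id,
        scheme=fat.provenance,
        gamma=fat.params.get("gamma"),
        volumetric_fat=volumetric_fat_fraction(fat, mesh),
        force=res.force,
        control_force=control_force,
        normalized_force=normalized_force(res.force, control_force),
        muscle_volume_cm3=mv / 1000.0,
        lean_volume_cm3=lean_volume(fat, mesh) / 1000.0,
        csa_60_cm2=csa,
        midbelly_fat=mb,
        converged=res.converged,
        seed=fat.params.get("seed"),
    )
    if return_result:
        return record, res
    return record


def pseudo_sweep(
    mesh: TetMesh,
    fibers: np.ndarray,
    control_force: float,
    regions=None,
    gammas=None,
    seed: int = 0,
    model_id: str = "synthetic",
    muscle_params=None,
    apo_params=None,
    bc: BoundarySpec | None = None,
    cfg: SolverConfig | None = None,
    u0=None,
) -> pd.DataFrame:
    """Pseudo-map sweep: regions x gamma levels, one solve each.

    ``u0`` (typically the control solution) warm-starts every run.

    Default grid: all eight regions at 10..100% in 10% steps.  Rows of
    non-converged runs are kept with ``converged=False`` so they can be
    excluded from curves and counted.
    """
    from .fatmap import PSEUDO_REGIONS

    regions = list(regions) if regions is not None else list(PSEUDO_REGIONS)
    gammas = list(gammas) if gammas is not None else list(range(10, 101, 10))
    rows = []
    for region in regions:
        u_run = u0  # chain warm starts up the gamma ladder per region
        for k, gamma in enumerate(gammas):
            fat = pseudo_map(mesh, PseudoScheme(region=region, gamma=gamma, seed=seed + k))
            rec, res = run_model(
                mesh, fibers, fat, control_force, model_id,
                muscle_params, apo_params, bc, cfg, u0=u_run, return_result=True,
            )
            if res.converged and u_run is not None:
                u_run = res.displacements
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def plot_normalized_force_curves(records: pd.DataFrame, path) -> None:
    """Advisory plot: normalized force vs volumetric fat fraction per
    scheme (the CSV tables remain the contract surface)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for scheme, grp in records[records["converged"]].groupby("scheme"):
        g = grp.sort_values("volumetric_fat")
        ax.plot(g["volumetric_fat"], g["normalized_force"], "o-", label=scheme)
    ax.plot([0, 100], [1, 0], "--", color="0.6", label="direct relationship")
    ax.set_xlabel("volumetric fat fraction (%)")
    ax.set_ylabel("normalized force")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scheme_comparison(records: pd.DataFrame) -> dict[str, RegressionSummary]:
    """Per-scheme regressions of the comparison quantities.

    Returns regressions of normalized force vs volumetric fat fraction,
    force vs volumetric fat fraction, and force vs lean volume, keyed as
    ``<scheme>:<relation>``.
    """
    out: dict[str, RegressionSummary] = {}
    for scheme, grp in records.groupby("scheme"):
        g = grp[grp["converged"]]
        if len(g) < 3:
            continue
        out[f"{scheme}:normforce_vs_fat"] = correlate(g["volumetric_fat"], g["normalized_force"])
        out[f"{scheme}:force_vs_fat"] = correlate(g["volumetric_fat"], g["force"])
        out[f"{scheme}:force_vs_leanvol"] = correlate(g["lean_volume_cm3"], g["force"])
    return out
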