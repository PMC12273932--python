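"""Synthetic tibialis-anterior-like geometry and geometric queries.

The generator produces a fusiform, tapered muscle volume with an embedded
central aponeurosis sheet (shared nodes, solid elements), a proximal
aponeurosis modelled as a short extrusion of the most proximal muscle
cross-section, and a tibial-origin strip on the anterior surface of the
proximal portion of the muscle.  It exists so the full pipeline (fibers,
fat mapping, contraction) is exercisable without any imaging data.

Construction: a structured template grid on the square cross-section
[-1,1]^2 x length is mapped through a smooth square-to-ellipse map and
scaled by a taper profile ``p(zeta)`` whose peak sits at 60% of muscle
length from the distal end (where the real muscle is thickest).  Template
cross-sections are radially rescaled so each polygonal section has exactly
the analytic elliptical area pi*a(zeta)*b(zeta); the mesh volume then
tracks the analytic profile volume closely even on coarse grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import (
    CENTRAL_APONEUROSIS,
    MUSCLE,
    PROXIMAL_APONEUROSIS,
    MeshError,
    TetMesh,
    boundary_face_pairs,
    hexes_to_tets,
    interface_face_pairs,
    orient_positive,
    structured_grid,
    tet_volumes,
)

__all__ = [
    "SynthGeomParams",
    "CrossSection",
    "generate_synthetic_ta",
    "element_volumes",
    "cross_section",
    "taper_profile",
    "analytic_muscle_volume",
]


@dataclass
class SynthGeomParams:
    """Parameters of the synthetic muscle generator.

    Lengths in mm.  Defaults emulate a mid-range adult tibialis anterior:
    300 mm muscle length, elliptical belly 40 x 30 mm, ~125 cm^3 volume,
    central aponeurosis sheet spanning half the length from the distal end,
    a 15 mm proximal extrusion and a tibial origin over the proximal 30%
    of muscle length.
    """

    muscle_length: float = 300.0
    max_width: float = 20.0  # medial-lateral semi-axis at the belly (x)
    max_depth: float = 15.0  # anterior-posterior semi-axis (y)
    taper_end: float = 0.45  # taper profile value at both ends (relative)
    taper_peak: float = 0.60  # length fraction (from distal) of max section
    apo_thickness: float = 3.0  # central aponeurosis sheet thickness
    apo_extent: float = 0.50  # sheet reach from the distal end, fraction
    apo_halfwidth: float = 0.80  # sheet width band in template x, fraction
    apo_offset: float = 0.0  # sheet plane position across the depth
    # (template y in (-1, 1); 0 = mid-plane.  A posterior offset is more
    # anatomical but breaks the symmetry and slows equilibration, so the
    # symmetric default is kept for desk-scale runs)
    extrusion_length: float = 15.0  # proximal aponeurosis extrusion
    origin_extent: float = 0.30  # tibial origin covers proximal this much
    nx: int = 6  # template cells across width (even)
    ny: int = 6  # template cells across depth (even, before sheet planes)
    nz: int = 18  # cells along the muscle length
    edge_length: float | None = None  # optional target edge (mm), sets n*
    seed: int = 0

    def __post_init__(self) -> None:
        if self.muscle_length <= 0 or self.max_width <= 0 or self.max_depth <= 0:
            raise ValueError("muscle_length, max_width and max_depth must be > 0")
        if not 0 < self.taper_end <= 1:
            raise ValueError(f"degenerate taper: taper_end={self.taper_end} not in (0,1]")
        if not 0 < self.taper_peak < 1:
            raise ValueError(f"taper_peak={self.taper_peak} not in (0,1)")
        if not 0 < self.apo_extent < 1:
            raise ValueError(f"apo_extent={self.apo_extent} not in (0,1)")
        if not 0 < self.origin_extent < 1:
            raise ValueError(f"origin_extent={self.origin_extent} not in (0,1)")
        if self.extrusion_length < 0:
            raise ValueError("extrusion_length must be >= 0")
        if self.apo_thickness <= 0:
            raise ValueError("apo_thickness must be > 0")
        if self.edge_length is not None:
            e = self.edge_length
            self.nz = max(8, int(round(self.muscle_length / e)))
            self.nx = max(4, 2 * int(round(self.max_width / e)))
            self.ny = max(4, 2 * int(round(self.max_depth / e)))
        if self.nx < 4 or self.nx % 2 or self.ny < 4 or self.ny % 2:
            raise ValueError("nx and ny must be even and >= 4")
        delta = self.apo_thickness / (2.0 * self.max_depth)
        if delta >= 1.0 / self.ny:
            raise MeshError(
                "edge length too large relative to sheet thickness: "
                f"apo_thickness={self.apo_thickness} requires template half-gap "
                f"{delta:.3f} < 1/ny={1.0 / self.ny:.3f}; refine ny or thicken the sheet"
            )


@dataclass
class CrossSection:
    """Planar section of the muscle perpendicular to the long axis."""

    length_fraction: float  # from the distal end, in [0, 1]
    area: float  # mm^2, muscle-domain elements only
    mean_fat_fraction: float | None = None  # percent, area weighted


def taper_profile(zeta: np.ndarray, params: SynthGeomParams) -> np.ndarray:
    """Relative semi-axis scale p(zeta), peak 1 at ``taper_peak``.

    Shaped as a beta-density bump zeta^3 (1-zeta)^2 (mode exactly 0.6 for
    the default peak) floored at ``taper_end`` so neither end pinches to a
    point."""
    zeta = np.asarray(zeta, dtype=float)
    zp = params.taper_peak
    m = zp / (1.0 - zp) * 2.0  # zeta^m (1-zeta)^2 has mode m/(m+2) = zp
    bump = zeta**m * (1.0 - zeta) ** 2
    bump = bump / (zp**m * (1.0 - zp) ** 2)
    return params.taper_end + (1.0 - params.taper_end) * bump


def analytic_muscle_volume(params: SynthGeomParams, n: int = 20000) -> float:
    """High-resolution quadrature of the generating profile volume
    integral(0..1) pi a(z) b(z) L dz  (mm^3); the oracle for mesh volume."""
    z = (np.arange(n) + 0.5) / n
    p = taper_profile(z, params)
    return float(
        np.pi * params.max_width * params.max_depth * params.muscle_length * np.mean(p**2)
    )


def _square_to_disc(xh: np.ndarray, yh: np.ndarray):
    """Smooth bijection of [-1,1]^2 onto the unit disc (elliptical map)."""
    u = xh * np.sqrt(np.maximum(1.0 - 0.5 * yh**2, 0.0))
    v = yh * np.sqrt(np.maximum(1.0 - 0.5 * xh**2, 0.0))
    return u, v


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def generate_synthetic_ta(params: SynthGeomParams | None = None) -> TetMesh:
    """Build the synthetic TA mesh (linear tets, all six canonical facet
    sets populated).  Deterministic for fixed parameters."""
    p = params or SynthGeomParams()
    L, ext = p.muscle_length, p.extrusion_length

    # template planes; the y=0 plane is replaced by a +-delta pair bounding
    # the aponeurosis sheet layer
    xs = np.linspace(-1.0, 1.0, p.nx + 1)
    delta = p.apo_thickness / (2.0 * p.max_depth)
    ys0 = np.linspace(-1.0, 1.0, p.ny + 1)
    mid = int(np.argmin(np.abs(ys0 - p.apo_offset)))
    if mid == 0 or mid == p.ny:
        raise MeshError("apo_offset must be interior to the cross-section")
    y0 = ys0[mid]
    ys = np.concatenate([ys0[:mid], [y0 - delta, y0 + delta], ys0[mid + 1 :]])
    dz = L / p.nz
    n_ext = max(1, int(round(ext / dz))) if ext > 0 else 0
    zetas = np.concatenate(
        [np.arange(p.nz + 1) / p.nz, 1.0 + (ext / L) * (np.arange(n_ext) + 1) / max(n_ext, 1)]
    )

    ref, hexes = structured_grid(xs, ys, zetas)
    xh, yh, zh = ref[:, 0], ref[:, 1], ref[:, 2]
    u, v = _square_to_disc(xh, yh)

    # radial compensation so each polygonal cross-section has area pi*a*b
    bx, by = _boundary_loop(xs, ys)
    bu, bv = _square_to_disc(bx, by)
    comp = np.sqrt(np.pi / _polygon_area(np.column_stack([bu, bv])))

    zeta_sec = np.minimum(zh, 1.0)  # extrusion keeps the proximal section
    prof = taper_profile(zeta_sec, p)
    coords = np.column_stack(
        [p.max_width * prof * comp * u, p.max_depth * prof * comp * v, zh * L]
    )

    conn = orient_positive(coords, hexes_to_tets(hexes))
    n_tets = conn.shape[0]

    # template-space hex centroids, replicated for the 6 tets per hex
    hex_cen = ref[hexes].mean(axis=1)
    cen = np.repeat(hex_cen, 6, axis=0)
    domain = np.full(n_tets, MUSCLE, dtype=np.int64)
    sheet = (
        (np.abs(cen[:, 1] - y0) < delta)
        & (np.abs(cen[:, 0]) < p.apo_halfwidth)
        & (cen[:, 2] <= p.apo_extent)
    )
    domain[sheet] = CENTRAL_APONEUROSIS
    domain[cen[:, 2] > 1.0] = PROXIMAL_APONEUROSIS
    if not sheet.any():
        raise MeshError("central aponeurosis sheet is empty; check apo_extent/apo_halfwidth")

    mesh = TetMesh(
        node_coords=coords,
        tet_conn=conn,
        elem_domain=domain,
        long_axis=np.array([0.0, 0.0, 1.0]),
        distal_point=np.zeros(3),
    )

    b = boundary_face_pairs(conn)
    fc = coords[mesh.face_corner_nodes(b)].mean(axis=1)
    fdom = domain[b[:, 0]]
    tol = 1e-9 * L
    z_top = L + (ext if ext > 0 else 0.0)

    distal = (np.abs(fc[:, 2]) < tol) & (fdom == CENTRAL_APONEUROSIS)
    prox_end = (np.abs(fc[:, 2] - z_top) < tol) if ext > 0 else np.zeros(len(b), bool)

    # tibial-origin band: the muscle surface over the proximal portion
    # (the fascicle-origin surface; wrapping the section keeps the
    # anterior/posterior halves architecturally equivalent)
    frac = fc[:, 2] / L
    origin = (
        (fdom == MUSCLE)
        & (frac >= 1.0 - p.origin_extent - 1e-12)
        & (frac <= 1.0 + 1e-12)
        & (np.abs(fc[:, 2] - L) > tol)
    )
    if not origin.any():
        raise MeshError("tibial_origin strip is empty; check origin_extent")

    assigned = distal | prox_end | origin
    mesh.facet_sets["distal_apo_end"] = b[distal]
    mesh.facet_sets["proximal_apo_end"] = b[prox_end]
    mesh.facet_sets["tibial_origin"] = b[origin]

    mesh.facet_sets["muscle_insertion_interface"] = interface_face_pairs(
        conn, domain, MUSCLE, CENTRAL_APONEUROSIS
    )
    if ext > 0:
        mesh.facet_sets["proximal_apo_inlet"] = interface_face_pairs(
            conn, domain, MUSCLE, PROXIMAL_APONEUROSIS
        )
        mesh.facet_sets["free_surface"] = b[~assigned]
    else:
        prox_muscle = (np.abs(fc[:, 2] - L) < tol) & (fdom == MUSCLE)
        mesh.facet_sets["proximal_apo_inlet"] = b[prox_muscle]
        mesh.facet_sets["free_surface"] = b[~(assigned | prox_muscle)]

    mesh.validate()
    return mesh


def _boundary_loop(xs: np.ndarray, ys: np.ndarray):
    """Counter-clockwise boundary points of the template square grid."""
    bottom = [(x, ys[0]) for x in xs]
    right = [(xs[-1], y) for y in ys[1:]]
    top = [(x, ys[-1]) for x in xs[::-1][1:]]
    left = [(xs[0], y) for y in ys[::-1][1:-1]]
    pts = np.array(bottom + right + top + left)
    return pts[:, 0], pts[:, 1]


# ----------------------------------------------------------------------


def element_volumes(mesh: TetMesh) -> np.ndarray:
    """Per-element volumes (mm^3); raises on inverted elements."""
    vols = tet_volumes(mesh.node_coords, mesh.corners)
    bad = np.flatnonzero(vols <= 0)
    if bad.size:
        raise MeshError(f"inverted elements: {bad[:20].tolist()}")
    return vols


def cross_section(
    mesh: TetMesh,
    length_fraction: float,
    fat: np.ndarray | None = None,
) -> CrossSection:
    """Muscle cross-section by the plane perpendicular to the long axis at
    ``length_fraction`` of muscle length from the distal end.

    Area is the summed area of tet/plane intersection polygons over
    muscle-domain elements; the fat fraction (percent per element, if
    given) is averaged weighted by intersection area.
    """
    if not 0.0 < length_fraction < 1.0:
        raise ValueError("length_fraction must be in (0, 1)")
    axis = mesh.long_axis
    d_plane = length_fraction * mesh.muscle_length()
    s_node = (mesh.node_coords - mesh.distal_point) @ axis - d_plane
    # nodes exactly on the plane are pushed to the positive side so a
    # plane through a mesh layer still cuts exactly one element sheet
    eps = 1e-9 * mesh.muscle_length()
    s_node = np.where(np.abs(s_node) < eps, eps, s_node)

    # orthonormal in-plane basis for polygon areas
    t1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(t1) < 1e-8:
        t1 = np.cross(axis, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(axis, t1)

    total_area = 0.0
    fat_acc = 0.0
    muscle_elems = np.flatnonzero(mesh.elem_domain == MUSCLE)
    conn = mesh.corners[muscle_elems]
    s_el = s_node[conn]
    cut = np.flatnonzero((s_el.min(axis=1) < 0.0) & (s_el.max(axis=1) > 0.0))
    edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for idx in cut:
        verts = []
        nodes = conn[idx]
        s = s_el[idx]
        for a, bx_ in edges:
            if (s[a] < 0.0) != (s[bx_] < 0.0):
                t = s[a] / (s[a] - s[bx_])
                pa = mesh.node_coords[nodes[a]]
                pb = mesh.node_coords[nodes[bx_]]
                verts.append(pa + t * (pb - pa))
        if len(verts) < 3:
            continue
        verts = np.asarray(verts)
        uv = np.column_stack([verts @ t1, verts @ t2])
        c = uv.mean(axis=0)
        order = np.argsort(np.arctan2(uv[:, 1] - c[1], uv[:, 0] - c[0]))
        area = _polygon_area(uv[order])
        total_area += area
        if fat is not None:
            fat_acc += area * fat[muscle_elems[idx]]

    if total_area <= 0.0:
        raise MeshError(f"section plane at fraction {length_fraction} misses the muscle")
    mean_fat = (fat_acc / total_area) if fat is not None else None
    return CrossSection(length_fraction=length_fraction, area=total_area, mean_fat_fraction=mean_fat)
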