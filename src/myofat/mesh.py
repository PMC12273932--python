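"""Tetrahedral mesh container and low-level mesh utilities.

The mesh is the shared substrate of the whole pipeline: geometry generation,
the Laplace fiber solve, voxel fat mapping and the mechanics solver all
operate on :class:`TetMesh`.  Conventions:

* units are mm (coordinates), so volumes are mm^3,
* tetrahedra are stored with positive signed volume,
* facet sets are arrays of ``(element, local_face)`` pairs; local face ``i``
  is the face opposite vertex ``i`` with outward orientation
  ``FACE_VERTICES[i]``,
* element order 1 (4-node) or 2 (10-node, VTK edge ordering); the first four
  columns of the connectivity are always the geometric corner vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# domain labels
MUSCLE = 0
CENTRAL_APONEUROSIS = 1
PROXIMAL_APONEUROSIS = 2
DOMAIN_NAMES = {
    MUSCLE: "muscle",
    CENTRAL_APONEUROSIS: "central_aponeurosis",
    PROXIMAL_APONEUROSIS: "proximal_aponeurosis",
}
DOMAIN_CODES = {v: k for k, v in DOMAIN_NAMES.items()}

#: outward-oriented corner vertices of the face opposite each tet vertex
FACE_VERTICES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])

#: TET10 edge ordering (VTK): midside node 4+k lies on edge EDGE_VERTICES[k]
EDGE_VERTICES = np.array([[0, 1], [1, 2], [0, 2], [0, 3], [1, 3], [2, 3]])

#: facet sets every tibialis-anterior pipeline mesh must carry
CANONICAL_FACET_SETS = (
    "distal_apo_end",
    "proximal_apo_end",
    "tibial_origin",
    "proximal_apo_inlet",
    "muscle_insertion_interface",
    "free_surface",
)
#: canonical sets that live on the global mesh boundary (the remaining two
#: are muscle/aponeurosis interface surfaces, stored from the muscle side)
EXTERIOR_FACET_SETS = (
    "distal_apo_end",
    "proximal_apo_end",
    "tibial_origin",
    "free_surface",
)


class MeshError(ValueError):
    """Raised for invalid or inconsistent mesh data."""


@dataclass
class TetMesh:
    node_coords: np.ndarray  # (n_nodes, 3) mm
    tet_conn: np.ndarray  # (n_elem, 4) or (n_elem, 10)
    elem_domain: np.ndarray  # (n_elem,) int codes
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    long_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    distal_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.tet_conn = np.asarray(self.tet_conn, dtype=np.int64)
        self.elem_domain = np.asarray(self.elem_domain, dtype=np.int64)
        self.long_axis = np.asarray(self.long_axis, dtype=float)
        self.long_axis = self.long_axis / np.linalg.norm(self.long_axis)
        self.distal_point = np.asarray(self.distal_point, dtype=float)

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.tet_conn.shape[0]

    @property
    def order(self) -> int:
        return 1 if self.tet_conn.shape[1] == 4 else 2

    @property
    def corners(self) -> np.ndarray:
        """Corner-vertex connectivity, (n_elem, 4)."""
        return self.tet_conn[:, :4]

    # ------------------------------------------------------------------
    def muscle_length(self) -> float:
        """Length of the muscle domain projected on the long axis (mm)."""
        nodes = np.unique(self.corners[self.elem_domain == MUSCLE])
        if nodes.size == 0:  # plain test meshes: use all nodes
            nodes = np.unique(self.corners)
        s = (self.node_coords[nodes] - self.distal_point) @ self.long_axis
        return float(s.max() - s.min())

    def length_fraction(self, points: np.ndarray) -> np.ndarray:
        """Length coordinate of world points: distal end 0, proximal end 1.

        Measured from the distal end along ``long_axis`` and normalised by
        the muscle length; points on the proximal extrusion map above 1.
        """
        points = np.atleast_2d(points)
        s = (points - self.distal_point) @ self.long_axis
        return s / self.muscle_length()

    def elem_centroids(self) -> np.ndarray:
        return self.node_coords[self.corners].mean(axis=1)

    # ------------------------------------------------------------------
    def face_corner_nodes(self, pairs: np.ndarray) -> np.ndarray:
        """Corner-node triples (k, 3) of (elem, local_face) pairs."""
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return self.corners[pairs[:, 0][:, None], FACE_VERTICES[pairs[:, 1]]]

    def face_nodes(self, pairs: np.ndarray) -> np.ndarray:
        """All nodes on the given faces, including midsides for order 2."""
        tris = self.face_corner_nodes(pairs)
        if self.order == 1:
            return np.unique(tris)
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        # midside node on each face edge: find local edge index
        extra = []
        for (e, lf), tri in zip(pairs, tris):
            conn = self.tet_conn[e]
            loc = {int(v): i for i, v in enumerate(conn[:4])}
            for a, b in ((0, 1), (1, 2), (2, 0)):
                ia, ib = loc[int(tri[a])], loc[int(tri[b])]
                k = _local_edge_index(ia, ib)
                extra.append(conn[4 + k])
        return np.unique(np.concatenate([tris.ravel(), np.array(extra, dtype=np.int64)]))

    def facet_set_nodes(self, name: str) -> np.ndarray:
        return self.face_nodes(self.facet_sets[name])

    # ------------------------------------------------------------------
    def validate(self, require_canonical: bool = False) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure."""
        vols = tet_volumes(self.node_coords, self.corners)
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise MeshError(f"non-positive tetrahedron volume at elements {bad[:10].tolist()}")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[np.unique(self.tet_conn)] = True
        if not used.all():
            raise MeshError(
                f"orphan nodes not referenced by any element: {np.flatnonzero(~used)[:10].tolist()}"
            )
        if require_canonical:
            missing = [n for n in CANONICAL_FACET_SETS if n not in self.facet_sets]
            if missing:
                raise MeshError(f"missing facet sets: {missing}")
            bpairs = boundary_face_pairs(self.corners)
            bkeys = set(map(tuple, np.sort(self.face_corner_nodes(bpairs), axis=1)))
            seen: dict[tuple, str] = {}
            for name in EXTERIOR_FACET_SETS:
                for tri in np.sort(self.face_corner_nodes(self.facet_sets[name]), axis=1):
                    key = tuple(tri)
                    if key not in bkeys:
                        raise MeshError(f"facet set {name!r} contains a non-boundary face")
                    if key in seen:
                        raise MeshError(f"face in both {seen[key]!r} and {name!r}")
                    seen[key] = name
            if len(seen) != len(bkeys):
                raise MeshError(
                    f"exterior facet sets cover {len(seen)} of {len(bkeys)} boundary faces"
                )


def _local_edge_index(ia: int, ib: int) -> int:
    for k, (a, b) in enumerate(EDGE_VERTICES):
        if {ia, ib} == {a, b}:
            return k
    raise ValueError(f"no tet edge between local vertices {ia}, {ib}")


# ----------------------------------------------------------------------
# basic tet computations


def tet_volumes(coords: np.ndarray, conn: np.ndarray) -> np.ndarray:
    """Signed volumes (mm^3) of tetrahedra, det convention positive for
    right-handed vertex ordering."""
    x = coords[conn[:, :4]]
    d = x[:, 1:] - x[:, :1]
    return np.linalg.det(d) / 6.0


def orient_positive(coords: np.ndarray, conn: np.ndarray) -> np.ndarray:
    """Flip vertex ordering where needed so all signed volumes are > 0."""
    conn = conn.copy()
    neg = tet_volumes(coords, conn) < 0
    conn[neg, 1], conn[neg, 2] = conn[neg, 2], conn[neg, 1].copy()
    return conn


def boundary_face_pairs(conn: np.ndarray) -> np.ndarray:
    """(elem, local_face) pairs of faces appearing in exactly one tet."""
    n_elem = conn.shape[0]
    tris = conn[:, :4][:, FACE_VERTICES]  # (n_elem, 4, 3)
    keys = np.sort(tris.reshape(-1, 3), axis=1)
    order = np.lexsort(keys.T)
    keys_sorted = keys[order]
    uniq, first, counts = np.unique(
        keys_sorted, axis=0, return_index=True, return_counts=True
    )
    single = first[counts == 1]
    flat = order[single]
    return np.column_stack([flat // 4, flat % 4])


def interface_face_pairs(
    conn: np.ndarray, domain: np.ndarray, dom_a: int, dom_b: int
) -> np.ndarray:
    """Faces shared between a dom_a element and a dom_b element, returned as
    (elem, local_face) pairs on the dom_a side."""
    tris = conn[:, :4][:, FACE_VERTICES].reshape(-1, 3)
    keys = np.sort(tris, axis=1)
    order = np.lexsort(keys.T)
    ks = keys[order]
    elem = order // 4
    out = []
    i = 0
    n = ks.shape[0]
    while i < n:
        j = i + 1
        while j < n and (ks[j] == ks[i]).all():
            j += 1
        if j - i == 2:
            e0, e1 = elem[i], elem[j - 1]
            d0, d1 = domain[e0], domain[e1]
            if {d0, d1} == {dom_a, dom_b} and d0 != d1:
                flat = order[i] if d0 == dom_a else order[j - 1]
                out.append((flat // 4, flat % 4))
        i = j
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


# ----------------------------------------------------------------------
# structured meshing helpers

_KUHN_PATHS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


def hexes_to_tets(hex_conn: np.ndarray) -> np.ndarray:
    """Split trilinear hexes (VTK vertex order) into 6 tets each (Kuhn
    subdivision); face diagonals are consistent between translated hexes."""
    # map (i, j, k) in {0,1}^3 to VTK hex local index
    vtk = {(0, 0, 0): 0, (1, 0, 0): 1, (1, 1, 0): 2, (0, 1, 0): 3,
           (0, 0, 1): 4, (1, 0, 1): 5, (1, 1, 1): 6, (0, 1, 1): 7}
    tets = []
    for path in _KUHN_PATHS:
        ijk = [0, 0, 0]
        verts = [vtk[tuple(ijk)]]
        for ax in path:
            ijk[ax] += 1
            verts.append(vtk[tuple(ijk)])
        tets.append(verts)
    tets = np.array(tets)  # (6, 4)
    return hex_conn[:, tets].reshape(-1, 4)


def structured_grid(xs: np.ndarray, ys: np.ndarray, zs: np.ndarray):
    """Structured node grid and hex connectivity for plane coordinates."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    hexes = np.column_stack([
        nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
        nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
        nid(i, j + 1, k + 1),
    ])
    return coords, hexes


def mesh_box(
    lx: float, ly: float, lz: float, nx: int = 2, ny: int = 2, nz: int = 4,
    domain: int = MUSCLE,
) -> TetMesh:
    """Axis-aligned box [0,lx]x[0,ly]x[0,lz] meshed with tets.

    Facet sets ``x0, x1, y0, y1, z0, z1`` name the six box faces; the long
    axis is +z with the distal reference at z=0.
    """
    coords, hexes = structured_grid(
        np.linspace(0, lx, nx + 1), np.linspace(0, ly, ny + 1), np.linspace(0, lz, nz + 1)
    )
    conn = orient_positive(coords, hexes_to_tets(hexes))
    mesh = TetMesh(
        node_coords=coords,
        tet_conn=conn,
        elem_domain=np.full(conn.shape[0], domain),
        long_axis=np.array([0.0, 0.0, 1.0]),
        distal_point=np.zeros(3),
    )
    b = boundary_face_pairs(conn)
    cen = coords[mesh.face_corner_nodes(b)].mean(axis=1)
    tol = 1e-9 * max(lx, ly, lz)
    for name, axis, val in (
        ("x0", 0, 0.0), ("x1", 0, lx), ("y0", 1, 0.0), ("y1", 1, ly),
        ("z0", 2, 0.0), ("z1", 2, lz),
    ):
        mesh.facet_sets[name] = b[np.abs(cen[:, axis] - val) < tol]
    return mesh


def mesh_spherical_shell_patch(
    r_inner: float, r_outer: float, nr: int = 4, ntheta: int = 6, nphi: int = 6,
    theta_range=(np.pi / 6, np.pi / 2), phi_range=(0.0, np.pi / 2),
) -> TetMesh:
    """Patch of a spherical shell (structured in r, theta, phi).

    The lateral faces are surfaces of revolution containing the radial
    direction, so a purely radial field has zero flux through them; the
    harmonic 1/r profile between ``inner`` and ``outer`` facet sets is then
    the exact continuum solution on this patch.
    """
    rs = np.linspace(r_inner, r_outer, nr + 1)
    ths = np.linspace(*theta_range, ntheta + 1)
    phs = np.linspace(*phi_range, nphi + 1)
    ref, hexes = structured_grid(rs, ths, phs)
    r, th, ph = ref[:, 0], ref[:, 1], ref[:, 2]
    coords = np.column_stack([
        r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph), r * np.cos(th)
    ])
    conn = orient_positive(coords, hexes_to_tets(hexes))
    mesh = TetMesh(
        node_coords=coords,
        tet_conn=conn,
        elem_domain=np.full(conn.shape[0], MUSCLE),
    )
    b = boundary_face_pairs(conn)
    rad = np.linalg.norm(coords[mesh.face_corner_nodes(b)], axis=2)  # (k, 3)
    dr = (r_outer - r_inner) / nr
    mesh.facet_sets["inner"] = b[np.abs(rad - r_inner).max(axis=1) < 0.1 * dr]
    mesh.facet_sets["outer"] = b[np.abs(rad - r_outer).max(axis=1) < 0.1 * dr]
    return mesh


# ----------------------------------------------------------------------
# quadratic promotion


def promote_to_quadratic(mesh: TetMesh) -> TetMesh:
    """Promote a linear mesh to 10-node tets with straight midside nodes.

    Facet sets, domains, axis data carry over unchanged (they refer to
    elements and local faces, not node ids).
    """
    if mesh.order == 2:
        return mesh
    conn = mesh.corners
    edges = conn[:, EDGE_VERTICES]  # (n_elem, 6, 2)
    flat = np.sort(edges.reshape(-1, 2), axis=1)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.node_coords[uniq[:, 0]] + mesh.node_coords[uniq[:, 1]])
    coords = np.vstack([mesh.node_coords, mid])
    mid_ids = mesh.n_nodes + inv.reshape(-1, 6)
    conn10 = np.column_stack([conn, mid_ids])
    return TetMesh(
        node_coords=coords,
        tet_conn=conn10,
        elem_domain=mesh.elem_domain.copy(),
        facet_sets={k: v.copy() for k, v in mesh.facet_sets.items()},
        long_axis=mesh.long_axis.copy(),
        distal_point=mesh.distal_point.copy(),
    )
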