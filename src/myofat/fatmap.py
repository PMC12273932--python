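"""Per-element fat fractions: voxel mapping, anatomic schemes, pseudo maps.

Four anatomic representations of an imaged fat distribution are supported:
the element-averaged voxel map (``mri``), its 50%-threshold binarisation
(``binary``), length-third regional means (``regional``) and the uniform
volumetric mean (``total``).  Pseudo maps place beta-distributed fat in one
of eight canonical regions (length thirds, distal+proximal combination,
medial/lateral/anterior/posterior halves) with a prescribed regional mean
``gamma``; with the beta shape alpha fixed at 2 the second shape parameter
follows from gamma = alpha/(alpha+beta).

All schemes assign fat to muscle-domain elements only; aponeurosis
elements always carry 0%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import element_volumes
from .mesh import MUSCLE, MeshError, TetMesh

__all__ = [
    "VoxelFatMap",
    "ElementFatField",
    "PseudoScheme",
    "PSEUDO_REGIONS",
    "map_voxels_to_elements",
    "binary_map",
    "regional_map",
    "total_map",
    "beta_from_gamma",
    "pseudo_map",
    "region_mask",
    "lean_volume",
    "volumetric_fat_fraction",
    "load_fat_image",
    "save_fat_image",
]

ALPHA_DIST = 2.0  # fixed beta-distribution shape

PSEUDO_REGIONS = (
    "distal_third",
    "middle_third",
    "proximal_third",
    "proximal_distal",
    "medial",
    "lateral",
    "anterior",
    "posterior",
)


@dataclass
class VoxelFatMap:
    """3-D fat-fraction image (percent per voxel) with voxel-to-world affine."""

    data: np.ndarray  # (ni, nj, nk), percent, NaN allowed outside the body
    affine: np.ndarray  # 4x4, voxel index -> world mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise ValueError("affine must be an invertible 4x4 matrix")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 100 + 1e-9):
            raise ValueError("fat fractions must lie in [0, 100] percent")

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_centers(self) -> np.ndarray:
        ni, nj, nk = self.data.shape
        idx = np.stack(
            np.meshgrid(np.arange(ni), np.arange(nj), np.arange(nk), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class ElementFatField:
    """Per-element fat fraction (percent) with provenance."""

    values: np.ndarray  # (n_elems,), in [0, 100]; 0 on aponeurosis domains
    provenance: str  # mri | binary | regional | total | pseudo:<region>
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-9 or self.values.max() > 100 + 1e-9:
            raise ValueError("element fat fractions must lie in [0, 100]")


@dataclass
class PseudoScheme:
    """Regional beta-distributed fat assignment."""

    region: str  # one of PSEUDO_REGIONS
    gamma: float  # target regional mean, percent in (0, 100]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in PSEUDO_REGIONS:
            raise ValueError(f"unknown region selector {self.region!r}; choose from {PSEUDO_REGIONS}")
        if not 0.0 < self.gamma <= 100.0:
            raise ValueError("gamma must be in (0, 100] percent")


# ----------------------------------------------------------------------
# voxel -> element


def _barycentric(points: np.ndarray, tet: np.ndarray) -> np.ndarray:
    T = (tet[1:] - tet[0]).T
    lam = np.linalg.solve(T, (points - tet[0]).T).T
    return np.column_stack([1.0 - lam.sum(axis=1), lam])


def map_voxels_to_elements(img: VoxelFatMap, mesh: TetMesh) -> ElementFatField:
    """Average the fat fractions of voxels whose centers fall inside each
    muscle element; elements without any voxel center get the image value
    interpolated at their centroid.  Aponeurosis elements carry 0."""
    from scipy.ndimage import map_coordinates

    centers = img.voxel_centers()
    vals = img.data.ravel()
    good = np.isfinite(vals)
    centers, vals = centers[good], vals[good]

    lo = mesh.node_coords.min(axis=0) - 1e-9
    hi = mesh.node_coords.max(axis=0) + 1e-9
    inbox = np.all((centers >= lo) & (centers <= hi), axis=1)
    if not inbox.any():
        raise MeshError("mesh lies entirely outside the fat image")
    centers, vals = centers[inbox], vals[inbox]

    # bucket voxel centers on a uniform grid keyed by cell index for
    # candidate lookup per element bounding box
    cell = np.maximum(img.voxel_size.max(), 1e-6)
    keys = np.floor((centers - lo) / cell).astype(np.int64)
    order = np.lexsort(keys.T)
    keys_s = keys[order]
    bucket: dict[tuple, tuple[int, int]] = {}
    start = 0
    for i in range(1, len(keys_s) + 1):
        if i == len(keys_s) or (keys_s[i] != keys_s[start]).any():
            bucket[tuple(keys_s[start])] = (start, i)
            start = i

    out = np.zeros(mesh.n_elems)
    unassigned = []
    muscle = np.flatnonzero(mesh.elem_domain == MUSCLE)
    coords = mesh.node_coords
    for e in muscle:
        tet = coords[mesh.corners[e]]
        k0 = np.floor((tet.min(axis=0) - lo) / cell).astype(np.int64)
        k1 = np.floor((tet.max(axis=0) - lo) / cell).astype(np.int64)
        cand = []
        for kx in range(k0[0], k1[0] + 1):
            for ky in range(k0[1], k1[1] + 1):
                for kz in range(k0[2], k1[2] + 1):
                    rng = bucket.get((kx, ky, kz))
                    if rng:
                        cand.append(order[rng[0] : rng[1]])
        if cand:
            cand = np.concatenate(cand)
            lam = _barycentric(centers[cand], tet)
            inside = np.all(lam > -1e-9, axis=1)
            if inside.any():
                out[e] = vals[cand[inside]].mean()
                continue
        unassigned.append(e)

    if unassigned:
        unassigned = np.array(unassigned)
        cen = coords[mesh.corners[unassigned]].mean(axis=1)
        inv = np.linalg.inv(img.affine)
        ijk = (cen @ inv[:3, :3].T + inv[:3, 3]).T
        filled = np.nan_to_num(img.data, nan=0.0)
        out[unassigned] = np.clip(
            map_coordinates(filled, ijk, order=1, mode="nearest"), 0.0, 100.0
        )
    return ElementFatField(values=np.clip(out, 0.0, 100.0), provenance="mri")


# ----------------------------------------------------------------------
# anatomic schemes


def binary_map(fat: ElementFatField) -> ElementFatField:
    """Threshold at 50%: values >= 50 become 100, the rest 0 (idempotent)."""
    v = np.where(fat.values >= 50.0, 100.0, 0.0)
    return ElementFatField(values=v, provenance="binary")


def _thirds(mesh: TetMesh) -> np.ndarray:
    """Region index per element: 0 distal [0,1/3), 1 middle [1/3,2/3),
    2 proximal [2/3, ...] by centroid length fraction."""
    frac = mesh.length_fraction(mesh.elem_centroids())
    return np.clip((frac * 3).astype(int), 0, 2)


def regional_map(fat: ElementFatField, mesh: TetMesh) -> ElementFatField:
    """Replace values in each length third of the muscle by that third's
    volume-weighted mean (exact conservation of the overall mean)."""
    vols = element_volumes(mesh)
    thirds = _thirds(mesh)
    muscle = mesh.elem_domain == MUSCLE
    v = np.zeros(mesh.n_elems)
    for r in range(3):
        sel = muscle & (thirds == r)
        if not sel.any():
            raise MeshError(f"length third {r} contains no muscle elements")
        v[sel] = np.average(fat.values[sel], weights=vols[sel])
    return ElementFatField(values=v, provenance="regional")


def total_map(fat: ElementFatField, mesh: TetMesh) -> ElementFatField:
    """Uniform map at the total volumetric fat fraction."""
    vols = element_volumes(mesh)
    muscle = mesh.elem_domain == MUSCLE
    mean = np.average(fat.values[muscle], weights=vols[muscle])
    v = np.zeros(mesh.n_elems)
    v[muscle] = mean
    return ElementFatField(values=v, provenance="total")


# ----------------------------------------------------------------------
# pseudo maps


def beta_from_gamma(gamma: float) -> float | None:
    """Second beta shape parameter for mean ``gamma`` (fraction in (0, 1])
    with the first shape fixed at 2: beta = alpha (1 - gamma) / gamma.
    Returns None for the degenerate gamma = 1 (constant assignment)."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must be a fraction in (0, 1]")
    if gamma == 1.0:
        return None
    return ALPHA_DIST * (1.0 - gamma) / gamma


def region_mask(mesh: TetMesh, region: str, ml_axis=None, ap_axis=None, n_slabs: int = 24):
    """Boolean element mask of a pseudo-scheme region (muscle domain only).

    Length-wise regions use centroid length fractions; the proximal+distal
    combination is the distal third plus the proximal 20% of length.
    Cross-section halves split each length slab at 50% of its extent along
    the medial-lateral or anterior-posterior axis (bounding-box midline).
    """
    muscle = mesh.elem_domain == MUSCLE
    cen = mesh.elem_centroids()
    frac = mesh.length_fraction(cen)
    if region == "distal_third":
        sel = frac < 1.0 / 3.0
    elif region == "middle_third":
        sel = (frac >= 1.0 / 3.0) & (frac < 2.0 / 3.0)
    elif region == "proximal_third":
        sel = frac >= 2.0 / 3.0
    elif region == "proximal_distal":
        sel = (frac < 1.0 / 3.0) | (frac >= 0.8)
    elif region in ("medial", "lateral", "anterior", "posterior"):
        if region in ("medial", "lateral"):
            axis = np.asarray(ml_axis, dtype=float) if ml_axis is not None else np.array([1.0, 0.0, 0.0])
        else:
            axis = np.asarray(ap_axis, dtype=float) if ap_axis is not None else np.array([0.0, 1.0, 0.0])
        s = cen @ axis
        sel = np.zeros(mesh.n_elems, dtype=bool)
        slabs = np.clip((frac * n_slabs).astype(int), 0, n_slabs - 1)
        for k in range(n_slabs):
            ks = muscle & (slabs == k)
            if not ks.any():
                continue
            mid = 0.5 * (s[ks].min() + s[ks].max())
            if region in ("medial", "posterior"):
                sel |= ks & (s <= mid)
            else:
                sel |= ks & (s > mid)
    else:
        raise ValueError(f"unknown region selector {region!r}")
    return sel & muscle


def pseudo_map(mesh: TetMesh, scheme: PseudoScheme, ml_axis=None, ap_axis=None) -> ElementFatField:
    """Draw i.i.d. Beta(2, beta(gamma)) fat fractions (scaled to percent)
    for elements inside the scheme's region; elements outside get 0.
    Reproducible for a fixed seed."""
    sel = region_mask(mesh, scheme.region, ml_axis=ml_axis, ap_axis=ap_axis)
    if not sel.any():
        raise MeshError(f"region {scheme.region!r} selected no muscle elements")
    v = np.zeros(mesh.n_elems)
    gamma = scheme.gamma / 100.0
    b = beta_from_gamma(gamma)
    if b is None:  # gamma = 100%: degenerate Beta, constant full fat
        v[sel] = 100.0
    else:
        rng = np.random.default_rng(scheme.seed)
        v[sel] = 100.0 * rng.beta(ALPHA_DIST, b, size=int(sel.sum()))
    return ElementFatField(
        values=v,
        provenance=f"pseudo:{scheme.region}",
        params={"gamma": scheme.gamma, "seed": scheme.seed},
    )


# ----------------------------------------------------------------------
# summary quantities


def lean_volume(fat: ElementFatField, mesh: TetMesh) -> float:
    """Fat-free muscle volume sum(vol_e (1 - X_e/100)) over muscle (mm^3)."""
    vols = element_volumes(mesh)
    muscle = mesh.elem_domain == MUSCLE
    return float(np.sum(vols[muscle] * (1.0 - fat.values[muscle] / 100.0)))


def volumetric_fat_fraction(fat: ElementFatField, mesh: TetMesh) -> float:
    """Volume-weighted mean fat fraction over the muscle domain (percent)."""
    vols = element_volumes(mesh)
    muscle = mesh.elem_domain == MUSCLE
    return float(np.average(fat.values[muscle], weights=vols[muscle]))


# ----------------------------------------------------------------------
# NIfTI I/O


def load_fat_image(path) -> VoxelFatMap:
    import nibabel as nib

    img = nib.load(str(path))
    return VoxelFatMap(data=np.asarray(img.dataobj, dtype=float), affine=img.affine)


def save_fat_image(img: VoxelFatMap, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(img.data.astype(np.float32), img.affine), str(path))
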