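"""Synthetic voxel fat-fraction images.

Generates NIfTI-style fat maps with the spatial structure the mapping
stage assumes — uniform levels, axial ramps, smoothed regional blobs,
medial/lateral gradients and spatially correlated diffuse noise — so the
imaging-based pipeline is testable without scan data.  Patterns are
parameterised in mesh-intrinsic coordinates (length fraction, ML/AP axes)
and then rasterised on a voxel grid covering the mesh bounding box, so
one recipe stresses any geometry.  Default voxel size 1.1 x 1.1 x 4.0 mm
mimics an axial T1 Dixon acquisition (thick slices along the long axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .fatmap import VoxelFatMap
from .mesh import TetMesh

__all__ = ["FatImageRecipe", "make_fat_image", "PATTERNS"]

PATTERNS = (
    "uniform",
    "axial_ramp",
    "distal_blob",
    "middle_blob",
    "proximal_blob",
    "medial_gradient",
    "lateral_gradient",
    "diffuse_noise",
    "composite",
)


@dataclass
class FatImageRecipe:
    pattern: str = "uniform"
    amplitude: float = 40.0  # peak / mean fat level, percent
    voxel_size: tuple = (1.1, 1.1, 4.0)  # mm, slices along the long axis
    smoothness: float = 8.0  # Gaussian smoothing scale, mm
    margin: float = 6.0  # image padding around the mesh, mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if not 0.0 <= self.amplitude <= 100.0:
            raise ValueError("amplitude must be in [0, 100] percent")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be > 0")


def make_fat_image(recipe: FatImageRecipe, mesh: TetMesh) -> VoxelFatMap:
    """Rasterise the recipe over the mesh bounding box (+margin).

    Values are percent in [0, 100]; deterministic for a fixed seed.
    """
    lo = mesh.node_coords.min(axis=0) - recipe.margin
    hi = mesh.node_coords.max(axis=0) + recipe.margin
    vs = np.asarray(recipe.voxel_size, dtype=float)
    shape = np.maximum(np.ceil((hi - lo) / vs).astype(int), 1)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = lo + 0.5 * vs

    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=-1
    ).astype(float)
    world = idx * vs + (lo + 0.5 * vs)
    frac = mesh.length_fraction(world.reshape(-1, 3)).reshape(shape)
    ml = world[..., 0] - 0.5 * (lo[0] + hi[0])  # signed ML coordinate
    ml_half = 0.5 * (hi[0] - lo[0])

    A = recipe.amplitude
    rng = np.random.default_rng(recipe.seed)

    def blob(center: float) -> np.ndarray:
        img = np.where(np.abs(frac - center) < 1.0 / 6.0, A, 0.0)
        return _smooth(img, recipe, vs)

    if recipe.pattern == "uniform":
        data = np.full(shape, A)
    elif recipe.pattern == "axial_ramp":
        data = A * np.clip(frac, 0.0, 1.0)
    elif recipe.pattern == "distal_blob":
        data = blob(1.0 / 6.0)
    elif recipe.pattern == "middle_blob":
        data = blob(0.5)
    elif recipe.pattern == "proximal_blob":
        data = blob(5.0 / 6.0)
    elif recipe.pattern == "medial_gradient":
        data = A * np.clip(0.5 - 0.5 * ml / ml_half, 0.0, 1.0)
    elif recipe.pattern == "lateral_gradient":
        data = A * np.clip(0.5 + 0.5 * ml / ml_half, 0.0, 1.0)
    elif recipe.pattern == "diffuse_noise":
        noise = rng.standard_normal(shape)
        noise = _smooth(noise, recipe, vs, renorm=True)
        data = A + 0.5 * A * noise
    else:  # composite: blob + gradient + correlated noise
        noise = _smooth(rng.standard_normal(shape), recipe, vs, renorm=True)
        data = 0.5 * blob(1.0 / 6.0) + 0.3 * A * np.clip(
            0.5 - 0.5 * ml / ml_half, 0.0, 1.0
        ) + 0.15 * A * (1.0 + noise)
    return VoxelFatMap(data=np.clip(data, 0.0, 100.0), affine=affine)


def _smooth(img: np.ndarray, recipe: FatImageRecipe, vs: np.ndarray, renorm: bool = False):
    sigma = recipe.smoothness / vs
    out = gaussian_filter(img, sigma=sigma, mode="nearest")
    if renorm and out.std() > 0:
        out = (out - out.mean()) / out.std()
    return out
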