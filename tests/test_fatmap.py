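"""Fat mapping: voxel averaging, anatomic schemes, beta-sampled pseudo maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myofat import element_volumes
from myofat.fatmap import (
    ALPHA_DIST,
    ElementFatField,
    PseudoScheme,
    VoxelFatMap,
    beta_from_gamma,
    binary_map,
    lean_volume,
    map_voxels_to_elements,
    pseudo_map,
    region_mask,
    regional_map,
    total_map,
    volumetric_fat_fraction,
)
from myofat.images import FatImageRecipe, make_fat_image
from myofat.mesh import MUSCLE, MeshError


@pytest.fixture(scope="module")
def vols(coarse_ta):
    return element_volumes(coarse_ta)


@pytest.fixture(scope="module")
def muscle(coarse_ta):
    return coarse_ta.elem_domain == MUSCLE


# ----------------------------------------------------------------------
# voxel -> element


def test_constant_image_maps_exactly(coarse_ta, muscle):
    img = make_fat_image(FatImageRecipe(pattern="uniform", amplitude=30.0), coarse_ta)
    f = map_voxels_to_elements(img, coarse_ta)
    assert np.allclose(f.values[muscle], 30.0, atol=1e-9)
    assert np.all(f.values[~muscle] == 0.0)
    assert f.provenance == "mri"


def test_axial_ramp_matches_centroid_values(coarse_ta, muscle):
    img = make_fat_image(FatImageRecipe(pattern="axial_ramp", amplitude=100.0), coarse_ta)
    f = map_voxels_to_elements(img, coarse_ta)
    frac = coarse_ta.length_fraction(coarse_ta.elem_centroids())
    err = np.abs(f.values[muscle] - 100.0 * np.clip(frac[muscle], 0, 1))
    assert np.median(err) < 2.0


def test_coarse_voxels_fall_back_to_centroid(coarse_ta, muscle, vols):
    """Voxels much larger than elements: every element still assigned and
    the volume-weighted mean is close to the image mean."""
    img = make_fat_image(
        FatImageRecipe(pattern="axial_ramp", amplitude=80.0, voxel_size=(12.0, 12.0, 24.0)),
        coarse_ta,
    )
    f = map_voxels_to_elements(img, coarse_ta)
    ramp_mean = np.average(
        80.0 * np.clip(coarse_ta.length_fraction(coarse_ta.elem_centroids()[muscle]), 0, 1),
        weights=vols[muscle],
    )
    got = np.average(f.values[muscle], weights=vols[muscle])
    assert got == pytest.approx(ramp_mean, rel=0.05)


def test_mesh_outside_image_raises(coarse_ta):
    img = VoxelFatMap(data=np.zeros((4, 4, 4)), affine=np.diag([1.0, 1, 1, 1]))
    img.affine[:3, 3] = [5000.0, 5000.0, 5000.0]
    with pytest.raises(MeshError):
        map_voxels_to_elements(img, coarse_ta)


# ----------------------------------------------------------------------
# anatomic schemes


def test_binary_threshold_at_50(coarse_ta):
    v = np.zeros(coarse_ta.n_elems)
    v[0], v[1], v[2] = 50.0, 49.9, 73.0
    b = binary_map(ElementFatField(values=v, provenance="mri"))
    assert b.values[0] == 100.0  # exactly 50 maps to full fat
    assert b.values[1] == 0.0
    assert b.values[2] == 100.0
    assert set(np.unique(b.values)) <= {0.0, 100.0}


def test_binary_idempotent(coarse_ta):
    rng = np.random.default_rng(0)
    f = ElementFatField(values=rng.uniform(0, 100, coarse_ta.n_elems), provenance="mri")
    once = binary_map(f)
    twice = binary_map(once)
    assert np.array_equal(once.values, twice.values)


def test_regional_map_piecewise_constant_and_conserving(coarse_ta, muscle, vols):
    rng = np.random.default_rng(1)
    v = np.where(muscle, rng.uniform(0, 100, coarse_ta.n_elems), 0.0)
    f = ElementFatField(values=v, provenance="mri")
    r = regional_map(f, coarse_ta)
    frac = coarse_ta.length_fraction(coarse_ta.elem_centroids())
    for lo, hi in [(0, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 1.01)]:
        sel = muscle & (frac >= lo) & (frac < hi)
        assert np.ptp(r.values[sel]) == pytest.approx(0.0, abs=1e-12)
    assert volumetric_fat_fraction(r, coarse_ta) == pytest.approx(
        volumetric_fat_fraction(f, coarse_ta), abs=1e-9
    )


def test_regional_map_fixed_point_on_uniform(coarse_ta, muscle):
    f = ElementFatField(values=np.where(muscle, 20.0, 0.0), provenance="mri")
    r = regional_map(f, coarse_ta)
    assert np.allclose(r.values, f.values)


def test_total_map_uniform_mean(coarse_ta, muscle, vols):
    # 50% in (approximately) half of the volume, 0 in the rest
    frac = coarse_ta.length_fraction(coarse_ta.elem_centroids())
    v = np.where(muscle & (frac < 0.5), 50.0, 0.0)
    f = ElementFatField(values=v, provenance="mri")
    t = total_map(f, coarse_ta)
    mean = np.average(v[muscle], weights=vols[muscle])
    assert np.ptp(t.values[muscle]) == pytest.approx(0.0, abs=1e-12)
    assert t.values[muscle][0] == pytest.approx(mean, abs=1e-12)
    assert volumetric_fat_fraction(t, coarse_ta) == pytest.approx(
        volumetric_fat_fraction(f, coarse_ta), abs=1e-12
    )


# ----------------------------------------------------------------------
# pseudo maps


def test_beta_from_gamma_closed_forms():
    assert beta_from_gamma(0.5) == pytest.approx(2.0)
    assert beta_from_gamma(0.2) == pytest.approx(8.0)
    assert beta_from_gamma(1.0) is None  # degenerate constant assignment
    with pytest.raises(ValueError):
        beta_from_gamma(0.0)


@given(gamma=st.floats(min_value=0.01, max_value=0.99))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_beta_from_gamma_inverts_mean(gamma):
    b = beta_from_gamma(gamma)
    assert ALPHA_DIST / (ALPHA_DIST + b) == pytest.approx(gamma, rel=1e-12)


def test_pseudo_degenerate_full_fat(coarse_ta, muscle):
    f = pseudo_map(coarse_ta, PseudoScheme(region="middle_third", gamma=100.0))
    sel = region_mask(coarse_ta, "middle_third")
    assert np.all(f.values[sel] == 100.0)
    assert np.all(f.values[~sel] == 0.0)


def test_pseudo_regional_mean_matches_gamma(coarse_ta, vols):
    """Region mean within 3 Monte-Carlo standard errors of the Beta mean."""
    gamma = 40.0
    f = pseudo_map(coarse_ta, PseudoScheme(region="distal_third", gamma=gamma, seed=5))
    sel = region_mask(coarse_ta, "distal_third")
    n = int(sel.sum())
    b = beta_from_gamma(gamma / 100.0)
    var = ALPHA_DIST * b / ((ALPHA_DIST + b) ** 2 * (ALPHA_DIST + b + 1.0))
    se = 100.0 * np.sqrt(var / n)
    assert abs(f.values[sel].mean() - gamma) < 3.0 * se


def test_pseudo_variance_matches_beta(coarse_ta):
    gamma = 50.0
    f = pseudo_map(coarse_ta, PseudoScheme(region="proximal_third", gamma=gamma, seed=2))
    sel = region_mask(coarse_ta, "proximal_third")
    b = beta_from_gamma(0.5)
    var = 1e4 * ALPHA_DIST * b / ((ALPHA_DIST + b) ** 2 * (ALPHA_DIST + b + 1.0))
    assert f.values[sel].var() == pytest.approx(var, rel=0.35)


def test_proximal_distal_gap_is_fat_free(coarse_ta, muscle):
    f = pseudo_map(coarse_ta, PseudoScheme(region="proximal_distal", gamma=70.0, seed=1))
    frac = coarse_ta.length_fraction(coarse_ta.elem_centroids())
    gap = muscle & (frac >= 1 / 3 + 1e-9) & (frac < 0.8 - 1e-9)
    assert np.all(f.values[gap] == 0.0)


def test_halves_partition_muscle(coarse_ta, muscle):
    for a, b in [("medial", "lateral"), ("anterior", "posterior")]:
        ma, mb = region_mask(coarse_ta, a), region_mask(coarse_ta, b)
        assert not (ma & mb).any()
        assert (ma | mb).sum() == muscle.sum()


def test_pseudo_deterministic_per_seed(coarse_ta):
    s = PseudoScheme(region="medial", gamma=30.0, seed=9)
    f1 = pseudo_map(coarse_ta, s)
    f2 = pseudo_map(coarse_ta, s)
    assert np.array_equal(f1.values, f2.values)
    f3 = pseudo_map(coarse_ta, PseudoScheme(region="medial", gamma=30.0, seed=10))
    assert not np.array_equal(f1.values, f3.values)


def test_unknown_region_rejected():
    with pytest.raises(ValueError, match="unknown region"):
        PseudoScheme(region="dorsal", gamma=50.0)


# ----------------------------------------------------------------------
# summary quantities


def test_lean_volume_arithmetic(coarse_ta, muscle, vols):
    mv = vols[muscle].sum()
    zero = ElementFatField(values=np.zeros(coarse_ta.n_elems), provenance="x")
    full = ElementFatField(values=np.where(muscle, 100.0, 0.0), provenance="x")
    quarter = ElementFatField(values=np.where(muscle, 25.0, 0.0), provenance="x")
    assert lean_volume(zero, coarse_ta) == pytest.approx(mv)
    assert lean_volume(full, coarse_ta) == pytest.approx(0.0, abs=1e-9)
    assert lean_volume(quarter, coarse_ta) == pytest.approx(0.75 * mv)


def test_bounds_enforced():
    with pytest.raises(ValueError):
        ElementFatField(values=np.array([-1.0]), provenance="x")
    with pytest.raises(ValueError):
        ElementFatField(values=np.array([101.0]), provenance="x")
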