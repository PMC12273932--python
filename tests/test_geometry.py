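"""Synthetic geometry: volumes, sections, facet sets, determinism."""

import numpy as np
import pytest

from myofat import (
    MeshError,
    SynthGeomParams,
    cross_section,
    element_volumes,
    generate_synthetic_ta,
    mesh_box,
)
from myofat.geometry import analytic_muscle_volume
from myofat.mesh import CENTRAL_APONEUROSIS, MUSCLE, PROXIMAL_APONEUROSIS


def test_unit_tet_volume():
    coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    conn = np.array([[0, 1, 2, 3]])
    from myofat.mesh import tet_volumes

    assert tet_volumes(coords, conn)[0] == pytest.approx(1.0 / 6.0)


def test_box_volume_conservation():
    box = mesh_box(10, 10, 10, 3, 3, 3)
    assert element_volumes(box).sum() == pytest.approx(1000.0, rel=1e-9)


def test_synthetic_volume_matches_taper_profile(default_ta):
    """Mesh volume tracks the analytic profile volume within 1%."""
    p = SynthGeomParams()
    vols = element_volumes(default_ta)
    mesh_vol = vols[default_ta.elem_domain != PROXIMAL_APONEUROSIS].sum()
    assert mesh_vol == pytest.approx(analytic_muscle_volume(p), rel=0.01)


def test_volume_error_decreases_under_refinement():
    errs = []
    for nz, nxy in [(10, 4), (20, 6), (40, 8)]:
        p = SynthGeomParams(nx=nxy, ny=nxy, nz=nz)
        m = generate_synthetic_ta(p)
        v = element_volumes(m)[m.elem_domain != PROXIMAL_APONEUROSIS].sum()
        errs.append(abs(v - analytic_muscle_volume(p)) / analytic_muscle_volume(p))
    assert errs[2] < errs[0]


def test_facet_sets_partition_boundary(coarse_ta):
    coarse_ta.validate(require_canonical=True)


def test_tibial_origin_in_proximal_30_percent(coarse_ta):
    tris = coarse_ta.face_corner_nodes(coarse_ta.facet_sets["tibial_origin"])
    frac = coarse_ta.length_fraction(coarse_ta.node_coords[tris].mean(axis=1))
    assert frac.min() >= 0.70 - 1e-9


def test_zero_extrusion_degenerates_cleanly():
    m = generate_synthetic_ta(SynthGeomParams(nx=4, ny=4, nz=10, extrusion_length=0.0))
    assert not (m.elem_domain == PROXIMAL_APONEUROSIS).any()
    # the inlet set coincides with the proximal muscle face
    tris = m.face_corner_nodes(m.facet_sets["proximal_apo_inlet"])
    z = m.node_coords[tris][..., 2]
    assert np.allclose(z, 300.0)


def test_generator_deterministic(coarse_params, coarse_ta):
    m2 = generate_synthetic_ta(coarse_params)
    assert np.array_equal(m2.node_coords, coarse_ta.node_coords)
    assert np.array_equal(m2.tet_conn, coarse_ta.tet_conn)


def test_degenerate_parameters_rejected():
    with pytest.raises((ValueError, MeshError)):
        SynthGeomParams(taper_end=0.0)
    with pytest.raises(MeshError, match="apo_thickness"):
        SynthGeomParams(ny=4, apo_thickness=10.0)


def test_length_fraction_monotone_along_axis(coarse_ta):
    z = np.linspace(1.0, 299.0, 40)
    pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    frac = coarse_ta.length_fraction(pts)
    assert np.all(np.diff(frac) > 0)
    assert frac[0] == pytest.approx(1.0 / 300.0, rel=1e-6)


class TestCrossSection:
    def test_bar_area(self):
        bar = mesh_box(10, 10, 300, 2, 2, 10)
        cs = cross_section(bar, 0.5)
        assert cs.area == pytest.approx(100.0, rel=1e-6)

    def test_uniform_fat_mean(self):
        bar = mesh_box(10, 10, 300, 2, 2, 10)
        cs = cross_section(bar, 0.37, fat=np.full(bar.n_elems, 40.0))
        assert cs.mean_fat_fraction == pytest.approx(40.0, rel=1e-9)

    def test_max_csa_near_60_percent(self, default_ta):
        fracs = np.linspace(0.05, 0.95, 19)
        areas = [cross_section(default_ta, f).area for f in fracs]
        assert fracs[int(np.argmax(areas))] == pytest.approx(0.60, abs=0.051)

    def test_plane_outside_raises(self, coarse_ta):
        with pytest.raises(ValueError):
            cross_section(coarse_ta, 1.5)

    def test_muscle_only(self, coarse_ta):
        """Aponeurosis elements do not contribute to muscle CSA."""
        cs = cross_section(coarse_ta, 0.2)
        # compare against the full elliptical section: the sheet cuts a hole
        from myofat.geometry import taper_profile

        p = SynthGeomParams(nx=4, ny=4, nz=10)
        full = np.pi * 20 * 15 * taper_profile(0.2, p) ** 2
        assert cs.area < full
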