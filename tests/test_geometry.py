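import numpy as np
import pytest

from aortatlas.core import EXCLUDED, ROI_NAMES, VertexField
from aortatlas import geometry as geo
from aortatlas.synthetic import cylinder_mesh

from conftest import straight_centerline


def _sphere_mask(radius=12.0, spacing=1.0, pad=4):
    n = int(2 * (radius + pad) / spacing) + 1
    c = (n - 1) / 2 * spacing
    x = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    mask = ((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2 <= radius**2).astype(np.uint8)
    return mask, c


def test_mask_to_surface_sphere_area_oracle():
    # [DERIVED] sphere surface area 4*pi*r^2 within 5%
    mask, c = _sphere_mask(radius=12.0)
    mesh = geo.mask_to_surface(mask, spacing=1.0)
    assert mesh.total_area == pytest.approx(4 * np.pi * 12.0**2, rel=0.05)
    # outward orientation: normals align with the radial direction
    radial = mesh.vertices - np.array([c, c, c])
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    assert np.einsum("ij,ij->i", mesh.normals, radial).mean() > 0.9


def test_mask_to_surface_errors():
    with pytest.raises(ValueError, match="empty"):
        geo.mask_to_surface(np.zeros((5, 5, 5), dtype=np.uint8), 1.0)
    two = np.zeros((24, 10, 10), dtype=np.uint8)
    two[2:8, 2:8, 2:8] = 1
    two[14:20, 2:8, 2:8] = 1
    with pytest.raises(ValueError, match="ambiguous"):
        geo.mask_to_surface(two, 1.0)


def test_mask_to_surface_origin_offset():
    mask, _ = _sphere_mask(radius=8.0)
    a = geo.mask_to_surface(mask, 1.0, origin=(0, 0, 0))
    b = geo.mask_to_surface(mask, 1.0, origin=(5.0, -3.0, 2.0))
    assert np.allclose(b.vertices, a.vertices + [5.0, -3.0, 2.0])


def test_extract_centerline_straight_tube(tube_steady):
    sub = tube_steady
    cl = geo.extract_centerline(
        sub.lumen_mask, sub.spacing, sub.inlet_point, sub.outlet_point,
        origin=sub.origin, stations=sub.landmarks,
    )
    # [DERIVED] a 60 mm straight tube has a ~60 mm near-axial centerline
    assert cl.length == pytest.approx(60.0, abs=3.0)
    assert np.linalg.norm(cl.points[0] - sub.inlet_point) < 3.0
    assert np.linalg.norm(cl.points[-1] - sub.outlet_point) < 3.0
    # the path hugs the axis (distance transform rewards the middle)
    assert np.abs(cl.points[:, :2]).max() < 2.0


def test_extract_centerline_candy_cane_length(small_subject):
    sub = small_subject
    cl = geo.extract_centerline(
        sub.lumen_mask, sub.spacing, sub.inlet_point, sub.outlet_point,
        origin=sub.origin, stations=sub.landmarks,
    )
    expected = 50.0 + np.pi * 30.0 + 110.0
    assert cl.length == pytest.approx(expected, rel=0.05)
    for st in ("annulus", "PA_bifurcation", "brachiocephalic", "left_subclavian", "diaphragm"):
        assert st in cl.stations


def test_extract_centerline_disconnected_mask_fails():
    mask = np.zeros((40, 9, 9), dtype=np.uint8)
    mask[1:15, 3:6, 3:6] = 1
    mask[25:39, 3:6, 3:6] = 1
    with pytest.raises(ValueError):
        geo.extract_centerline(mask, 1.0, (2.0, 4.0, 4.0), (38.0, 4.0, 4.0))


def test_label_rois_partitions_by_arclength_bands(cyl):
    cl = straight_centerline(length=60.0)
    labels = geo.label_rois(cyl, cl)
    s = cyl.vertices[:, 2] + 30.0  # arclength of the nearest axis point
    pa_desc = geo.descending_pa_level_from_centerline(cl)
    bands = {
        "pAAo": (0.0, 15.0),
        "dAAo": (15.0, 24.0),
        "pDAo": (30.0, pa_desc),
        "dDAo": (pa_desc, 60.0),
    }
    for roi, (a, b) in bands.items():
        inside = (s >= a + 1) & (s < b - 1)  # away from band edges
        assert np.all(labels[inside] == roi)
    assert np.all(labels[(s > 25) & (s < 29)] == EXCLUDED)  # arch band
    assert set(np.unique(labels)) <= set(ROI_NAMES) | {EXCLUDED}


def test_label_rois_requires_stations(cyl):
    with pytest.raises(ValueError, match="station"):
        geo.label_rois(cyl, straight_centerline(with_stations=False))


def test_measure_diameter_cylinder_oracle(cyl):
    cl = straight_centerline(length=60.0)
    # station between vertex rings so the plane cuts triangle interiors
    d_area = geo.measure_diameter(cyl, cl, 29.0, mode="area")
    # [DERIVED] area-equivalent diameter of an inscribed 48-gon section
    n = 48
    poly_area = 0.5 * n * 10.0**2 * np.sin(2 * np.pi / n)
    assert d_area == pytest.approx(2 * np.sqrt(poly_area / np.pi), rel=0.02)
    d_c2c = geo.measure_diameter(cyl, cl, 29.0, mode="cusp_to_cusp")
    assert d_c2c == pytest.approx(20.0, rel=0.02)
    assert d_c2c >= d_area - 1e-9
    with pytest.raises(ValueError):
        geo.measure_diameter(cyl, cl, 1000.0)
    with pytest.raises(ValueError):
        geo.measure_diameter(cyl, cl, 29.0, mode="nope")


def test_select_template_picks_central_mesh(cyl):
    meshes = [cyl.translated([-4, 0, 0]), cyl, cyl.translated([4, 0, 0])]
    assert geo.select_template(meshes) == 1
    # stable under relabelling: the same mesh wins
    assert geo.select_template(meshes[::-1]) == 1
    with pytest.raises(ValueError):
        geo.select_template([cyl])


def test_register_identity_is_exact(cyl):
    d = geo.register_nonrigid(cyl, cyl)
    assert d.converged
    assert d.mean_residual < 1e-6
    assert np.abs(d.displacement).max() < 1e-6


def test_register_recovers_translation(cyl):
    target = cyl.translated([3.0, 0.0, 0.0])
    d = geo.register_nonrigid(cyl, target)
    assert d.converged
    disp = np.linalg.norm(d.displacement, axis=1)
    assert disp.mean() == pytest.approx(3.0, abs=0.1)
    assert d.mean_residual < 0.2


def test_register_recovers_radial_inflation():
    src = cylinder_mesh(10.0, 60.0, n_theta=48, dz=2.0)
    tgt = cylinder_mesh(11.5, 60.0, n_theta=48, dz=2.0)
    d = geo.register_nonrigid(src, tgt)
    assert d.converged
    disp = np.linalg.norm(d.displacement, axis=1)
    # interior vertices move out by 1.5 mm
    interior = np.abs(src.vertices[:, 2]) < 20.0
    assert disp[interior].mean() == pytest.approx(1.5, abs=0.15)


def test_register_flags_failure_not_silent(cyl):
    # an unreachable target (tight residual tolerance) must be flagged
    target = cylinder_mesh(13.0, 60.0, n_theta=48, dz=2.0)
    d = geo.register_nonrigid(cyl, target, iterations=1, lam_initial=1e6,
                              lam_final=1e6, residual_tolerance=0.01)
    assert not d.converged


def test_register_empty_mesh_errors(cyl):
    from aortatlas.core import SurfaceMesh

    empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int),
                        np.zeros((0, 3)), np.zeros(0))
    with pytest.raises(ValueError):
        geo.register_nonrigid(empty, cyl)


def test_interpolate_to_mesh_identity_exact(cyl, rng):
    d = geo.register_nonrigid(cyl, cyl)
    vals = rng.normal(size=cyl.n_vertices)
    out = geo.interpolate_to_mesh(VertexField(vals, cyl), d, cyl)
    assert np.allclose(out.values, vals, atol=1e-9)


def test_interpolate_vector_field_shape(cyl, rng):
    d = geo.register_nonrigid(cyl, cyl)
    vals = rng.normal(size=(cyl.n_vertices, 3))
    out = geo.interpolate_to_mesh(VertexField(vals, cyl), d, cyl)
    assert out.values.shape == (cyl.n_vertices, 3)
    assert np.allclose(out.values, vals, atol=1e-9)


def test_nearest_vertex_transfer_preserves_binary(cyl, rng):
    d = geo.register_nonrigid(cyl, cyl.translated([0.5, 0, 0]))
    ind = (rng.random(cyl.n_vertices) < 0.4).astype(float)
    out = geo.nearest_vertex_transfer(ind, d, cyl.translated([0.5, 0, 0]))
    assert set(np.unique(out)) <= {0.0, 1.0}
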