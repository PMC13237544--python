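import numpy as np
import pytest

from aortatlas import atlas as am
from aortatlas.core import Deformation, SurfaceMesh
from aortatlas.synthetic import cylinder_mesh


@pytest.fixture(scope="module")
def mesh():
    return cylinder_mesh(10.0, 40.0, n_theta=32, dz=2.0)


@pytest.fixture(scope="module")
def gauss_atlas(mesh):
    rng = np.random.default_rng(3)
    maps = [rng.normal(5.0, 1.0, mesh.n_vertices) for _ in range(8)]
    return am.build_scalar_atlas([mesh] * 8, maps, template_index=0), maps


def test_scalar_atlas_matches_numpy_moments(gauss_atlas):
    # identical geometry: interpolation is exact, so the atlas moments are
    # exactly the per-vertex sample mean and SD (ddof = 1)
    atlas, maps = gauss_atlas
    X = np.vstack(maps)
    assert np.allclose(atlas.mean, X.mean(axis=0), atol=1e-12)
    assert np.allclose(atlas.sd, X.std(axis=0, ddof=1), atol=1e-12)
    assert atlas.n_controls == 8


def test_ci_maps_are_exact_mean_plus_minus_sd(gauss_atlas):
    atlas, _ = gauss_atlas
    assert np.allclose(atlas.ci_upper, atlas.mean + 1.96 * atlas.sd, atol=1e-12)
    assert np.allclose(atlas.ci_lower, atlas.mean - 1.96 * atlas.sd, atol=1e-12)


def test_atlas_needs_two_controls(mesh):
    with pytest.raises(ValueError):
        am.build_scalar_atlas([mesh], [np.zeros(mesh.n_vertices)])
    with pytest.raises(ValueError):
        am.build_scalar_atlas([mesh, mesh], [np.zeros(mesh.n_vertices)])


def test_identical_maps_give_zero_sd(mesh):
    const = np.full(mesh.n_vertices, 3.0)
    atlas = am.build_scalar_atlas([mesh, mesh, mesh], [const] * 3)
    assert np.all(atlas.sd == 0.0)


def test_failed_control_registration_warns_and_excludes(mesh, monkeypatch):
    calls = {"n": 0}

    def fake_register(src, tgt, **kw):
        calls["n"] += 1
        ok = calls["n"] > 1
        return Deformation(src.vertices.copy(), np.zeros(src.n_vertices),
                           src, tgt, converged=ok)

    monkeypatch.setattr(am, "register_nonrigid", fake_register)
    maps = [np.full(mesh.n_vertices, float(k)) for k in range(4)]
    with pytest.warns(UserWarning, match="excluded"):
        atlas = am.build_scalar_atlas([mesh] * 4, maps, template_index=0)
    assert atlas.excluded_controls == [1]
    assert atlas.n_controls == 3


def test_project_atlas_identity(mesh, gauss_atlas):
    atlas, _ = gauss_atlas
    proj = am.project_atlas(atlas, mesh)
    assert np.allclose(proj["mean"], atlas.mean, atol=1e-9)
    assert np.allclose(proj["ci_upper"], atlas.ci_upper, atol=1e-9)


def _tiny_mesh(n=5):
    verts = np.column_stack([np.arange(n), np.zeros(n), np.zeros(n)]).astype(float)
    faces = np.array([[i, i + 1, (i + 2) % n] for i in range(n - 2)])
    return SurfaceMesh(verts, faces)


def test_classify_scalar_boundary_is_normal():
    mesh = _tiny_mesh()
    proj = {"mean": np.full(5, 1.0), "sd": np.full(5, 0.5),
            "ci_lower": np.full(5, 0.0), "ci_upper": np.full(5, 2.0)}
    values = np.array([2.0, 2.0 + 1e-9, -1e-9, 0.0, 1.0])
    hm = am.classify_scalar(values, proj, mesh)
    assert list(hm.labels) == ["normal", "increased", "decreased", "normal", "normal"]
    assert not hm.flags.any()


def test_classify_scalar_degenerate_sd_flagged():
    mesh = _tiny_mesh()
    proj = {"mean": np.full(5, 1.0), "sd": np.zeros(5),
            "ci_lower": np.full(5, 1.0), "ci_upper": np.full(5, 1.0)}
    hm = am.classify_scalar(np.array([1.0, 1.1, 0.9, 1.0, 1.0]), proj, mesh)
    assert list(hm.labels) == ["normal", "increased", "decreased", "normal", "normal"]
    assert hm.flags.all()


def test_classify_direction_threshold_rule():
    mesh = _tiny_mesh()
    d = np.tile([0.0, 0.0, 1.0], (5, 1))
    proj = {"mean_direction": d, "undefined": np.zeros(5, bool)}
    ang = np.radians([180.0, 60.0, 120.0, 119.999, 120.001])
    vecs = np.column_stack([np.sin(ang), np.zeros(5), np.cos(ang)])
    hm = am.classify_direction(vecs, proj, mesh)
    assert list(hm.labels) == [
        "abnormal_direction", "normal", "normal", "normal", "abnormal_direction",
    ]


def test_classify_direction_zero_vector_flagged_normal():
    mesh = _tiny_mesh()
    proj = {"mean_direction": np.tile([0.0, 0.0, 1.0], (5, 1)),
            "undefined": np.array([False, False, False, False, True])}
    vecs = np.tile([0.0, 0.0, -1.0], (5, 1))
    vecs[0] = 0.0  # zero patient vector
    hm = am.classify_direction(vecs, proj, mesh)
    assert hm.labels[0] == "normal" and hm.flags[0]
    assert hm.labels[4] == "normal" and hm.flags[4]
    assert all(l == "abnormal_direction" for l in hm.labels[1:4])


def test_vector_atlas_unit_directions(mesh):
    rng = np.random.default_rng(1)
    base = np.tile([0.0, 0.0, 1.0], (mesh.n_vertices, 1))
    maps = [base + rng.normal(0, 0.1, base.shape) for _ in range(5)]
    va = am.build_vector_atlas([mesh] * 5, maps, template_index=0)
    norms = np.linalg.norm(va.mean_direction[~va.undefined], axis=1)
    assert np.allclose(norms, 1.0, atol=1e-9)
    assert np.all(va.resultant_length <= 1.0 + 1e-12)
    assert va.mean_direction[~va.undefined][:, 2].min() > 0.9


def test_incidence_map_proportions_are_integral(mesh, rng):
    hms, meshes = [], []
    for _ in range(4):
        m = mesh.translated(rng.normal(0, 0.2, 3))
        lab = np.full(m.n_vertices, "normal", dtype=object)
        lab[rng.random(m.n_vertices) < 0.3] = "increased"
        hms.append(am.Heatmap(lab, m, "scalar"))
        meshes.append(m)
    inc = am.build_incidence_map(hms, meshes)
    counts = inc.proportion * inc.n_patients
    assert np.allclose(counts, np.round(counts), atol=1e-9)
    assert inc.proportion.min() >= 0.0 and inc.proportion.max() <= 1.0
    assert inc.label == "increased"


def test_incidence_map_single_patient(mesh):
    lab = np.full(mesh.n_vertices, "normal", dtype=object)
    lab[:10] = "increased"
    inc = am.build_incidence_map([am.Heatmap(lab, mesh, "scalar")], [mesh])
    assert set(np.unique(inc.proportion)) == {0.0, 1.0}
    assert inc.proportion[:10].min() == 1.0
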