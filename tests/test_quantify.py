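import numpy as np
import pytest
from scipy import stats

from aortatlas import quantify as qt
from aortatlas.atlas import Heatmap
from aortatlas.core import ROI_NAMES
from aortatlas.geometry import label_rois
from aortatlas.synthetic import cylinder_mesh

from conftest import straight_centerline


def test_roi_means_hand_oracle():
    labels = np.array(["pAAo", "pAAo", "dAAo", "excluded"], dtype=object)
    values = np.array([2.0, 4.0, 6.0, 100.0])
    areas = np.array([1.0, 3.0, 2.0, 5.0])
    out = qt.roi_means(values, labels, areas)
    assert out["pAAo"] == pytest.approx((2 * 1 + 4 * 3) / 4)  # area weighted
    assert out["dAAo"] == 6.0
    assert np.isnan(out["pDAo"]) and np.isnan(out["dDAo"])  # empty -> missing


def test_roi_means_respects_flags():
    labels = np.array(["pAAo", "pAAo"], dtype=object)
    out = qt.roi_means(np.array([2.0, 99.0]), labels, np.ones(2),
                       flags=np.array([False, True]))
    assert out["pAAo"] == 2.0
    with pytest.warns(UserWarning, match="flagged"):
        out = qt.roi_means(np.array([2.0, 99.0]), labels, np.ones(2),
                           flags=np.array([True, True]))
    assert np.isnan(out["pAAo"])


def test_roi_means_shape_mismatch():
    with pytest.raises(ValueError):
        qt.roi_means(np.zeros(3), np.array(["pAAo"] * 2, dtype=object), np.ones(3))


def test_abnormal_area_percent_analytic_band():
    # [DERIVED] an abnormal axial band of 1/5 the length covers 20% of the area
    mesh = cylinder_mesh(10.0, 50.0, n_theta=48, dz=1.0)
    cl = straight_centerline(length=50.0, z0=-25.0)
    labels = label_rois(mesh, cl)
    z = mesh.vertices[:, 2]
    hm_labels = np.full(mesh.n_vertices, "normal", dtype=object)
    band = (z >= -25.0) & (z < -15.0)  # 10 of 50 mm, inside pAAo
    hm_labels[band] = "increased"
    hm = Heatmap(hm_labels, mesh, "scalar")
    paao = (labels == "pAAo")
    expected = 100.0 * 10.0 / (np.ptp(np.unique(z[paao])) + 1.0)
    summ = qt.abnormal_area_percent(hm, labels, mesh.vertex_area)
    assert summ.percent["pAAo"]["increased"] == pytest.approx(expected, abs=3.0)
    assert summ.percent["dDAo"]["increased"] == 0.0
    assert summ.any_abnormal["pAAo"]["increased"]
    assert not summ.any_abnormal["dDAo"]["increased"]


def test_abnormal_area_excludes_flagged_vertices():
    mesh = cylinder_mesh(10.0, 50.0, n_theta=24, dz=2.0)
    labels = np.full(mesh.n_vertices, "pAAo", dtype=object)
    hm_labels = np.full(mesh.n_vertices, "increased", dtype=object)
    flags = np.zeros(mesh.n_vertices, dtype=bool)
    flags[: mesh.n_vertices // 2] = True
    hm = Heatmap(hm_labels, mesh, "scalar", flags=flags)
    summ = qt.abnormal_area_percent(hm, labels, mesh.vertex_area)
    assert summ.percent["pAAo"]["increased"] == pytest.approx(100.0)


def test_diameter_adjust_arithmetic():
    regional = {
        "displacement_mm": {r: 10.0 for r in ROI_NAMES},
        "velocity_cm_s": {r: 80.0 for r in ROI_NAMES},
        "wss_pa": {r: 0.5 for r in ROI_NAMES},
    }
    diam = {"root": 40.0, "ascending": 32.0, "proximal_descending": 25.0, "diaphragm": 20.0}
    out = qt.diameter_adjust(regional, diam)
    assert out["pAAo"]["displacement_adj"] == pytest.approx(10.0 / 40.0 * 100.0)
    assert out["dAAo"]["velocity_adj"] == pytest.approx(80.0 / 32.0)
    assert out["pDAo"]["wss_adj_mpa_mm"] == pytest.approx(0.5 * 1000.0 / 25.0)
    assert out["dDAo"]["diameter_mm"] == 20.0


def test_diameter_adjust_missing_diameter_gives_nan():
    out = qt.diameter_adjust({"displacement_mm": {r: 1.0 for r in ROI_NAMES}},
                             {"root": 0.0})
    assert all(np.isnan(out[r]["displacement_adj"]) for r in ROI_NAMES)


def test_registration_audit_matches_paired_t(rng):
    pre = rng.normal(5.0, 1.0, 12)
    post = pre + rng.normal(0.1, 0.2, 12)
    audit = qt.registration_audit(pre, post)
    t, p = stats.ttest_rel(post, pre)
    assert audit.p_value == pytest.approx(p, abs=1e-12)
    assert audit.mean_difference == pytest.approx((post - pre).mean())
    assert audit.ci_lower < audit.mean_difference < audit.ci_upper
    assert not audit.degenerate


def test_registration_audit_degenerate_and_errors():
    audit = qt.registration_audit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert audit.degenerate and audit.mean_difference == 0.0 and audit.p_value == 1.0
    with pytest.raises(ValueError):
        qt.registration_audit([1.0], [1.0])
    with pytest.raises(ValueError):
        qt.registration_audit([1.0, 2.0], [1.0])
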