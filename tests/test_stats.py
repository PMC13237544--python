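import numpy as np
import pytest
from scipy import stats as ss
from scipy.special import comb

from aortatlas import stats_report as sr

# fixed 3x5 toy table used for the Tukey cross-check
TOY = {
    "control": [9.1, 10.2, 9.8, 10.5, 9.4],
    "native": [8.2, 8.9, 8.5, 9.1, 8.0],
    "ars": [5.9, 6.4, 6.1, 6.8, 5.5],
}


def _tukey_oracle(groups):
    """Independent Tukey HSD p-values via the studentized range distribution."""
    names = sorted(groups)
    arrays = {g: np.asarray(groups[g], dtype=float) for g in names}
    k = len(names)
    dfw = sum(len(a) - 1 for a in arrays.values())
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / dfw
    out = {}
    from itertools import combinations

    for g1, g2 in combinations(names, 2):
        a, b = arrays[g1], arrays[g2]
        se = np.sqrt(msw / 2 * (1 / len(a) + 1 / len(b)))
        q = abs(a.mean() - b.mean()) / se
        out[f"{g1}_vs_{g2}"] = float(ss.studentized_range.sf(q, k, dfw))
    return out


def test_tukey_matches_studentized_range_oracle():
    res = sr.compare_groups(TOY)
    oracle = _tukey_oracle(TOY)
    assert res.omnibus_significant
    assert set(res.pairwise_p) == set(oracle)
    for key, p in oracle.items():
        assert res.pairwise_p[key] == pytest.approx(p, abs=1e-6)


def test_identical_groups_omnibus_not_significant():
    g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [1.0, 2.0, 3.0]}
    res = sr.compare_groups(g)
    assert not res.omnibus_significant
    assert res.pairwise_p == {}  # gated: no pairwise reporting
    assert res.anova_p == pytest.approx(1.0)


def test_zero_variance_everywhere_is_degenerate():
    g = {"a": [2.0, 2.0], "b": [3.0, 3.0]}
    res = sr.compare_groups(g)
    assert res.degenerate and np.isnan(res.anova_p)


def test_compare_groups_validation():
    with pytest.raises(ValueError):
        sr.compare_groups({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        sr.compare_groups({"a": [1.0, 2.0], "b": [3.0]})


def test_anova_power_under_large_shift():
    # [DERIVED] two groups shifted by 5 SD, n=20: omnibus p < 0.0125 in
    # >= 99% of 200 seeded simulations
    hits = 0
    for seed in range(200):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(5.0, 1.0, 20)
        if sr.compare_groups({"a": a, "b": b}).omnibus_significant:
            hits += 1
    assert hits >= 198


def test_anova_affine_invariance():
    res1 = sr.compare_groups(TOY)
    scaled = {g: [7.5 * x - 3.0 for x in v] for g, v in TOY.items()}
    res2 = sr.compare_groups(scaled)
    assert res2.anova_p == pytest.approx(res1.anova_p, rel=1e-9)


def test_rank_test_exact_separation_oracle():
    # [DERIVED] complete separation, n = 10 vs 10: two-sided exact p is
    # 2 / C(20, 10)
    a = np.arange(10.0)
    b = np.arange(100.0, 110.0)
    res = sr.compare_abnormal_areas(a, b)
    assert res.p_value == pytest.approx(2.0 / comb(20, 10, exact=True), rel=1e-9)


def test_rank_test_identical_samples():
    res = sr.compare_abnormal_areas([0.0, 0.0, 0.0], [0.0, 0.0])
    assert res.p_value == 1.0 and res.degenerate
    assert res.formatted("native") == "0 (IQR: 0–0)"


def test_rank_test_scale_invariance():
    rng = np.random.default_rng(5)
    a, b = rng.random(12), rng.random(15) + 0.3
    p1 = sr.compare_abnormal_areas(a, b).p_value
    p2 = sr.compare_abnormal_areas(100 * a, 100 * b).p_value
    assert p1 == pytest.approx(p2, rel=1e-12)


def test_rank_test_empty_group_errors():
    with pytest.raises(ValueError):
        sr.compare_abnormal_areas([], [1.0])


def test_correlate_perfect_and_closed_form():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    assert sr.correlate(x, 2 * x + 1).r == pytest.approx(1.0, abs=1e-7)
    # [DERIVED] hand-computed covariance formula on a fixed 6-point set
    y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
    r_hand = (((x - x.mean()) * (y - y.mean())).sum()
              / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
    res = sr.correlate(x, y)
    assert res.r == pytest.approx(r_hand, abs=1e-12)
    # Fisher-z closed form
    z = np.arctanh(res.r)
    se = 1 / np.sqrt(6 - 3)
    assert res.ci_lower == pytest.approx(np.tanh(z - 1.959963984540054 * se), abs=1e-9)
    assert res.ci_upper == pytest.approx(np.tanh(z + 1.959963984540054 * se), abs=1e-9)


def test_correlate_validation():
    with pytest.raises(ValueError):
        sr.correlate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        sr.correlate([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


def test_correlate_ci_coverage_under_null():
    # [DERIVED] independent Gaussians n=50: CI covers 0 in about 95% of repeats
    cover = 0
    n_rep = 300
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        res = sr.correlate(rng.normal(size=50), rng.normal(size=50))
        cover += res.ci_lower <= 0.0 <= res.ci_upper
    # binomial 99% bounds around 0.95
    assert abs(cover / n_rep - 0.95) < 2.58 * np.sqrt(0.95 * 0.05 / n_rep)


def test_logistic_2x2_closed_form_odds_ratio():
    # [DERIVED] (a, b, c, d) = (10, 10, 5, 20) -> OR = (10*20)/(10*5) = 4
    y = np.array([1.0] * 10 + [0.0] * 10 + [1.0] * 5 + [0.0] * 20)
    x = np.array([1.0] * 20 + [0.0] * 25)
    res = sr.logistic_univariable(y, x)
    assert not res.separated
    assert res.odds_ratio == pytest.approx(4.0, abs=1e-6)
    assert res.ci_lower < 4.0 < res.ci_upper


def test_logistic_validation_and_separation():
    with pytest.raises(ValueError):
        sr.logistic_univariable([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        sr.logistic_univariable([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])
    # perfectly separated predictor -> flagged, no numeric OR
    y = np.array([0.0] * 10 + [1.0] * 10)
    x = np.arange(20.0)
    res = sr.logistic_univariable(y, x)
    assert res.separated and np.isnan(res.odds_ratio)


def test_incidence_table_formatting():
    assert sr.incidence_table([True] * 31 + [False]) == "97% (31/32)"
    assert sr.incidence_table([False] * 5) == "0% (0/5)"
    assert sr.incidence_table([True] * 4) == "100% (4/4)"
    with pytest.raises(ValueError):
        sr.incidence_table([])


def test_metadata_records_rank_test_substitution():
    assert "Mann-Whitney" in sr.METADATA["rank_test"]
    assert "signed-rank" in sr.METADATA["rank_test"]
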