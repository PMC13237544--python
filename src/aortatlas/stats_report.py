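"""Cohort-level statistics.

Group comparisons use one-way ANOVA with a Bonferroni-corrected omnibus
threshold of 0.0125 (four ROIs per parameter) followed by Tukey HSD
pairwise contrasts at 0.05; abnormal-area percentages are compared with
the two-sample rank-sum (Mann-Whitney) test and reported as
median (IQR); associations use Pearson correlation with Fisher-z 95%
confidence intervals; determinants of binary abnormality outcomes use
univariable logistic regression with Wald intervals.

Note on the rank test: a signed-rank test is only defined for paired
samples; for two independent groups of unequal size the rank-sum test is
the applicable rank-based test, and that is what this module computes
(recorded in the metadata of every report).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

OMNIBUS_ALPHA = 0.0125  # Bonferroni over the four ROIs
PAIRWISE_ALPHA = 0.05

METADATA = {
    "omnibus_alpha": OMNIBUS_ALPHA,
    "pairwise_alpha": PAIRWISE_ALPHA,
    "rank_test": "Mann-Whitney rank-sum (two independent samples; a signed-rank "
                 "test is not defined for independent groups of unequal size)",
    "pairwise": "Tukey HSD, reported only when the omnibus ANOVA is significant",
    "correlation_ci": "Fisher z, 95%",
}


@dataclass
class GroupComparison:
    parameter: str
    roi: str
    groups: dict  # name -> (mean, sd, n)
    anova_p: float
    pairwise_p: dict  # contrast 'a_vs_b' -> p (empty unless omnibus significant)
    omnibus_significant: bool
    significant_contrasts: tuple = ()
    degenerate: bool = False


def compare_groups(values_by_group: dict, threshold: float = OMNIBUS_ALPHA,
                   parameter: str = "", roi: str = "") -> GroupComparison:
    """One-way ANOVA omnibus + Tukey HSD pairwise contrasts.

    Pairwise p-values are reported only when the omnibus p is below the
    (Bonferroni-corrected) threshold, mirroring the gated workflow.
    """
    names = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in names]
    if len(names) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    summary = {g: (float(a.mean()), float(a.std(ddof=1)), len(a))
               for g, a in zip(names, arrays)}
    if all(a.std(ddof=1) == 0 for a in arrays):
        return GroupComparison(parameter, roi, summary, np.nan, {}, False,
                               degenerate=True)
    f, p = stats.f_oneway(*arrays)
    pairwise = {}
    significant = []
    if p < threshold:
        from itertools import combinations

        data = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
        res = pairwise_tukeyhsd(data, labels, alpha=PAIRWISE_ALPHA)
        # contrasts come in combinations order of the sorted unique groups
        for (g1, g2), pv in zip(combinations(res.groupsunique, 2), res.pvalues):
            key = f"{g1}_vs_{g2}"
            pairwise[key] = float(pv)
            if pv < PAIRWISE_ALPHA:
                significant.append(key)
    return GroupComparison(parameter, roi, summary, float(p), pairwise,
                           bool(p < threshold), tuple(significant))


@dataclass
class RankTestResult:
    p_value: float
    medians: dict
    iqrs: dict  # name -> (q1, q3)
    degenerate: bool = False

    def formatted(self, name: str) -> str:
        q1, q3 = self.iqrs[name]
        return f"{self.medians[name]:g} (IQR: {q1:g}–{q3:g})"


def compare_abnormal_areas(native_values, ars_values) -> RankTestResult:
    """Two-sample rank test on abnormal-area percentages with medians and
    IQRs reported per group."""
    a = np.asarray(native_values, dtype=float)
    b = np.asarray(ars_values, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    med = {"native": float(np.median(a)), "ars": float(np.median(b))}
    iqr = {
        "native": (float(np.percentile(a, 25)), float(np.percentile(a, 75))),
        "ars": (float(np.percentile(b, 25)), float(np.percentile(b, 75))),
    }
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return RankTestResult(1.0, med, iqr, degenerate=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankTestResult(float(min(res.pvalue, 1.0)), med, iqr)


@dataclass
class CorrelationResult:
    r: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with Fisher-z 95% CI and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -0.9999999, 0.9999999))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(0.975)
    return CorrelationResult(r, float(np.tanh(z - zc * se)),
                             float(np.tanh(z + zc * se)), float(p), n)


@dataclass
class LogisticResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    separated: bool = False


def logistic_univariable(outcome, predictor) -> LogisticResult:
    """Univariable logistic regression: OR = exp(coefficient), Wald 95% CI.

    Complete separation is flagged (no numeric OR is reported).
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = sm.add_constant(x)
    try:
        import warnings as _w

        with np.errstate(all="ignore"), _w.catch_warnings():
            _w.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        coef = fit.params[1]
        se = fit.bse[1]
        if not np.isfinite(se) or se > 50 or abs(coef) > 50:
            return LogisticResult(np.nan, np.nan, np.nan, np.nan, len(y), separated=True)
        zc = stats.norm.ppf(0.975)
        return LogisticResult(
            float(np.exp(coef)),
            float(np.exp(coef - zc * se)),
            float(np.exp(coef + zc * se)),
            float(fit.pvalues[1]),
            len(y),
        )
    except Exception:
        return LogisticResult(np.nan, np.nan, np.nan, np.nan, len(y), separated=True)


def incidence_table(any_abnormal_flags) -> str:
    """'97% (31/32)'-style incidence of at least one abnormal vertex."""
    flags = np.asarray(any_abnormal_flags, dtype=bool)
    n = len(flags)
    if n == 0:
        raise ValueError("need at least one patient")
    k = int(flags.sum())
    return f"{round(100.0 * k / n):.0f}% ({k}/{n})"
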