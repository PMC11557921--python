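"""Unit and property tests for the discrimination/outcome statistics."""

import math

import numpy as np
import pytest

from sahscore.stats import (
    EstimationError,
    PerfectSeparationError,
    TwoByTwo,
    diagnostic_metrics,
    dichotomize_outcome,
    format_p,
    logistic_fit,
    median_with_ci,
    odds_ratio,
    ols_multivariate,
    roc_auc,
    two_by_two,
    youden_cutoff,
)


def brute_force_auc(scores, labels) -> float:
    """Independent oracle: average over all positive-negative pairs, ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Outcome dichotomization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mrs, expected", [
    (0, "favorable"), (2, "favorable"), (3, "unfavorable"), (6, "unfavorable"),
])
def test_mrs_dichotomization(mrs, expected):
    assert dichotomize_outcome(mrs) == expected


def test_mrs_out_of_range():
    with pytest.raises(ValueError):
        dichotomize_outcome(7)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("scores, labels, expected", [
    ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
    ([1, 3, 2, 4], [0, 0, 1, 1], 0.75),
    ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
])
def test_auc_examples(scores, labels, expected):
    assert roc_auc(scores, labels).auc == pytest.approx(expected)


def test_auc_matches_pair_counting_on_random_instances(rng):
    for _ in range(200):
        n = int(rng.integers(4, 51))
        scores = rng.integers(0, 10, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels)
        )


def test_auc_negation_symmetry(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, 60)
    labels[0], labels[1] = 0, 1
    assert roc_auc(-scores, labels).auc == pytest.approx(
        1 - roc_auc(scores, labels).auc
    )


def test_auc_equals_trapezoidal_curve_area(rng):
    scores = rng.integers(0, 6, 80).astype(float)
    labels = rng.integers(0, 2, 80)
    labels[:2] = [0, 1]
    r = roc_auc(scores, labels)
    area = np.trapezoid(r.sensitivity, r.one_minus_specificity)
    assert r.auc == pytest.approx(area)


def test_auc_ci_contains_estimate_and_shrinks_with_n(rng):
    small = roc_auc(rng.normal(size=40) + np.r_[np.zeros(20), np.ones(20)],
                    np.r_[np.zeros(20, int), np.ones(20, int)])
    big_scores = rng.normal(size=2000) + np.r_[np.zeros(1000), np.ones(1000)]
    big = roc_auc(big_scores, np.r_[np.zeros(1000, int), np.ones(1000, int)])
    assert small.auc_ci_low <= small.auc <= small.auc_ci_high
    assert (big.auc_ci_high - big.auc_ci_low) < (small.auc_ci_high - small.auc_ci_low)


def test_auc_single_class_raises():
    with pytest.raises(EstimationError):
        roc_auc([1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# Cutoff selection and the 2x2 table
# ---------------------------------------------------------------------------


def test_youden_cutoff_on_perfect_separator():
    cut = youden_cutoff(roc_auc([1, 2, 3, 4], [0, 0, 1, 1]))
    assert 2 <= cut < 3  # any threshold in [2, 3) separates; ties break low


def test_youden_cutoff_flat_roc_breaks_to_lowest_threshold():
    r = roc_auc([5, 5, 5, 5], [0, 1, 0, 1])
    assert youden_cutoff(r) == r.thresholds.min()


def test_youden_cutoff_by_enumeration(rng):
    scores = rng.integers(0, 12, 50).astype(float)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    r = roc_auc(scores, labels)
    candidates = sorted(set(scores) | {scores.max() + 1})
    js = []
    for t in candidates:
        m = diagnostic_metrics(two_by_two(scores, labels, t))
        js.append(m.sensitivity + m.specificity - 1)
    best = max(js)
    expected = min(t for t, j in zip(candidates, js) if j >= best - 1e-12)
    assert youden_cutoff(r) == expected


def test_two_by_two_strict_inequality():
    t = two_by_two([8, 7], [1, 0], cutoff=7)
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 1)


def test_two_by_two_matches_enumeration_and_conserves_n(rng):
    scores = rng.integers(0, 9, 20).astype(float)
    labels = rng.integers(0, 2, 20)
    for cutoff in range(-1, 10):
        t = two_by_two(scores, labels, cutoff)
        assert t.total == 20
        assert t.tp == sum(1 for s, y in zip(scores, labels) if s > cutoff and y)
        assert t.tn == sum(1 for s, y in zip(scores, labels) if s <= cutoff and not y)


def test_two_by_two_invariant_under_monotone_transform(rng):
    scores = rng.uniform(0, 10, 40)
    labels = rng.integers(0, 2, 40)
    t1 = two_by_two(scores, labels, 5.0)
    t2 = two_by_two(np.exp(scores), labels, math.exp(5.0))
    assert t1 == t2


# ---------------------------------------------------------------------------
# Diagnostic metrics and odds ratios
# ---------------------------------------------------------------------------


def test_metrics_perfect_and_inverted_tables():
    perfect = diagnostic_metrics(TwoByTwo(tp=1, fp=0, fn=0, tn=1))
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv,
            perfect.npv) == (1.0, 1.0, 1.0, 1.0)
    inverted = diagnostic_metrics(TwoByTwo(tp=0, fp=1, fn=1, tn=0))
    assert (inverted.sensitivity, inverted.specificity, inverted.ppv,
            inverted.npv) == (0.0, 0.0, 0.0, 0.0)


def test_metrics_reference_ratios():
    m = diagnostic_metrics(TwoByTwo(tp=90, fp=60, fn=34, tn=140))
    assert m.sensitivity == pytest.approx(90 / 124, abs=1e-9)
    assert m.specificity == pytest.approx(0.700, abs=1e-3)
    assert m.ppv == pytest.approx(0.600, abs=1e-3)
    assert m.npv == pytest.approx(140 / 174, abs=1e-9)
    assert m.undefined == []


def test_metrics_undefined_marker_not_nan():
    m = diagnostic_metrics(TwoByTwo(tp=0, fp=0, fn=2, tn=3))
    assert m.ppv is None and "ppv" in m.undefined
    assert m.sensitivity == 0.0


@pytest.mark.parametrize("cells, expected", [
    ((1, 1, 1, 1), 1.0),
    ((2, 1, 1, 2), 4.0),
    ((90, 60, 34, 140), 90 * 140 / (60 * 34)),
])
def test_odds_ratio_cross_product(cells, expected):
    assert odds_ratio(TwoByTwo(*cells)).odds_ratio == pytest.approx(expected)


def test_odds_ratio_invariances():
    base = odds_ratio(TwoByTwo(tp=12, fp=5, fn=7, tn=20))
    both_swapped = odds_ratio(TwoByTwo(tp=20, fp=7, fn=5, tn=12))
    one_swapped = odds_ratio(TwoByTwo(tp=5, fp=12, fn=20, tn=7))
    assert both_swapped.odds_ratio == pytest.approx(base.odds_ratio)
    assert one_swapped.odds_ratio == pytest.approx(1 / base.odds_ratio)


def test_odds_ratio_ci_matches_statsmodels():
    from statsmodels.stats.contingency_tables import Table2x2

    t = TwoByTwo(tp=90, fp=60, fn=34, tn=140)
    ours = odds_ratio(t)
    ref = Table2x2(np.array([[t.tp, t.fp], [t.fn, t.tn]]))
    lo, hi = ref.oddsratio_confint(0.05)
    assert ours.odds_ratio == pytest.approx(ref.oddsratio)
    assert ours.ci_low == pytest.approx(lo, rel=1e-6)
    assert ours.ci_high == pytest.approx(hi, rel=1e-6)


def test_odds_ratio_haldane_correction_flagged():
    r = odds_ratio(TwoByTwo(tp=5, fp=0, fn=3, tn=7))
    assert r.haldane_corrected
    assert r.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))


def test_odds_ratio_degenerate_margin_raises():
    with pytest.raises(EstimationError):
        odds_ratio(TwoByTwo(tp=0, fp=0, fn=3, tn=7))


# ---------------------------------------------------------------------------
# Regression fits
# ---------------------------------------------------------------------------


def test_logistic_null_slope_near_zero(rng):
    x = rng.normal(size=4000)
    y = rng.integers(0, 2, 4000)
    row = logistic_fit(x, y, name="score").row("score")
    assert abs(row.estimate) < 0.1
    assert row.p_value > 0.001


def test_logistic_recovers_configured_slope(rng):
    x = rng.normal(size=5000)
    p = 1 / (1 + np.exp(-(0.2 + 1.0 * x)))
    y = (rng.random(5000) < p).astype(int)
    row = logistic_fit(x, y, name="score").row("score")
    assert row.estimate == pytest.approx(1.0, abs=0.1)
    assert row.ci_low < 1.0 < row.ci_high


def test_logistic_intercept_closed_form(rng):
    n = 10000
    y = np.zeros(n, int)
    y[: int(0.3 * n)] = 1
    x = rng.normal(size=n)  # independent of y
    table = logistic_fit(x, y, name="score")
    assert table.row("intercept").estimate == pytest.approx(
        math.log(0.3 / 0.7), abs=0.08
    )


def test_logistic_perfect_separation_names_covariate():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = np.r_[np.zeros(10, int), np.ones(10, int)]
    with pytest.raises(PerfectSeparationError, match="lods_total"):
        logistic_fit(x, y, name="lods_total")


def test_logistic_single_class_raises():
    with pytest.raises(EstimationError):
        logistic_fit([1.0, 2.0, 3.0], [1, 1, 1])


def test_ols_exact_fit_without_noise(rng):
    X = rng.normal(size=(50, 3))
    beta = np.array([0.5, -1.0, 2.0])
    y = 1.5 + X @ beta
    table = ols_multivariate(X, y, names=["a", "b", "c"])
    assert table.row("intercept").estimate == pytest.approx(1.5, abs=1e-10)
    for name, b in zip("abc", beta):
        assert table.row(name).estimate == pytest.approx(b, abs=1e-10)


def test_ols_covariate_order_permutes_rows_only(rng):
    X = rng.normal(size=(80, 2))
    y = 0.3 * X[:, 0] - 0.7 * X[:, 1] + rng.normal(size=80)
    t1 = ols_multivariate(X, y, names=["u", "v"])
    t2 = ols_multivariate(X[:, ::-1], y, names=["v", "u"])
    assert t1.row("u").estimate == pytest.approx(t2.row("u").estimate)
    assert t1.row("v").p_value == pytest.approx(t2.row("v").p_value)


def test_ols_rank_deficiency_names_columns(rng):
    x = rng.normal(size=60)
    X = np.column_stack([x, 2 * x])
    with pytest.raises(EstimationError, match="a~b"):
        ols_multivariate(X, rng.normal(size=60), names=["a", "b"])


def test_ols_ci_uses_t_critical_value(rng):
    from scipy import stats as sps

    X = rng.normal(size=(40, 2))
    y = X[:, 0] + rng.normal(size=40)
    row = ols_multivariate(X, y, names=["a", "b"]).row("a")
    tcrit = sps.t.ppf(0.975, 40 - 3)
    assert row.ci_high - row.estimate == pytest.approx(tcrit * row.std_error)


# ---------------------------------------------------------------------------
# Median with order-statistic CI
# ---------------------------------------------------------------------------


def test_median_examples():
    med, lo, hi = median_with_ci([1, 2, 3])
    assert med == 2 and lo <= med <= hi


def test_median_ci_collapses_on_constant_vector():
    med, lo, hi = median_with_ci([4.0] * 25)
    assert med == lo == hi == 4.0


def test_median_ci_covers_truth_on_normal_samples(rng):
    hits = sum(
        (lambda r: r[1] <= 0.0 <= r[2])(median_with_ci(rng.normal(size=101)))
        for _ in range(300)
    )
    assert hits / 300 >= 0.92


def test_p_value_formatting():
    assert format_p(0.25) == "0.2500"
    assert format_p(5e-5) == "<0.0001"
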