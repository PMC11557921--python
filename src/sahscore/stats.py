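"""Discrimination and outcome statistics for dichotomized clinical scores.

ROC/AUC, Youden-index cutoff selection, 2x2 diagnostic metrics, odds ratios,
simple logistic regression per dichotomous endpoint and multiple linear
regression of ordinal outcome on covariates.

Conventions, chosen once and used everywhere:

* test-positive means ``score > cutoff`` (strict), matching the clinical
  reading "score above the cutoff vs. scores 1..cutoff";
* AUC is the Mann-Whitney rank statistic with ties counted 1/2, with a
  Hanley-McNeil normal-approximation 95% CI;
* odds-ratio CIs use the Woolf logit method, with the Haldane-Anscombe +0.5
  continuity correction (flagged) when any cell is empty;
* a metric whose denominator is empty is reported as an explicit
  ``undefined`` marker, never a silent NaN.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "TwoByTwo",
    "RocResult",
    "OddsRatioResult",
    "DiagnosticMetrics",
    "RegressionRow",
    "RegressionTable",
    "dichotomize_outcome",
    "roc_auc",
    "youden_cutoff",
    "two_by_two",
    "diagnostic_metrics",
    "odds_ratio",
    "logistic_fit",
    "ols_multivariate",
    "median_with_ci",
]


class EstimationError(ValueError):
    """Raised when a statistic is not estimable from the given data."""


class PerfectSeparationError(EstimationError):
    """Logistic endpoint perfectly separated by the covariate."""


def dichotomize_outcome(mrs: int) -> str:
    """Dichotomize a modified Rankin Scale value: mRS <= 2 is favorable."""
    if not 0 <= mrs <= 6:
        raise ValueError(f"mRS must be in 0..6, got {mrs}")
    return "favorable" if mrs <= 2 else "unfavorable"


@dataclass(frozen=True)
class TwoByTwo:
    """Diagnostic 2x2 table: test-positive/negative vs. disease-positive/negative."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total == 0:
            raise ValueError("2x2 table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    n_positive: int
    n_negative: int
    ci_method: str = "hanley-mcneil"


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV; a value is None when its denominator
    is empty, with the reason recorded in ``undefined``."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    undefined: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    haldane_corrected: bool


@dataclass(frozen=True)
class RegressionRow:
    name: str
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    statistic: float  # |t| or |z|
    p_value: float


@dataclass(frozen=True)
class RegressionTable:
    rows: list[RegressionRow]
    kind: str  # "ols" or "logistic"
    n: int

    def row(self, name: str) -> RegressionRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def _as_arrays(scores: Sequence[float], labels: Sequence[int]):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """Empirical ROC curve and AUC with a Hanley-McNeil 95% CI.

    The AUC is the probability that a random positive outranks a random
    negative, computed from midranks so that ties count 1/2; it equals the
    trapezoidal area under the empirical curve.
    """
    s, y = _as_arrays(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EstimationError("both outcome classes must be present for ROC analysis")
    ranks = sps.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    # Hanley & McNeil variance with their exponential approximation.
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))

    # Curve: sensitivity / 1-specificity at every threshold under the strict
    # score > t positivity rule; thresholds descend from above-max to min.
    uniq = np.unique(s)
    # sentinel thresholds above max and below min anchor (0,0) and (1,1)
    thresholds = np.concatenate(([uniq[-1] + 1.0], uniq[::-1], [uniq[0] - 1.0]))
    sens = np.array([(s[y == 1] > t).mean() for t in thresholds])
    fpr = np.array([(s[y == 0] > t).mean() for t in thresholds])
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        one_minus_specificity=fpr,
        auc=float(auc),
        auc_ci_low=float(max(0.0, auc - half)),
        auc_ci_high=float(min(1.0, auc + half)),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def youden_cutoff(roc: RocResult) -> float:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the lower threshold (the more sensitive test).
    """
    j = roc.sensitivity - roc.one_minus_specificity
    best = np.max(j)
    winners = roc.thresholds[j >= best - 1e-12]
    return float(np.min(winners))


def two_by_two(scores: Sequence[float], labels: Sequence[int],
               cutoff: float) -> TwoByTwo:
    """Cross-tabulate the strict ``score > cutoff`` call against the labels."""
    s, y = _as_arrays(scores, labels)
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    call = s > cutoff
    return TwoByTwo(
        tp=int((call & (y == 1)).sum()),
        fp=int((call & (y == 0)).sum()),
        fn=int((~call & (y == 1)).sum()),
        tn=int((~call & (y == 0)).sum()),
    )


def diagnostic_metrics(t: TwoByTwo) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV and NPV from a 2x2 table."""
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    return DiagnosticMetrics(
        sensitivity=ratio(t.tp, t.tp + t.fn, "sensitivity"),
        specificity=ratio(t.tn, t.tn + t.fp, "specificity"),
        ppv=ratio(t.tp, t.tp + t.fp, "ppv"),
        npv=ratio(t.tn, t.tn + t.fn, "npv"),
        undefined=undefined,
    )


def odds_ratio(t: TwoByTwo) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf logit 95% CI and Wald p-value.

    When any cell is zero the Haldane-Anscombe correction adds 0.5 to every
    cell (flagged in the result). A table with an empty margin (an entire
    row or column of the 2x2) carries no association information and raises.
    """
    if (t.tp + t.fp == 0 or t.fn + t.tn == 0
            or t.tp + t.fn == 0 or t.fp + t.tn == 0):
        raise EstimationError("odds ratio undefined: empty row or column in 2x2 table")
    cells = [t.tp, t.fp, t.fn, t.tn]
    corrected = any(c == 0 for c in cells)
    a, b, c, d = ((x + 0.5 for x in cells) if corrected else cells)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2 * sps.norm.sf(abs(z))
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - 1.959963984540054 * se),
        ci_high=math.exp(log_or + 1.959963984540054 * se),
        p_value=float(p),
        haldane_corrected=corrected,
    )


def _check_separation(x: np.ndarray, y: np.ndarray, name: str) -> None:
    lo_pos, hi_pos = x[y == 1].min(), x[y == 1].max()
    lo_neg, hi_neg = x[y == 0].min(), x[y == 0].max()
    if hi_neg < lo_pos or hi_pos < lo_neg:
        raise PerfectSeparationError(
            f"covariate '{name}' perfectly separates the endpoint classes; "
            "the logistic MLE does not exist"
        )


def logistic_fit(x: Sequence[float], y: Sequence[int],
                 name: str = "score") -> RegressionTable:
    """Simple logistic regression of a binary endpoint on one score.

    Maximum likelihood via iteratively reweighted least squares
    (Newton-Raphson), Wald standard errors and p-values. Perfect separation
    is detected up front and raised as an explicit error naming the
    covariate.
    """
    xv, yv = _as_arrays(x, y)
    if yv.min() == yv.max():
        raise EstimationError("endpoint has a single class; logistic fit not estimable")
    _check_separation(xv, yv, name)
    design = sm.add_constant(xv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(yv, design).fit(method="newton", maxiter=100,
                                       tol=1e-8, disp=False)
    return _table_from_result(res, ["intercept", name], kind="logistic",
                              n=len(yv), use_t=False)


def ols_multivariate(X, y, names: Optional[Sequence[str]] = None) -> RegressionTable:
    """Multiple linear regression of an (ordinal) outcome on covariates.

    Ordinary least squares with an intercept; SEs from the unbiased residual
    variance, two-sided t tests, and 95% CIs at the t critical value.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if names is None else list(names)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i}" for i in range(Xm.shape[1])] if names is None else list(names)
    yv = np.asarray(y, dtype=float)
    if Xm.shape[0] != len(yv):
        raise ValueError("X and y have different lengths")
    if Xm.shape[0] <= Xm.shape[1] + 1:
        raise EstimationError("need n > number of covariates + 1")
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        corr = np.corrcoef(Xm, rowvar=False)
        bad = [
            f"{names[i]}~{names[j]}"
            for i in range(len(names)) for j in range(i + 1, len(names))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise EstimationError(
            "design matrix is rank deficient; collinear columns: "
            + (", ".join(bad) if bad else "unidentified")
        )
    design = sm.add_constant(Xm)
    res = sm.OLS(yv, design).fit()
    return _table_from_result(res, ["intercept"] + names, kind="ols",
                              n=len(yv), use_t=True)


def _table_from_result(res, names, kind: str, n: int, use_t: bool) -> RegressionTable:
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci)
    rows = [
        RegressionRow(
            name=names[i],
            estimate=float(res.params[i]),
            std_error=float(res.bse[i]),
            ci_low=float(ci[i, 0]),
            ci_high=float(ci[i, 1]),
            statistic=float(abs(res.tvalues[i])),
            p_value=float(res.pvalues[i]),
        )
        for i in range(len(names))
    ]
    return RegressionTable(rows=rows, kind=kind, n=n)


def median_with_ci(values: Sequence[float],
                   confidence: float = 0.95) -> tuple[float, float, float]:
    """Sample median with a distribution-free order-statistic CI.

    The CI takes the order statistics (x_(j), x_(k)) whose coverage under the
    binomial(n, 1/2) law is at least the requested confidence; it is exact
    and makes no distributional assumption. Returns (median, low, high).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("median of empty sequence")
    med = float(np.median(x))
    if n == 1:
        return med, float(x[0]), float(x[0])
    alpha = 1 - confidence
    j = int(sps.binom.ppf(alpha / 2, n, 0.5))  # smallest j with F(j) >= alpha/2
    if sps.binom.cdf(j, n, 0.5) < alpha / 2:  # guard against ppf edge cases
        j += 1
    j = max(j, 0)
    k = n - 1 - j
    if k < j:
        j = k = n // 2
    return med, float(x[j]), float(x[k])


def format_p(p: float) -> str:
    """Render a p-value to four decimals, with values below 1e-4 as '<0.0001'."""
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"
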