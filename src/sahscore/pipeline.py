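"""End-to-end analysis pipeline and the typed analysis report.

``run_pipeline`` takes a patient table, applies the three scoring stages
(LODS, EBI, CCI), and runs the analysis stage: distribution summaries,
per-endpoint discrimination (ROC/AUC, cutoff, 2x2 metrics, odds ratio,
simple logistic fit of the score) for the three dichotomous endpoints
(severe EBI, unfavorable 3-month outcome, in-hospital death), and the
multiple linear regression of mRS on age, treatment modality, LODS, EBI
grade and CCI.

The report is a pydantic model: its JSON schema is the committed report
schema, and every report validates against it by construction on the way
out (and can be re-validated on the way in with ``AnalysisReport
.model_validate``). An endpoint with a single outcome class is reported as
not estimable rather than failing the run.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import __version__
from .io import score_cci_table, score_ebi_table, score_lods_table
from .stats import (
    EstimationError,
    diagnostic_metrics,
    format_p,
    logistic_fit,
    median_with_ci,
    odds_ratio,
    ols_multivariate,
    roc_auc,
    two_by_two,
    youden_cutoff,
)

__all__ = ["run_pipeline", "analyze_cohort", "AnalysisReport", "report_schema"]

DEFAULT_CUTOFF = 7


class MedianBlock(BaseModel):
    median: float
    ci_low: float
    ci_high: float
    method: str = "order-statistic (binomial, distribution-free)"


class DistributionBlock(BaseModel):
    counts: dict[str, int]
    n: int
    median: Optional[MedianBlock] = None


class TwoByTwoBlock(BaseModel):
    tp: int
    fp: int
    fn: int
    tn: int


class MetricsBlock(BaseModel):
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    undefined: list[str] = []


class OddsRatioBlock(BaseModel):
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    p_display: str
    haldane_corrected: bool


class FitBlock(BaseModel):
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    statistic: float
    p_value: float
    p_display: str


class RocBlock(BaseModel):
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    ci_method: str
    cutoff: float
    cutoff_mode: str
    table: TwoByTwoBlock
    metrics: MetricsBlock
    odds_ratio: Optional[OddsRatioBlock]


class EndpointBlock(BaseModel):
    endpoint: str
    n_positive: int
    n_negative: int
    estimable: bool
    reason: Optional[str] = None
    roc: Optional[RocBlock] = None
    logistic_lods: Optional[FitBlock] = None
    logistic_lods_without_gcs: Optional[FitBlock] = None


class RegressionRowBlock(BaseModel):
    name: str
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    statistic: float
    p_value: float
    p_display: str


class MultivariateBlock(BaseModel):
    outcome: str
    rows: list[RegressionRowBlock]
    n: int
    estimable: bool = True
    reason: Optional[str] = None


class AnalysisReport(BaseModel):
    """Top-level analysis report written as JSON by the pipeline."""

    version: str
    seed: Optional[int]
    config: dict
    n_patients: int
    distributions: dict[str, DistributionBlock]
    endpoints: list[EndpointBlock]
    multivariate: Optional[MultivariateBlock]


def report_schema() -> dict:
    """The committed JSON schema every report validates against."""
    return AnalysisReport.model_json_schema()


def _distribution(values: pd.Series, with_median: bool = False) -> DistributionBlock:
    vals = values.dropna().astype(int)
    counts = vals.value_counts().sort_index()
    med = None
    if with_median and len(vals):
        m, lo, hi = median_with_ci(vals.to_numpy())
        med = MedianBlock(median=m, ci_low=lo, ci_high=hi)
    return DistributionBlock(
        counts={str(k): int(v) for k, v in counts.items()},
        n=int(len(vals)),
        median=med,
    )


def _fit_block(scores: np.ndarray, labels: np.ndarray, name: str) -> FitBlock:
    row = logistic_fit(scores, labels, name=name).row(name)
    return FitBlock(
        estimate=row.estimate, std_error=row.std_error,
        ci_low=row.ci_low, ci_high=row.ci_high, statistic=row.statistic,
        p_value=row.p_value, p_display=format_p(row.p_value),
    )


def _endpoint_block(name: str, scores: np.ndarray, scores_no_gcs: np.ndarray,
                    labels: np.ndarray, cutoff: Union[int, float, str]) -> EndpointBlock:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return EndpointBlock(
            endpoint=name, n_positive=n_pos, n_negative=n_neg,
            estimable=False,
            reason="endpoint has a single outcome class; not estimable",
        )
    roc = roc_auc(scores, labels)
    if cutoff == "auto":
        cut, mode = youden_cutoff(roc), "auto (Youden)"
    else:
        cut, mode = float(cutoff), "fixed"
    table = two_by_two(scores, labels, cut)
    metrics = diagnostic_metrics(table)
    try:
        orr = odds_ratio(table)
        or_block = OddsRatioBlock(
            odds_ratio=orr.odds_ratio, ci_low=orr.ci_low, ci_high=orr.ci_high,
            p_value=orr.p_value, p_display=format_p(orr.p_value),
            haldane_corrected=orr.haldane_corrected,
        )
    except EstimationError:
        or_block = None

    def _try_fit(s: np.ndarray, label: str) -> Optional[FitBlock]:
        try:
            return _fit_block(s, labels, label)
        except EstimationError:
            return None

    return EndpointBlock(
        endpoint=name, n_positive=n_pos, n_negative=n_neg, estimable=True,
        roc=RocBlock(
            auc=roc.auc, auc_ci_low=roc.auc_ci_low, auc_ci_high=roc.auc_ci_high,
            ci_method=roc.ci_method, cutoff=cut, cutoff_mode=mode,
            table=TwoByTwoBlock(tp=table.tp, fp=table.fp, fn=table.fn, tn=table.tn),
            metrics=MetricsBlock(
                sensitivity=metrics.sensitivity, specificity=metrics.specificity,
                ppv=metrics.ppv, npv=metrics.npv, undefined=metrics.undefined,
            ),
            odds_ratio=or_block,
        ),
        logistic_lods=_try_fit(scores, "lods_total"),
        logistic_lods_without_gcs=_try_fit(scores_no_gcs, "lods_total_without_gcs"),
    )


def analyze_cohort(scored: pd.DataFrame,
                   cutoff: Union[int, float, str] = DEFAULT_CUTOFF,
                   seed: Optional[int] = None,
                   config: Optional[dict] = None) -> AnalysisReport:
    """Analysis stage over an already-scored cohort table.

    Requires the ``lods_*``, ``ebi_*``/``severe_ebi`` and ``cci`` columns
    plus outcomes; ``cutoff`` is a fixed score threshold (default 7) or
    ``"auto"`` for Youden selection on each endpoint's ROC.
    """
    required = {"lods_total", "lods_total_without_gcs", "ebi_grade",
                "severe_ebi", "cci", "mrs", "died_in_hospital", "age",
                "treatment"}
    missing = sorted(required - set(scored.columns))
    if missing:
        raise ValueError(f"scored table lacks column(s): {', '.join(missing)}")

    lods = scored["lods_total"].to_numpy(dtype=float)
    lods_ng = scored["lods_total_without_gcs"].to_numpy(dtype=float)
    unfavorable = (scored["mrs"].to_numpy(dtype=int) > 2).astype(int)
    endpoints = [
        ("severe_ebi", scored["severe_ebi"].to_numpy(dtype=bool).astype(int)),
        ("unfavorable_outcome", unfavorable),
        ("in_hospital_death",
         scored["died_in_hospital"].to_numpy(dtype=bool).astype(int)),
    ]

    distributions = {
        "ebi_grade": _distribution(scored["ebi_grade"], with_median=True),
        "lods_total": _distribution(scored["lods_total"], with_median=True),
        "mrs": _distribution(scored["mrs"]),
    }

    endpoint_blocks = [
        _endpoint_block(name, lods, lods_ng, labels, cutoff)
        for name, labels in endpoints
    ]

    X = pd.DataFrame({
        "age": scored["age"].to_numpy(dtype=float),
        "treatment_clipping":
            (scored["treatment"].astype(str) == "clipping").astype(float),
        "lods_total": lods,
        "ebi_grade": scored["ebi_grade"].to_numpy(dtype=float),
        "cci": scored["cci"].to_numpy(dtype=float),
    })
    try:
        table = ols_multivariate(X, scored["mrs"].to_numpy(dtype=float))
        multivariate = MultivariateBlock(
            outcome="mrs",
            rows=[
                RegressionRowBlock(
                    name=r.name, estimate=r.estimate, std_error=r.std_error,
                    ci_low=r.ci_low, ci_high=r.ci_high, statistic=r.statistic,
                    p_value=r.p_value, p_display=format_p(r.p_value),
                )
                for r in table.rows
            ],
            n=table.n,
        )
    except EstimationError as exc:
        multivariate = MultivariateBlock(outcome="mrs", rows=[], n=len(scored),
                                         estimable=False, reason=str(exc))

    return AnalysisReport(
        version=__version__,
        seed=seed,
        config=dict(config or {}, cutoff=cutoff),
        n_patients=int(len(scored)),
        distributions=distributions,
        endpoints=endpoint_blocks,
        multivariate=multivariate,
    )


def run_pipeline(frame: pd.DataFrame,
                 cutoff: Union[int, float, str] = DEFAULT_CUTOFF,
                 strict: bool = True,
                 seed: Optional[int] = None,
                 config: Optional[dict] = None
                 ) -> tuple[pd.DataFrame, AnalysisReport]:
    """Score a raw patient table and analyze it; returns (scores, report)."""
    scored = score_cci_table(
        score_ebi_table(score_lods_table(frame, strict=strict), strict=strict),
        strict=strict,
    )
    report = analyze_cohort(scored, cutoff=cutoff, seed=seed, config=config)
    # round-trip through the schema: guarantees the emitted JSON validates
    AnalysisReport.model_validate(report.model_dump())
    return scored, report
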