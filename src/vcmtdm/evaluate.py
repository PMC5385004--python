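"""Prediction-accuracy bookkeeping for the three trough predictors.

Three predictions of the steady-state trough exist per patient: the
population-mean prediction (PMMPV), the mixed-model correction (GLMMPV) and
the Bayesian individual estimate (BEPV), which serves as the reference.  The
signed deviations are

    PMMPDQ  = BEPV − PMMPV,     GLMMPDQ = BEPV − GLMMPV,

and the per-patient accuracy improvement is |PMMPDQ| − |GLMMPDQ|.  Overall
accuracy is summarised by ordinary least-squares regression of BEPV on each
predictor (with intercept — the comparison is of agreement, not of the
no-intercept prediction models) and by the count of deviations at or above a
clinically alarming threshold (default 10 μg/mL, the width of the
therapeutic window).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TroughComparison",
    "AccuracyReport",
    "deviations",
    "regression_r2",
    "large_deviation_summary",
    "accuracy_report",
]


@dataclass(frozen=True)
class TroughComparison:
    table: pd.DataFrame  # columns: bepv, pmmpv, glmmpv, pmmpdq, glmmpdq, improvement


def deviations(bepv: Sequence[float], pmmpv: Sequence[float],
               glmmpv: Sequence[float] | None = None) -> TroughComparison:
    """Exact signed deviations and the accuracy improvement per patient."""
    bepv = np.asarray(bepv, float)
    pmmpv = np.asarray(pmmpv, float)
    df = pd.DataFrame({"bepv": bepv, "pmmpv": pmmpv, "pmmpdq": bepv - pmmpv})
    if glmmpv is not None:
        glmmpv = np.asarray(glmmpv, float)
        df["glmmpv"] = glmmpv
        df["glmmpdq"] = bepv - glmmpv
        df["improvement"] = np.abs(df["pmmpdq"]) - np.abs(df["glmmpdq"])
    return TroughComparison(table=df)


def regression_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """OLS regression of y on x with intercept: (slope, intercept, R²)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("predictor has zero variance; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


def large_deviation_summary(devs: Sequence[float], threshold: float = 10.0,
                            signed: bool = False) -> tuple[int, float]:
    """Count and fraction of patients whose deviation reaches ``threshold``.

    By default the magnitude |deviation| is compared (positive and negative
    misses both matter clinically); ``signed=True`` counts only positive
    deviations, i.e. troughs under-predicted by at least the threshold.
    """
    devs = np.asarray(devs, float)
    vals = devs if signed else np.abs(devs)
    count = int(np.sum(vals >= threshold))
    return count, count / len(devs)


@dataclass(frozen=True)
class AccuracyReport:
    per_predictor: pd.DataFrame  # slope, intercept, r_squared, n_large, frac_large
    shapiro_p: float
    threshold: float
    n: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "threshold_ug_ml": self.threshold,
            "shapiro_p_bepv": self.shapiro_p,
            "predictors": self.per_predictor.to_dict(orient="index"),
        }


def accuracy_report(comparison: TroughComparison, threshold: float = 10.0,
                    signed: bool = False) -> AccuracyReport:
    """Accuracy comparison of PMMPV and GLMMPV against the BEPV reference."""
    df = comparison.table
    rows = {}
    for pred, dev in (("pmmpv", "pmmpdq"), ("glmmpv", "glmmpdq")):
        if pred not in df.columns:
            continue
        slope, intercept, r2 = regression_r2(df[pred], df["bepv"])
        count, frac = large_deviation_summary(df[dev], threshold, signed)
        rows[pred] = {"slope": slope, "intercept": intercept, "r_squared": r2,
                      "n_large_deviation": count,
                      "pct_large_deviation": round(100.0 * frac, 2)}
    return AccuracyReport(
        per_predictor=pd.DataFrame(rows).T,
        shapiro_p=float(stats.shapiro(df["bepv"]).pvalue),
        threshold=threshold, n=len(df))
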