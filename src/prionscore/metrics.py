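"""Predictor-evaluation panel for labeled variant data.

Given variants with a continuous predicted score, a continuous observed
aggregation readout and a binary observed class (aggregating or not),
this module computes the standard panel used to benchmark
aggregation-propensity predictors: confusion-matrix metrics (with MCC),
percentage-error summary statistics, and correlation statistics
(coefficient of determination with its two-tailed p-value, Spearman ρ).

Ratios with a zero denominator are reported as ``nan`` and rendered as
"–" in human-readable output, the usual convention for degenerate
classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_THRESHOLD = 0.45  # binarization of predicted scores: the low/increased boundary


@dataclass(frozen=True)
class LabeledPrediction:
    """One variant with predicted score and observed aggregation readout."""

    id: str
    predicted: float
    observed: float
    observed_class: bool

    def __post_init__(self) -> None:
        if not (math.isfinite(self.predicted) and math.isfinite(self.observed)):
            raise ValueError(f"non-finite values for prediction {self.id!r}")


@dataclass(frozen=True)
class MetricsReport:
    """The full evaluation panel; undefined entries are ``nan``."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    mcc: float
    mean_pct_error: float
    sd_pct_error: float
    sem_pct_error: float
    r_squared: float
    p_value: float
    spearman_rho: float
    n: int
    threshold: float
    metadata: dict = field(default_factory=dict)

    _ROWS = (
        ("Sensitivity", "sensitivity"),
        ("Specificity", "specificity"),
        ("Precision", "precision"),
        ("Accuracy", "accuracy"),
        ("MCC", "mcc"),
        ("Mean % error", "mean_pct_error"),
        ("Standard Deviation (%)", "sd_pct_error"),
        ("SEM (%)", "sem_pct_error"),
        ("Coefficient of Determination", "r_squared"),
        ("P-value (two tailed test)", "p_value"),
        ("Rho", "spearman_rho"),
    )

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        for label, attr in self._ROWS:
            v = getattr(self, attr)
            lines.append(f"{label}\t{'–' if isinstance(v, float) and math.isnan(v) else f'{v:.6g}'}")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        out = {attr: getattr(self, attr) for _, attr in self._ROWS}
        out.update(n=self.n, threshold=self.threshold, metadata=self.metadata)
        return out


def confusion_counts(preds: Sequence[LabeledPrediction], threshold: float = DEFAULT_THRESHOLD):
    """(tp, tn, fp, fn) with predicted class = predicted score >= threshold."""
    tp = tn = fp = fn = 0
    for p in preds:
        predicted_positive = p.predicted >= threshold
        if predicted_positive and p.observed_class:
            tp += 1
        elif predicted_positive and not p.observed_class:
            fp += 1
        elif not predicted_positive and p.observed_class:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(
    preds: Sequence[LabeledPrediction], threshold: float = DEFAULT_THRESHOLD
) -> dict[str, float]:
    """Sensitivity, specificity, precision, accuracy and MCC.

    MCC uses the 4-cell formula; any ratio with an empty denominator
    (e.g. precision of an all-negative classifier) is ``nan``.
    """
    if not preds:
        raise ValueError("at least one prediction is required")
    tp, tn, fp, fn = confusion_counts(preds, threshold)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "precision": _ratio(tp, tp + fp),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else math.nan,
    }


def correlation_stats(preds: Sequence[LabeledPrediction]) -> dict[str, float]:
    """R² (squared Pearson r of predicted vs observed), its two-tailed
    p-value, and Spearman ρ with average ranks on ties."""
    if len(preds) < 3:
        raise ValueError("correlation statistics require at least 3 pairs")
    x = np.array([p.predicted for p in preds])
    y = np.array([p.observed for p in preds])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r_squared": math.nan, "p_value": math.nan, "spearman_rho": math.nan}
    pearson = stats.pearsonr(x, y)
    rho = stats.spearmanr(x, y).statistic
    return {
        "r_squared": float(pearson.statistic**2),
        "p_value": float(pearson.pvalue),
        "spearman_rho": float(rho),
    }


def error_stats(preds: Sequence[LabeledPrediction]) -> dict[str, float]:
    """Mean, sample SD and SEM of per-variant percentage errors.

    Both series are min-max rescaled to a common [0, 1] span before
    differencing; the per-variant error is ``100 * (predicted -
    observed)`` on that scale.  With a single variant SD and SEM are
    undefined; a zero-span series makes the rescaling (and hence the
    panel) undefined.
    """
    if not preds:
        raise ValueError("at least one prediction is required")
    x = np.array([p.predicted for p in preds], dtype=float)
    y = np.array([p.observed for p in preds], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"mean_pct_error": math.nan, "sd_pct_error": math.nan, "sem_pct_error": math.nan}
    xs = (x - x.min()) / np.ptp(x)
    ys = (y - y.min()) / np.ptp(y)
    err = 100.0 * (xs - ys)
    mean = float(err.mean())
    if len(err) < 2:
        return {"mean_pct_error": mean, "sd_pct_error": math.nan, "sem_pct_error": math.nan}
    sd = float(err.std(ddof=1))
    return {"mean_pct_error": mean, "sd_pct_error": sd, "sem_pct_error": sd / math.sqrt(len(err))}


def evaluate_predictions(
    preds: Sequence[LabeledPrediction], threshold: float = DEFAULT_THRESHOLD
) -> MetricsReport:
    """Assemble the full panel for one predictor."""
    conf = confusion_metrics(preds, threshold)
    err = error_stats(preds)
    if len(preds) >= 3:
        corr = correlation_stats(preds)
    else:
        corr = {"r_squared": math.nan, "p_value": math.nan, "spearman_rho": math.nan}
    return MetricsReport(
        **conf, **err, **corr,
        n=len(preds), threshold=threshold,
        metadata={"pct_error_scale": "both series min-max rescaled to [0,1] before differencing"},
    )
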