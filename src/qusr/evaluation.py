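"""Diagnostic-performance evaluation with non-responder as the positive class.

Provides the confusion matrix, sensitivity/specificity/PPV/NPV/accuracy
(with exact Clopper-Pearson intervals for sensitivity, specificity and
accuracy and standard logit intervals for the predictive values), ROC/AUC,
and per-feature unpaired t-tests between response groups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

POSITIVE_LABEL = "NR"
NEGATIVE_LABEL = "R"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP = NR predicted NR; TN = R predicted R (positive class = NR)."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion metric in percent with its confidence interval."""

    point: float  # %
    ci_low: float  # %
    ci_high: float  # %
    method: str  # "clopper-pearson" | "logit" | "undefined"

    def __post_init__(self) -> None:
        if self.method != "undefined":
            if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 100.0):
                raise ValueError("CI must satisfy 0 <= low <= point <= high <= 100")

    @property
    def rounded(self) -> int:
        """Whole-percent display value."""
        return int(round(self.point))


def confusion_matrix(
    predictions: Mapping[str, str] | pd.Series,
    truths: Mapping[str, str] | pd.Series,
) -> ConfusionCounts:
    """Tally the confusion counts from id-matched label mappings."""
    pred = pd.Series(predictions)
    true = pd.Series(truths)
    if set(pred.index) != set(true.index):
        raise ValueError("prediction and truth patient ids do not match")
    true = true[pred.index]
    bad = (set(pred.unique()) | set(true.unique())) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise ValueError(f"labels must be R/NR, got {sorted(bad)}")
    tp = int(np.sum((true == POSITIVE_LABEL) & (pred == POSITIVE_LABEL)))
    fn = int(np.sum((true == POSITIVE_LABEL) & (pred == NEGATIVE_LABEL)))
    tn = int(np.sum((true == NEGATIVE_LABEL) & (pred == NEGATIVE_LABEL)))
    fp = int(np.sum((true == NEGATIVE_LABEL) & (pred == POSITIVE_LABEL)))
    return ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)


def clopper_pearson_ci(
    successes: int, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Exact binomial confidence interval via beta-distribution quantiles."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return low, high


def logit_ci(
    numerator: int, denominator: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Standard logit confidence interval for a proportion.

    Undefined (raises) at p = 0 or 1: the logit is infinite at the boundary.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    p = numerator / denominator
    if not 0.0 < p < 1.0:
        raise ValueError("logit interval undefined for boundary proportions")
    z = stats.norm.ppf(1 - alpha / 2)
    se = np.sqrt(1.0 / numerator + 1.0 / (denominator - numerator))
    lo = np.log(p / (1 - p)) - z * se
    hi = np.log(p / (1 - p)) + z * se
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))
    return float(expit(lo)), float(expit(hi))


def _metric(
    numerator: int, denominator: int, method: str, alpha: float
) -> MetricWithCI:
    if denominator == 0:
        return MetricWithCI(float("nan"), float("nan"), float("nan"), "undefined")
    p = 100.0 * numerator / denominator
    if method == "clopper-pearson":
        lo, hi = clopper_pearson_ci(numerator, denominator, alpha)
    else:
        try:
            lo, hi = logit_ci(numerator, denominator, alpha)
        except ValueError:
            # boundary proportion: fall back to the exact interval, flagged
            lo, hi = clopper_pearson_ci(numerator, denominator, alpha)
            method = "clopper-pearson (logit undefined at boundary)"
    return MetricWithCI(p, 100.0 * lo, 100.0 * hi, method)


def classification_metrics(
    counts: ConfusionCounts, alpha: float = 0.05
) -> dict[str, MetricWithCI]:
    """Sensitivity, specificity, PPV, NPV and accuracy with CIs (percent).

    Sensitivity/specificity/accuracy carry exact Clopper-Pearson intervals;
    the predictive values carry standard logit intervals.
    """
    c = counts
    return {
        "sensitivity": _metric(c.TP, c.TP + c.FN, "clopper-pearson", alpha),
        "specificity": _metric(c.TN, c.TN + c.FP, "clopper-pearson", alpha),
        "ppv": _metric(c.TP, c.TP + c.FP, "logit", alpha),
        "npv": _metric(c.TN, c.TN + c.FN, "logit", alpha),
        "accuracy": _metric(c.TP + c.TN, c.total, "clopper-pearson", alpha),
    }


def roc_auc(
    scores: Sequence[float] | pd.Series,
    truths: Sequence[str] | pd.Series,
) -> tuple[float, np.ndarray]:
    """AUC (ties count 1/2) and the ROC polyline as (FPR, TPR) rows."""
    truths = np.asarray(truths)
    scores = np.asarray(scores, dtype=float)
    ybin = (truths == POSITIVE_LABEL).astype(int)
    if len(np.unique(ybin)) < 2:
        raise ValueError("ROC requires both classes present")
    auc = float(roc_auc_score(ybin, scores))
    fpr, tpr, _ = roc_curve(ybin, scores)
    return auc, np.column_stack([fpr, tpr])


def auc_concordance(scores, truths) -> float:
    """O(n^2) pairwise-concordance AUC oracle (ties count 1/2)."""
    truths = np.asarray(truths)
    scores = np.asarray(scores, dtype=float)
    pos = scores[truths == POSITIVE_LABEL]
    neg = scores[truths != POSITIVE_LABEL]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def group_ttests(
    deltas: pd.DataFrame,
    truths: pd.Series,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-feature unpaired t-tests (Welch by default) between R and NR.

    Returns a DataFrame indexed by feature with columns t, p (unadjusted).
    Features with zero variance in both groups get NaN, flagged undefined.
    """
    truths = truths[deltas.index]
    g1 = deltas[truths == POSITIVE_LABEL]
    g2 = deltas[truths == NEGATIVE_LABEL]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 patients per response group")
    rows = []
    for col in deltas.columns:
        a, b = g1[col].to_numpy(), g2[col].to_numpy()
        if np.var(a) == 0 and np.var(b) == 0:
            rows.append({"feature": col, "t": np.nan, "p": np.nan, "defined": False})
            continue
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append({"feature": col, "t": float(t), "p": float(p), "defined": True})
    return pd.DataFrame(rows).set_index("feature")


@dataclass
class PerformanceReport:
    counts: ConfusionCounts
    metrics: dict[str, MetricWithCI]
    auc: float | None
    roc_points: np.ndarray | None
    n_excluded: int = 0

    def to_dict(self) -> dict:
        out = {
            "counts": asdict(self.counts),
            "n": self.counts.total,
            "n_excluded": self.n_excluded,
            "metrics": {
                k: {
                    "percent": m.point,
                    "percent_rounded": m.rounded if np.isfinite(m.point) else None,
                    "ci_low": m.ci_low,
                    "ci_high": m.ci_high,
                    "method": m.method,
                }
                for k, m in self.metrics.items()
            },
        }
        if self.auc is not None:
            out["auc"] = self.auc
            out["roc_points"] = self.roc_points.tolist() if self.roc_points is not None else None
        return out

    def to_text(self) -> str:
        lines = [
            f"n = {self.counts.total} (excluded: {self.n_excluded})",
            f"confusion: TP={self.counts.TP} FN={self.counts.FN} "
            f"TN={self.counts.TN} FP={self.counts.FP}  (positive class = NR)",
        ]
        for k, m in self.metrics.items():
            if np.isfinite(m.point):
                lines.append(
                    f"{k:>12s}: {m.rounded:3d}% ({m.ci_low:.0f}-{m.ci_high:.0f}%) [{m.method}]"
                )
            else:
                lines.append(f"{k:>12s}: undefined")
        if self.auc is not None:
            lines.append(f"{'AUC':>12s}: {self.auc:.2f}")
        return "\n".join(lines)


def evaluate_predictions(
    predictions: pd.DataFrame,
    truths: pd.Series,
    exclude: Sequence[str] = (),
    alpha: float = 0.05,
) -> PerformanceReport:
    """Full report from a predictions table (class_score, predicted_label).

    ``exclude`` removes patients before evaluation (exploratory re-analysis).
    """
    keep = [i for i in predictions.index if i not in set(exclude)]
    n_excluded = len(predictions) - len(keep)
    pred = predictions.loc[keep]
    truth = truths[keep]
    counts = confusion_matrix(pred["predicted_label"], truth)
    metrics = classification_metrics(counts, alpha)
    auc = None
    roc_points = None
    if "class_score" in pred.columns and truth.nunique() == 2:
        auc, roc_points = roc_auc(pred["class_score"], truth)
    return PerformanceReport(
        counts=counts, metrics=metrics, auc=auc, roc_points=roc_points, n_excluded=n_excluded
    )
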