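"""Video-level performance metrics, ROC/AUC, threshold sweeps and the paired
McNemar comparison.

Conventions: the positive class is "free fluid present"; sensitivity is the
true-positive rate (recall); degenerate ratios (e.g. precision with no
positive calls) are reported as NaN with an explicit flag, never silently 0.
The McNemar test is the exact binomial variant — appropriate at the tens-of-
videos scale where the chi-square approximation is unreliable — with a
continuity-corrected chi-square option for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .infer import PredictionRecord


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    threshold: float
    undefined: tuple[str, ...] = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class RocCurve:
    points: list[tuple[float, float]]   # (FPR, TPR), sorted by FPR
    thresholds: list[float]
    auc: float


@dataclass
class McNemarResult:
    b: int              # videos model A alone got right
    c: int              # videos model B alone got right
    n_concordant: int   # both right + both wrong
    p_value: float
    statistic: float | None = None
    degenerate: bool = False
    method: str = "exact-binomial"


def _counts(records: list[PredictionRecord], threshold: float
            ) -> tuple[int, int, int, int]:
    tp = fp = fn = tn = 0
    for r in records:
        if r.true_label is None:
            raise ValueError(f"record {r.video_id!r} has no true label")
        pred_pos = r.video_score >= threshold
        if r.true_label == "positive":
            tp += bool(pred_pos)
            fn += not pred_pos
        else:
            fp += bool(pred_pos)
            tn += not pred_pos
    return int(tp), int(fp), int(fn), int(tn)


def compute_metrics(records: list[PredictionRecord], threshold: float
                    ) -> MetricsReport:
    """Confusion counts and the four standard ratios at one threshold.

    Video scores are re-thresholded here, so one set of records can be swept
    over a threshold grid.
    """
    tp, fp, fn, tn = _counts(records, threshold)
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = ratio(tp + tn, tp + fp + fn + tn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        undefined.append("f1")
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn, accuracy=accuracy,
                         precision=precision, sensitivity=sensitivity, f1=f1,
                         threshold=threshold, undefined=tuple(undefined))


def confusion_matrix_normalized(records: list[PredictionRecord],
                                threshold: float) -> np.ndarray:
    """2x2 confusion matrix with each true-class row normalized to 1.

    Rows: (positive, negative) truth; columns: (positive, negative) calls.
    A row with no videos of that class is NaN.
    """
    tp, fp, fn, tn = _counts(records, threshold)
    out = np.full((2, 2), np.nan)
    if tp + fn:
        out[0] = [tp / (tp + fn), fn / (tp + fn)]
    if fp + tn:
        out[1] = [fp / (fp + tn), tn / (fp + tn)]
    return out


def roc_auc(records: list[PredictionRecord]) -> RocCurve:
    """ROC over the video scores with trapezoidal AUC.

    Thresholds are the sorted unique scores plus a sentinel above the maximum;
    the curve always contains (0, 0) and (1, 1).
    """
    y = np.array([1 if r.true_label == "positive" else 0 for r in records])
    s = np.array([r.video_score for r in records], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
                    thresholds=[float(t) for t in thr],
                    auc=float(_trapezoid_auc(fpr, tpr)))


_SELECTORS = {
    "f1": lambda m: m.f1,
    "accuracy": lambda m: m.accuracy,
    "youden": lambda m: (m.sensitivity if not np.isnan(m.sensitivity) else 0.0)
    - (m.fp / (m.fp + m.tn) if (m.fp + m.tn) else 0.0),
}


def threshold_sweep(records: list[PredictionRecord],
                    grid: "np.ndarray | list[float]" = None,
                    criterion: str = "f1",
                    override: float | None = None
                    ) -> tuple[list[MetricsReport], float]:
    """One MetricsReport per grid threshold plus the selected threshold.

    Selection maximizes the criterion (default F1; 'youden' and 'accuracy'
    also available), breaking ties toward the lower threshold; NaN scores
    never win. An ``override`` (e.g. an externally chosen operating point such
    as 0.75 or 0.05) bypasses selection but the sweep table is still returned.
    """
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    grid = list(grid)
    if any(t < 0 or t > 1 for t in grid):
        raise ValueError("grid thresholds must lie in [0, 1]")
    score = _SELECTORS[criterion]
    reports = [compute_metrics(records, t) for t in grid]
    if override is not None:
        return reports, float(override)
    best_t, best_v = None, -np.inf
    for t, rep in zip(grid, reports):
        v = score(rep)
        if not np.isnan(v) and v > best_v + 1e-12:
            best_t, best_v = t, v
    if best_t is None:
        best_t = grid[0]
    return reports, float(best_t)


def mcnemar_test(records_a: list[PredictionRecord],
                 records_b: list[PredictionRecord],
                 method: str = "exact-binomial") -> McNemarResult:
    """Paired comparison of two models on the same videos.

    b = videos only model A classified correctly, c = only model B. Exact
    two-sided p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b+c, 1/2);
    with no discordant videos the test is degenerate and p = 1. The
    'chi2-corrected' method applies the continuity-corrected chi-square.
    """
    by_id_b = {r.video_id: r for r in records_b}
    if set(by_id_b) != {r.video_id for r in records_a}:
        raise ValueError("the two record sets must cover the same videos")
    b = c = conc = 0
    for ra in records_a:
        rb = by_id_b[ra.video_id]
        if ra.true_label != rb.true_label:
            raise ValueError(f"true labels disagree for {ra.video_id!r}")
        ok_a = ra.predicted_label == ra.true_label
        ok_b = rb.predicted_label == rb.true_label
        if ok_a and not ok_b:
            b += 1
        elif ok_b and not ok_a:
            c += 1
        else:
            conc += 1
    n_disc = b + c
    if n_disc == 0:
        return McNemarResult(b=b, c=c, n_concordant=conc, p_value=1.0,
                             degenerate=True, method=method)
    if method == "exact-binomial":
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5)))
        return McNemarResult(b=b, c=c, n_concordant=conc, p_value=p,
                             method=method)
    if method == "chi2-corrected":
        chi2 = (abs(b - c) - 1) ** 2 / n_disc
        p = float(stats.chi2.sf(chi2, df=1))
        return McNemarResult(b=b, c=c, n_concordant=conc, p_value=p,
                             statistic=chi2, method=method)
    raise ValueError(f"unknown method {method!r}")
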