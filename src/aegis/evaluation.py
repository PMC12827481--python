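"""Classification metrics, threshold calibration and compound ranking.

Binary DILI prediction is evaluated with specificity, sensitivity,
precision and Matthews correlation coefficient (MCC):

    specificity = TN / (TN + FP)        sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A calibration curve sweeps every observed score as a cutoff (prediction
positive iff score >= cutoff) and records the metrics at each; the
best-by-MCC cutoff defines the high-risk zone.  Fisher's exact test with
the conditional-MLE odds ratio and its exact 95% CI summarises a 2x2
classification table; paired compound ranking tests the mean difference
in score between structurally similar compound pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
            setattr(self, name, int(v))
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_table(self) -> np.ndarray:
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass
class ClassificationMetrics:
    """Metrics are NaN (not 0) when their denominator is 0; MCC is 0 when
    any marginal total is 0 (no association determinable)."""

    specificity: float
    sensitivity: float
    precision: float
    mcc: float


def metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom2) if denom2 > 0 else 0.0
    return ClassificationMetrics(
        specificity=ratio(tn, tn + fp),
        sensitivity=ratio(tp, tp + fn),
        precision=ratio(tp, tp + fp),
        mcc=mcc,
    )


@dataclass
class CalibrationCurve:
    """Stepwise threshold sweep: metrics at every candidate cutoff.

    ``table`` is indexed by strictly increasing threshold, with columns
    tp, fp, tn, fn, sensitivity, specificity, precision, mcc.
    """

    table: pd.DataFrame
    best_threshold_by_mcc: float

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "threshold"
        out.to_csv(path, sep="\t")


def threshold_sweep(scores, labels=None) -> CalibrationCurve:
    """Calibration curve over all observed scores plus 0 and 1.

    ``scores`` is either a sequence of (score, label) pairs or an array of
    scores with ``labels`` (truthy = DILI positive) given separately.
    Prediction is positive iff score >= threshold.
    """
    if labels is None:
        pairs = list(scores)
        s = np.array([p[0] for p in pairs], dtype=float)
        y = np.array([bool(p[1]) for p in pairs])
    else:
        s = np.asarray(scores, dtype=float)
        y = np.asarray(labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("threshold sweep needs both positive and negative labels")
    thresholds = np.unique(np.concatenate([s, [0.0, 1.0]]))
    rows = []
    for thr in thresholds:
        pred = s >= thr
        cm = ConfusionMatrix(
            tp=int((pred & y).sum()),
            fp=int((pred & ~y).sum()),
            tn=int((~pred & ~y).sum()),
            fn=int((~pred & y).sum()),
        )
        mt = metrics(cm)
        rows.append(
            {
                "threshold": thr, "tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn,
                "sensitivity": mt.sensitivity, "specificity": mt.specificity,
                "precision": mt.precision, "mcc": mt.mcc,
            }
        )
    table = pd.DataFrame(rows).set_index("threshold")
    best = float(table["mcc"].idxmax())  # idxmax returns first (lowest) on ties
    return CalibrationCurve(table=table, best_threshold_by_mcc=best)


def precision_trend(curve: CalibrationCurve) -> float:
    """Spearman rank correlation of threshold vs precision over the
    thresholds where precision is defined.  A positive value means higher
    scores predict DILI with higher precision."""
    tab = curve.table["precision"].dropna()
    if len(tab) < 3:
        raise ValueError("need >= 3 thresholds with defined precision")
    rho, _ = stats.spearmanr(tab.index.to_numpy(), tab.to_numpy())
    return float(rho)


@dataclass
class FisherResult:
    p_two_sided: float
    odds_ratio_cmle: float
    ci_low: float
    ci_high: float


def fisher_exact(cm: ConfusionMatrix) -> FisherResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio and
    exact 95% CI (inverting one-sided exact tests at alpha/2)."""
    table = cm.as_table()
    _, p = stats.fisher_exact(table, alternative="two-sided")
    margins_ok = table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0
    if margins_ok:
        res = _odds_ratio(table, kind="conditional")
        ci = res.confidence_interval(confidence_level=0.95)
        return FisherResult(float(p), float(res.statistic), float(ci.low), float(ci.high))
    return FisherResult(float(p), float("nan"), float("nan"), float("nan"))


@dataclass
class PairRanking:
    """Per-pair score differences (more-toxic minus less-toxic) per dose,
    with a two-sided one-sample t-test of the mean difference against 0."""

    deltas: pd.DataFrame
    t_statistic: float
    p_value: float
    mean_delta: float
    median_percent_increase: float
    degenerate: bool = False


def pair_delta(scores: pd.DataFrame, pairs, dose: float | None = None) -> PairRanking:
    """Rank structurally similar compound pairs by score difference.

    ``scores`` needs columns compound, dose_multiple and a score column
    (``normalized`` or ``score_mean``; the first present is used).
    ``pairs`` is a list of (label_less, label_more).  ``dose`` restricts the
    comparison to one dose multiple; otherwise each common dose contributes
    a delta.  The t-test is computed across all deltas.
    """
    score_col = next(c for c in ("score_mean", "normalized", "score") if c in scores.columns)
    df = scores if dose is None else scores[scores["dose_multiple"] == dose]
    lookup = df.groupby(["compound", "dose_multiple"])[score_col].mean()
    rows = []
    for less, more in pairs:
        doses_less = {d for (c, d) in lookup.index if c == less}
        doses_more = {d for (c, d) in lookup.index if c == more}
        for d in sorted(doses_less & doses_more):
            s_less, s_more = lookup[(less, d)], lookup[(more, d)]
            rows.append(
                {
                    "label_less": less, "label_more": more, "dose_multiple": d,
                    "score_less": s_less, "score_more": s_more,
                    "delta": s_more - s_less,
                    "percent_increase": (s_more - s_less) / s_less * 100.0 if s_less > 0 else float("nan"),
                }
            )
    if not rows:
        raise ValueError("no pair has both members scored at a common dose")
    deltas = pd.DataFrame(rows)
    d = deltas["delta"].to_numpy()
    if len(d) < 2:
        raise ValueError("need >= 2 pair deltas for the t-test")
    degenerate = False
    if np.allclose(d.std(ddof=1), 0.0):
        degenerate = True
        if np.allclose(d.mean(), 0.0):
            tstat, p = 0.0, 1.0
        else:
            tstat, p = math.copysign(math.inf, d.mean()), 0.0
    else:
        tstat, p = stats.ttest_1samp(d, 0.0)
    return PairRanking(
        deltas=deltas,
        t_statistic=float(tstat),
        p_value=float(p),
        mean_delta=float(d.mean()),
        median_percent_increase=float(np.nanmedian(deltas["percent_increase"])),
        degenerate=degenerate,
    )
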