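"""Classification metrics, threshold sweep, Fisher exact, pair ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aegis import (
    ConfusionMatrix,
    fisher_exact,
    metrics,
    pair_delta,
    precision_trend,
    threshold_sweep,
)


class TestMetrics:
    def test_reported_performance_table(self):
        # the unique 12-positive/7-negative table with sens 75% and spec 86%
        mt = metrics(ConfusionMatrix(tp=9, fn=3, fp=1, tn=6))
        assert mt.sensitivity == pytest.approx(0.75)
        assert mt.specificity == pytest.approx(6 / 7)
        assert mt.precision == pytest.approx(0.90)
        assert mt.mcc == pytest.approx(0.5866, abs=1e-4)

    def test_perfect_classifier(self):
        mt = metrics(ConfusionMatrix(tp=5, fn=0, fp=0, tn=5))
        assert (mt.sensitivity, mt.specificity, mt.precision, mt.mcc) == (1, 1, 1, 1)

    def test_all_predicted_positive(self):
        mt = metrics(ConfusionMatrix(tp=3, fn=0, fp=7, tn=0))
        assert mt.specificity == 0.0
        assert mt.precision == pytest.approx(0.3)  # prevalence
        assert mt.mcc == 0.0  # a zero marginal

    def test_undefined_metric_is_nan_not_zero(self):
        mt = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=4))
        assert np.isnan(mt.sensitivity)
        assert np.isnan(mt.precision)

    def test_mcc_near_zero_under_label_permutation(self):
        rng = np.random.default_rng(0)
        mccs = []
        for _ in range(200):
            y = rng.permutation([1] * 10 + [0] * 10)
            pred = np.array([1] * 10 + [0] * 10)
            cm = ConfusionMatrix(
                tp=int((pred & y).sum()), fp=int((pred & (1 - y)).sum()),
                tn=int(((1 - pred) & (1 - y)).sum()), fn=int(((1 - pred) & y).sum()),
            )
            mccs.append(metrics(cm).mcc)
        assert abs(np.mean(mccs)) < 0.05


def brute_force_sweep(scores, labels, thresholds):
    """Independent cutoff enumeration."""
    out = []
    for thr in thresholds:
        pred = scores >= thr
        tp = int((pred & labels).sum()); fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum()); tn = int((~pred & ~labels).sum())
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
        out.append((tp, fp, tn, fn, mcc))
    return out


class TestThresholdSweep:
    def test_separable_toy_case(self):
        curve = threshold_sweep([(0.9, 1), (0.8, 1), (0.2, 0), (0.1, 0)])
        row = curve.table.loc[0.8]
        assert row["mcc"] == pytest.approx(1.0)
        assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0
        assert curve.best_threshold_by_mcc == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.uniform(size=200), 3)
        labels = rng.uniform(size=200) < stats.norm.cdf(3 * (scores - 0.5))
        curve = threshold_sweep(scores, labels)
        oracle = brute_force_sweep(scores, labels, curve.table.index.to_numpy())
        for (thr, row), (tp, fp, tn, fn, mcc) in zip(curve.table.iterrows(), oracle):
            assert (row["tp"], row["fp"], row["tn"], row["fn"]) == (tp, fp, tn, fn)
            assert row["mcc"] == pytest.approx(mcc)

    def test_monotone_sensitivity_specificity(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=100)
        labels = rng.integers(0, 2, size=100).astype(bool)
        curve = threshold_sweep(scores, labels)
        sens = curve.table["sensitivity"].to_numpy()
        spec = curve.table["specificity"].to_numpy()
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()
        assert (np.diff(curve.table["tp"] + curve.table["fp"]) <= 0).all()

    def test_shuffled_labels_best_mcc_near_chance(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=60)
        best = []
        for _ in range(200):
            labels = rng.permutation([True] * 30 + [False] * 30)
            best.append(threshold_sweep(scores, labels).table["mcc"].max())
        # best-of-sweep is optimistically biased but stays small under the null
        assert np.mean(best) < 0.35
        assert np.quantile(best, 0.05) > -0.05

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            threshold_sweep([(0.5, 1), (0.6, 1)])


class TestPrecisionTrend:
    def test_separable_scores_give_strong_positive_correlation(self):
        curve = threshold_sweep([(0.9, 1), (0.8, 1), (0.3, 0), (0.1, 0)])
        # precision plateaus (ties) keep Spearman just below 1 on tiny inputs
        assert precision_trend(curve) > 0.9
        prec = curve.table["precision"].dropna().to_numpy()
        assert (np.diff(prec) >= -1e-12).all()

    def test_anti_separated_scores_give_negative_correlation(self):
        curve = threshold_sweep([(0.9, 0), (0.8, 0), (0.3, 1), (0.1, 1)])
        assert precision_trend(curve) < 0

    def test_calibrated_generator_gives_positive_trend(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(50):
            scores = rng.uniform(size=80)
            labels = rng.uniform(size=80) < scores
            if labels.all() or not labels.any():
                continue
            if precision_trend(threshold_sweep(scores, labels)) > 0:
                hits += 1
        assert hits >= 45


def fisher_p_enumeration(table):
    """Two-sided Fisher p by full enumeration over tables with fixed margins."""
    a, b = table[0]
    c, d = table[1]
    r1, c1, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, r1, c1)
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        px = stats.hypergeom.pmf(x, n, r1, c1)
        if px <= obs * (1 + 1e-7):
            p += px
    return min(p, 1.0)


class TestFisherExact:
    def test_reported_classification_table(self):
        res = fisher_exact(ConfusionMatrix(tp=9, fn=3, fp=1, tn=6))
        assert res.p_two_sided == pytest.approx(0.0198, abs=2e-4)
        assert res.odds_ratio_cmle == pytest.approx(14.9, rel=0.01)
        assert res.ci_low == pytest.approx(1.15, rel=0.02)
        assert res.ci_high == pytest.approx(910.1, rel=0.02)
        assert res.ci_low <= res.odds_ratio_cmle <= res.ci_high

    def test_identical_rows_give_null_result(self):
        res = fisher_exact(ConfusionMatrix(tp=4, fn=4, fp=4, tn=4))
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.odds_ratio_cmle == pytest.approx(1.0, abs=1e-6)

    def test_p_matches_enumeration_on_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            cells = rng.integers(0, 8, size=4)
            if cells.sum() == 0:
                continue
            cm = ConfusionMatrix(tp=cells[0], fn=cells[1], fp=cells[2], tn=cells[3])
            res = fisher_exact(cm)
            assert res.p_two_sided == pytest.approx(
                fisher_p_enumeration(cm.as_table()), rel=1e-8
            )

    def test_p_invariant_to_transpose_and_label_swap(self):
        cm = ConfusionMatrix(tp=7, fn=2, fp=3, tn=5)
        p0 = fisher_exact(cm).p_two_sided
        transposed = ConfusionMatrix(tp=7, fn=3, fp=2, tn=5)
        swapped = ConfusionMatrix(tp=5, fn=3, fp=2, tn=7)
        assert fisher_exact(transposed).p_two_sided == pytest.approx(p0)
        assert fisher_exact(swapped).p_two_sided == pytest.approx(p0)


def scores_frame(records):
    return pd.DataFrame(records, columns=["compound", "dose_multiple", "normalized"])


class TestPairDelta:
    def test_all_zero_deltas_give_p_one(self):
        df = scores_frame(
            [("a", 10, 0.5), ("b", 10, 0.5), ("c", 10, 0.2), ("d", 10, 0.2)]
        )
        res = pair_delta(df, [("a", "b"), ("c", "d")], dose=10)
        assert res.p_value == 1.0 and res.t_statistic == 0.0
        assert res.degenerate

    def test_constant_positive_delta_flagged(self):
        df = scores_frame(
            [("a", 10, 0.2), ("b", 10, 0.5), ("c", 10, 0.4), ("d", 10, 0.7)]
        )
        res = pair_delta(df, [("a", "b"), ("c", "d")], dose=10)
        assert res.p_value == 0.0 and res.degenerate
        assert res.mean_delta == pytest.approx(0.3)

    def test_missing_pair_member_raises(self):
        df = scores_frame([("a", 10, 0.2)])
        with pytest.raises(ValueError):
            pair_delta(df, [("a", "zz")], dose=10)

    def test_rejection_rate_matches_noncentral_t_power(self):
        # delta ~ N(0.3, 0.2), 9 pairs: analytic power of the one-sample t-test
        rng = np.random.default_rng(6)
        n, mu, sd, alpha, reps = 9, 0.3, 0.2, 0.05, 1000
        rejections = 0
        for _ in range(reps):
            deltas = rng.normal(mu, sd, size=n)
            records = []
            for i, dlt in enumerate(deltas):
                records.append((f"less{i}", 10, 0.4))
                records.append((f"more{i}", 10, 0.4 + dlt))
            res = pair_delta(scores_frame(records), [(f"less{i}", f"more{i}") for i in range(n)], dose=10)
            rejections += res.p_value < alpha
        nc = mu / (sd / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
        se = np.sqrt(power * (1 - power) / reps)
        assert abs(rejections / reps - power) < 3.5 * se

    def test_median_percent_increase(self):
        df = scores_frame(
            [("a", 10, 0.2), ("b", 10, 0.3), ("c", 10, 0.5), ("d", 10, 0.6)]
        )
        res = pair_delta(df, [("a", "b"), ("c", "d")], dose=10)
        assert res.median_percent_increase == pytest.approx((50 + 20) / 2)
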