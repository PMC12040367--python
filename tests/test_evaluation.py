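"""Evaluation protocol: rank metrics vs brute force, PPV thresholds,
bootstrap, calibration, stratified split."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungrisk.evaluation import (
    InfeasiblePPVError,
    OperatingPoint,
    PredictionSet,
    auprc,
    auroc,
    bootstrap_ci,
    brier,
    build_metric_report,
    calibration_curve,
    concatenate,
    operating_point,
    stratified_split,
    threshold_for_ppv,
)


def auroc_brute(scores, labels):
    """Pairwise concordance by full enumeration."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def auprc_brute(scores, labels):
    """Average precision by walking distinct scores in descending order."""
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores), reverse=True):
        flagged = scores >= t
        tp = int((labels[flagged] == 1).sum())
        precision = tp / int(flagged.sum())
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def threshold_brute(scores, labels, target):
    """Exhaustive scan over all distinct-score cutoffs."""
    best = None
    for t in sorted(set(scores), reverse=True):
        flagged = scores >= t
        tp = int((labels[flagged] == 1).sum())
        if tp / flagged.sum() >= target:
            if best is None or flagged.sum() > best[1]:
                best = (t, int(flagged.sum()))
    return None if best is None else best[0]


class TestAuroc:
    def test_worked_example(self):
        preds = PredictionSet(np.array([0.1, 0.4, 0.35, 0.8]),
                              np.array([0, 0, 1, 1]))
        assert auroc(preds) == pytest.approx(0.75)

    def test_perfect_separation(self):
        preds = PredictionSet(np.array([0.1, 0.2, 0.8, 0.9]),
                              np.array([0, 0, 1, 1]))
        assert auroc(preds) == 1.0

    def test_all_ties(self):
        preds = PredictionSet(np.full(10, 0.3), np.array([0, 1] * 5))
        assert auroc(preds) == 0.5

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auroc(PredictionSet(np.array([0.1, 0.2]), np.array([1, 1])))


class TestAuprc:
    def test_perfect_ranking(self):
        preds = PredictionSet(np.array([0.9, 0.8, 0.2, 0.1]),
                              np.array([1, 1, 0, 0]))
        assert auprc(preds) == 1.0

    def test_single_positive_ranked_last(self):
        preds = PredictionSet(np.array([0.9, 0.8, 0.7, 0.1]),
                              np.array([0, 0, 0, 1]))
        assert auprc(preds) == pytest.approx(0.25)

    def test_stepwise_enumeration_example(self):
        preds = PredictionSet(np.array([0.9, 0.8, 0.7]),
                              np.array([1, 0, 1]))
        assert auprc(preds) == pytest.approx(1 * 0.5 + (2 / 3) * 0.5)

    def test_no_positive_raises(self):
        with pytest.raises(ValueError):
            auprc(PredictionSet(np.array([0.1, 0.2]), np.array([0, 0])))


class TestBrier:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1.0, 0.0, 1.0], [1, 0, 1], 0.0),
            ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.25),
            ([0.8, 0.2], [1, 0], 0.04),
        ],
    )
    def test_direct_arithmetic(self, scores, labels, expected):
        assert brier(PredictionSet(np.array(scores),
                                   np.array(labels))) == pytest.approx(expected)


class TestOracleEquivalence:
    def test_rank_metrics_match_brute_force_with_ties(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 50))
            # coarse grid forces plenty of ties
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            preds = PredictionSet(scores, labels)
            assert auroc(preds) == pytest.approx(
                auroc_brute(scores, labels), abs=1e-12)
            assert auprc(preds) == pytest.approx(
                auprc_brute(scores, labels), abs=1e-12)

    def test_matches_sklearn_on_untied_scores(self, rng):
        from sklearn.metrics import average_precision_score, roc_auc_score

        for _ in range(50):
            n = int(rng.integers(10, 200))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            preds = PredictionSet(scores, labels)
            assert auroc(preds) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)
            assert auprc(preds) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12)


class TestThresholdForPpv:
    def test_worked_examples(self):
        preds = PredictionSet(np.array([0.9, 0.8, 0.3]),
                              np.array([1, 0, 0]))
        assert threshold_for_ppv(preds, 0.5) == pytest.approx(0.8)
        assert threshold_for_ppv(preds, 1.0) == pytest.approx(0.9)

    def test_all_negative_infeasible(self):
        preds = PredictionSet(np.array([0.9, 0.8]), np.array([0, 0]))
        with pytest.raises(InfeasiblePPVError):
            threshold_for_ppv(preds, 0.1)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(st.integers(min_value=0, max_value=10**6),
           st.sampled_from([0.1, 0.3, 0.5, 0.9]))
    def test_matches_exhaustive_scan(self, seed, target):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        scores = rng.choice(np.linspace(0, 1, 9), size=n)
        labels = rng.integers(0, 2, size=n)
        oracle = threshold_brute(scores, labels, target)
        preds = PredictionSet(scores, labels)
        if oracle is None:
            with pytest.raises(InfeasiblePPVError):
                threshold_for_ppv(preds, target)
        else:
            assert threshold_for_ppv(preds, target) == pytest.approx(oracle)

    def test_sensitivity_monotone_in_target(self, rng):
        scores = rng.random(400)
        labels = (rng.random(400) < 0.3).astype(int)
        preds = PredictionSet(scores, labels)
        sens = []
        for target in (0.25, 0.3, 0.35, 0.4):
            try:
                sens.append(operating_point(preds, target).sensitivity)
            except InfeasiblePPVError:
                break
        assert all(a >= b for a, b in zip(sens, sens[1:]))


class TestOperatingPoint:
    def test_confusion_identities(self, rng):
        scores = rng.random(500)
        labels = (rng.random(500) < scores).astype(int)
        op = operating_point(PredictionSet(scores, labels), 0.6)
        assert op.n == 500
        assert op.ppv_achieved >= 0.6
        assert op.sensitivity == op.tp / (op.tp + op.fn)
        assert op.fp == pytest.approx(op.tp / op.ppv_achieved - op.tp)

    def test_case_finding_arithmetic_at_three_percent_ppv(self):
        # at PPV 3%, flagging tp true cases implies tp/0.03 - tp false
        # alarms; with 291 true positives that is 9409 patients, and
        # finding 1480 of 2386 cases is 62% sensitivity
        op = OperatingPoint(target_ppv=0.03, threshold=0.5,
                            tp=291, fp=9409, tn=500000, fn=185)
        assert op.ppv_achieved == pytest.approx(0.03, abs=1e-4)
        assert round(291 / 0.03 - 291) == 9409
        assert round(100 * 1480 / 2386) == 62


class TestCalibration:
    def test_constant_predictor_single_bin(self):
        preds = PredictionSet(np.full(50, 0.2),
                              np.array([1] * 10 + [0] * 40))
        rows = calibration_curve(preds)
        assert len(rows) == 1
        assert rows[0]["mean_predicted"] == pytest.approx(0.2)
        assert rows[0]["observed_rate"] == pytest.approx(0.2)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_bins_partition_all_predictions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 300))
        preds = PredictionSet(rng.random(n), rng.integers(0, 2, size=n))
        for scheme in ("quantile", "width"):
            rows = calibration_curve(preds, scheme=scheme)
            assert sum(r["n"] for r in rows) == n

    def test_simulated_calibrated_scores_fall_on_diagonal(self):
        rng = np.random.default_rng(8)
        p = rng.random(100_000)
        y = (rng.random(100_000) < p).astype(int)
        rows = calibration_curve(PredictionSet(p, y), n_bins=10)
        max_dev = max(abs(r["mean_predicted"] - r["observed_rate"])
                      for r in rows)
        assert max_dev < 0.02

    def test_too_few_bins_raises(self):
        preds = PredictionSet(np.array([0.1, 0.9]), np.array([0, 1]))
        with pytest.raises(ValueError):
            calibration_curve(preds, n_bins=1)


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        preds = PredictionSet(np.array([0.2, 0.8] * 20),
                              np.array([0, 1] * 20))
        point, lo, hi = bootstrap_ci(lambda p: 0.42, preds, B=100, seed=1)
        assert point == lo == hi == 0.42

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        preds = PredictionSet(rng.random(80), rng.integers(0, 2, size=80))
        a = bootstrap_ci(auroc, preds, B=200, seed=9)
        b = bootstrap_ci(auroc, preds, B=200, seed=9)
        assert a == b
        c = bootstrap_ci(auroc, preds, B=200, seed=10)
        assert a != c

    def test_unstable_bootstrap_raises(self):
        # a metric that is computable on the original set but infeasible
        # on any resample with repeated patients: nearly every resample
        # is skipped, which the bootstrap must refuse to summarise
        preds = PredictionSet(np.array([0.9, 0.8, 0.1, 0.05]),
                              np.array([0, 1, 0, 1]))

        def fussy_metric(p):
            if len(set(p.scores.tolist())) < 4:
                raise ValueError("degenerate resample")
            return 0.0

        with pytest.raises(RuntimeError, match="unstable"):
            bootstrap_ci(fussy_metric, preds, B=200, seed=0)

    def test_report_ci_brackets_point(self, rng):
        scores = np.clip(rng.normal(0.3, 0.2, size=300), 0, 1)
        labels = (rng.random(300) < scores).astype(int)
        rep = build_metric_report(PredictionSet(scores, labels), B=200, seed=3)
        for point, lo, hi in (rep.auroc, rep.auprc, rep.brier):
            assert lo <= point <= hi


class TestStratifiedSplit:
    def test_class_counts_match_fractions(self):
        labels = np.array([1] * 100 + [0] * 900)
        tr, tu, te = stratified_split(labels, seed=0)
        for part, frac in ((tr, 0.6), (tu, 0.2), (te, 0.2)):
            assert abs(labels[part].sum() - 100 * frac) <= 1
            assert abs(len(part) - 1000 * frac) <= 2

    def test_partition_disjoint_exhaustive(self, rng):
        labels = rng.integers(0, 2, size=237)
        if labels.sum() < 5:
            labels[:5] = 1
        tr, tu, te = stratified_split(labels, seed=4)
        allidx = np.concatenate([tr, tu, te])
        assert len(allidx) == 237
        assert len(np.unique(allidx)) == 237

    def test_same_seed_same_split(self):
        labels = np.array([0, 1] * 50)
        assert all(
            np.array_equal(a, b)
            for a, b in zip(stratified_split(labels, seed=2),
                            stratified_split(labels, seed=2))
        )

    def test_too_few_positives_raises(self):
        labels = np.array([1] + [0] * 99)
        with pytest.raises(ValueError):
            stratified_split(labels, seed=0)

    def test_bad_fractions_raise(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 1] * 10), fractions=(0.5, 0.2, 0.2))


class TestConcatenate:
    def test_stacked_metrics_equal_concatenated_recomputation(self, rng):
        parts = []
        for c in range(3):
            scores = rng.random(60)
            labels = rng.integers(0, 2, size=60)
            parts.append(PredictionSet(scores, labels,
                                       np.array([f"c{c}"] * 60)))
        stacked = concatenate(parts)
        assert stacked.n == 180
        direct = PredictionSet(
            np.concatenate([p.scores for p in parts]),
            np.concatenate([p.labels for p in parts]),
        )
        assert auroc(stacked) == pytest.approx(auroc(direct), abs=1e-15)
        assert brier(stacked) == pytest.approx(brier(direct), abs=1e-15)
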