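"""Metrics: confusion/accuracy, ROC/PR vs brute force, thresholds,
detection curves, the SNR estimator and the error-analysis statistics."""

import numpy as np
import pandas as pd
import pytest

from flightcall.evaluation import (
    SNRRecord,
    confusion_and_accuracy,
    curve_correlation,
    detection_histogram,
    estimate_snr,
    f1_at_threshold,
    pr,
    roc,
    select_threshold,
    snr_error_analysis,
)
from flightcall.frontend import AudioClip
from flightcall.synth import ARCHETYPES, SceneSpec, mix_scene, synth_call


def expand_counts(tp, fn, fp, tn, pos="WTSP", neg="OTHER"):
    y_true = [pos] * (tp + fn) + [neg] * (fp + tn)
    y_pred = [pos] * tp + [neg] * fn + [pos] * fp + [neg] * tn
    return y_true, y_pred


class TestConfusion:
    def test_perfect_predictions(self):
        cm = confusion_and_accuracy(["a", "b", "a"], ["a", "b", "a"])
        assert cm.overall_accuracy == 1.0
        assert np.all(cm.counts == np.array([[2, 0], [0, 1]]))

    def test_monitoring_confusion_per_class_accuracy(self):
        # a binary season where 40 of 656 target calls are recovered and
        # 6 of 11031 negatives leak through
        y_true, y_pred = expand_counts(tp=40, fn=616, fp=6, tn=11025)
        cm = confusion_and_accuracy(y_true, y_pred, labels=["WTSP", "OTHER"])
        per_class = cm.per_class_accuracy()
        np.testing.assert_allclose(per_class["WTSP"], 40 / 656, atol=1e-12)
        assert cm.total == 11687

    def test_all_negative_predictor_accuracy(self):
        # heavy imbalance: predicting the majority class alone scores 94.4%
        y_true, y_pred = expand_counts(tp=0, fn=656, fp=0, tn=11031)
        cm = confusion_and_accuracy(y_true, y_pred, labels=["WTSP", "OTHER"])
        assert round(100 * cm.overall_accuracy, 1) == 94.4

    def test_accuracy_equals_trace_over_total(self):
        gen = np.random.default_rng(0)
        y_true = gen.integers(0, 4, 200)
        y_pred = gen.integers(0, 4, 200)
        cm = confusion_and_accuracy(y_true, y_pred)
        assert cm.overall_accuracy == np.trace(cm.counts) / cm.counts.sum()
        assert cm.overall_accuracy == np.mean(y_true == y_pred)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_and_accuracy([], [])


def brute_force_curves(scores, y):
    """Exhaustive threshold enumeration oracle for ROC and PR points."""
    scores = np.asarray(scores, float)
    y = np.asarray(y, int)
    pts = []
    for t in np.unique(scores):
        pred = scores >= t
        tp = np.sum(pred & (y == 1))
        fp = np.sum(pred & (y == 0))
        fn = np.sum(~pred & (y == 1))
        tn = np.sum(~pred & (y == 0))
        pts.append((t, fp / (fp + tn), tp / (tp + fn), tp / max(tp + fp, 1)))
    return pts


class TestCurves:
    def test_perfect_scores_auc_one(self):
        y = [0, 0, 1, 1]
        assert roc([0.0, 0.0, 1.0, 1.0], y).auc == 1.0

    def test_random_scores_auc_near_half(self):
        gen = np.random.default_rng(1)
        y = gen.integers(0, 2, 4000)
        scores = gen.random(4000)
        assert abs(roc(scores, y).auc - 0.5) < 0.03

    def test_toy_curves_match_exhaustive_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        y = [0, 0, 1, 1]
        roc_res = roc(scores, y)
        pr_res = pr(scores, y)
        for t, fpr, tpr, precision in brute_force_curves(scores, y):
            # every enumerated operating point appears on both curves
            on_roc = np.isclose(roc_res.x, fpr) & np.isclose(roc_res.y, tpr)
            assert on_roc.any()
            on_pr = np.isclose(pr_res.x, tpr) & np.isclose(pr_res.y, precision)
            assert on_pr.any()

    def test_roc_monotone_and_auc_in_range(self):
        gen = np.random.default_rng(2)
        y = gen.integers(0, 2, 50)
        res = roc(gen.random(50), y)
        assert np.all(np.diff(res.x) >= 0)
        assert np.all(np.diff(res.y) >= 0)
        assert 0.0 <= res.auc <= 1.0

    def test_pr_endpoint_is_prevalence(self):
        gen = np.random.default_rng(3)
        y = (gen.random(200) < 0.3).astype(int)
        res = pr(gen.random(200), y)
        # most permissive threshold: recall 1, precision = prevalence
        assert res.x[0] == 1.0
        np.testing.assert_allclose(res.y[0], y.mean(), atol=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            pr([0.1, 0.2], [0, 0])


class TestThreshold:
    def test_default_is_half(self):
        assert select_threshold(mode="default") == 0.5

    def test_separated_scores_reach_f1_one(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        y = [0, 0, 1, 1]
        t = select_threshold(scores, y, mode="f1_train")
        assert f1_at_threshold(scores, y, t) == 1.0

    def test_matches_exhaustive_search(self):
        scores = [0.15, 0.3, 0.45, 0.55, 0.7, 0.95]
        y = [0, 1, 0, 1, 1, 1]
        t = select_threshold(scores, y, mode="oracle")
        best = max(
            f1_at_threshold(scores, y, c)
            for c in list(scores) + [0.0, 1.0]
        )
        assert f1_at_threshold(scores, y, t) == best

    def test_no_positives_errors(self):
        with pytest.raises(ValueError, match="positive"):
            select_threshold([0.1, 0.2], [0, 0], mode="f1_train")

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError):
            select_threshold([0.5], [1], mode="f2")


class TestDetectionCurves:
    def _season(self):
        ts = (
            ["2015-04-01T22:10:00"] * 3
            + ["2015-04-02T01:00:00"] * 2
            + ["2015-04-04T23:30:00"] * 4
        )
        probs = [0.9, 0.2, 0.7, 0.95, 0.1, 0.8, 0.85, 0.3, 0.6]
        labels = ["T", "O", "T", "T", "O", "T", "T", "O", "T"]
        return ts, probs, labels

    def test_threshold_zero_counts_everything(self):
        ts, probs, _ = self._season()
        curve = detection_histogram(ts, probabilities=probs, threshold=0.0)
        assert curve.counts.sum() == len(ts)
        assert len(curve.dates) == 4  # Apr 1-4 inclusive, gap filled with 0
        assert curve.counts[2] == 0

    def test_threshold_above_one_counts_nothing(self):
        ts, probs, _ = self._season()
        curve = detection_histogram(
            ts, probabilities=probs, threshold=1.01, date_range=("2015-04-01", "2015-04-04")
        )
        assert curve.counts.sum() == 0

    def test_reference_curve_conserves_positives(self):
        ts, _, labels = self._season()
        ref = detection_histogram(ts, labels=labels, positive_label="T")
        assert ref.counts.sum() == labels.count("T")
        assert ref.source == "reference"

    def test_missing_timestamps_name_clips(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            detection_histogram(["2015-04-01", None], probabilities=[0.9, 0.9])

    def test_identical_curves_r_one(self):
        ts, probs, _ = self._season()
        a = detection_histogram(ts, probabilities=probs, threshold=0.5)
        r, p, df = curve_correlation(a, a)
        np.testing.assert_allclose(r, 1.0)
        assert df == len(a.dates) - 2

    def test_negated_curve_r_minus_one(self):
        dates = pd.date_range("2015-04-01", periods=5)
        from flightcall.evaluation import DetectionCurve

        a = DetectionCurve(dates=dates, counts=np.array([1, 3, 5, 2, 0]))
        b = DetectionCurve(dates=dates, counts=-np.array([1, 3, 5, 2, 0]) + 5)
        r, _, _ = curve_correlation(a, b)
        np.testing.assert_allclose(r, -1.0)

    def test_correlation_matches_textbook_formula(self):
        gen = np.random.default_rng(4)
        dates = pd.date_range("2015-04-01", periods=57)
        from flightcall.evaluation import DetectionCurve

        x = gen.poisson(5, 57).astype(float)
        y = x + gen.normal(0, 2, 57)
        a = DetectionCurve(dates=dates, counts=x)
        b = DetectionCurve(dates=dates, counts=y)
        r, _, df = curve_correlation(a, b)
        manual = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        np.testing.assert_allclose(r, manual, atol=1e-12)
        assert df == 55

    def test_zero_variance_curve_errors(self):
        dates = pd.date_range("2015-04-01", periods=3)
        from flightcall.evaluation import DetectionCurve

        a = DetectionCurve(dates=dates, counts=np.array([1.0, 1, 1]))
        b = DetectionCurve(dates=dates, counts=np.array([1.0, 2, 3]))
        with pytest.raises(ValueError, match="zero-variance"):
            curve_correlation(a, b)


class TestSNR:
    def _tone_burst(self, ratio_db):
        """1 s 5 kHz tone whose central 150 ms is boosted by ratio_db."""
        sr = 22050
        t = np.arange(sr) / sr
        x = np.sin(2 * np.pi * 5000 * t)
        gain = np.ones(sr)
        mid = slice(int(0.425 * sr), int(0.575 * sr))
        gain[mid] = 10 ** (ratio_db / 20.0)
        return AudioClip(0.05 * x * gain, sr)

    def test_equal_energy_gives_zero_db(self):
        rec = estimate_snr(self._tone_burst(0.0))
        assert abs(rec.snr_db) < 0.3

    def test_ten_times_power_gives_ten_db(self):
        rec = estimate_snr(self._tone_burst(10.0))
        assert abs(rec.snr_db - 10.0) < 0.5

    def test_scale_invariance(self, call_scene):
        a = estimate_snr(call_scene)
        b = estimate_snr(call_scene.scaled(7.3))
        np.testing.assert_allclose(a.snr_db, b.snr_db, atol=1e-9)

    def test_methods_agree_roughly(self, call_scene):
        a = estimate_snr(call_scene, method="stft")
        b = estimate_snr(call_scene, method="bandpass")
        assert abs(a.snr_db - b.snr_db) < 2.0

    def test_short_clip_errors(self):
        with pytest.raises(ValueError, match="short"):
            estimate_snr(AudioClip(np.ones(2205), 22050))  # 100 ms

    def test_silent_clip_errors(self):
        with pytest.raises(ValueError, match="[Ss]ilent"):
            estimate_snr(AudioClip(np.zeros(22050), 22050))

    def test_closed_loop_with_generator(self):
        # the mixer calibrates background gain against this estimator;
        # requested and measured values must agree within 0.5 dB
        call = synth_call(ARCHETYPES["dsw"], seed=3)
        for target in (1.0, 5.0, 10.0, 20.0, 30.0):
            scene = mix_scene(call, SceneSpec(background="wind", snr_db=target, seed=11))
            rec = estimate_snr(scene)
            assert abs(rec.snr_db - target) <= 0.5, target


class TestSNRAnalysis:
    @staticmethod
    def records(tp_snr, fn_snr, confidences=None):
        recs = [SNRRecord(None, 1, 1, s, outcome="TP") for s in tp_snr]
        recs += [SNRRecord(None, 1, 1, s, outcome="FN") for s in fn_snr]
        if confidences is not None:
            for r, c in zip(recs, confidences):
                r.confidence = c
        return recs

    def test_identical_groups_ks_zero(self):
        snr = list(np.linspace(0, 10, 20))
        res = snr_error_analysis(self.records(snr, snr, confidences=np.linspace(0, 1, 40)))
        assert res.ks_statistic == 0.0

    def test_disjoint_groups_ks_one(self):
        res = snr_error_analysis(
            self.records([10, 11, 12], [0, 1, 2], confidences=[0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        )
        assert res.ks_statistic == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            snr_error_analysis(self.records([1.0, 2.0], []))

    def test_correlation_df(self):
        gen = np.random.default_rng(5)
        snr = gen.normal(5, 2, 30)
        conf = 0.5 + 0.04 * snr + gen.normal(0, 0.05, 30)
        recs = self.records(snr[:20], snr[20:], confidences=conf)
        res = snr_error_analysis(recs)
        assert res.df == 28
        assert res.pearson_r > 0
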