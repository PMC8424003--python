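"""Confusion metrics, sample remapping, episode extraction, EC57 scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecmaf.af_eval import (
    ConfusionCounts, Episode, brief_episode_sensitivity, classification_metrics,
    confusion_from_labels, ec57_metrics, episodes_from_labels, remap_to_samples,
)
from ecmaf.ecg_core import AF, NONAF
from ecmaf.ecm_builder import ECMWindow


def _window(lo, hi):
    return ECMWindow("r", 0, np.linspace(lo + 250, hi - 1250, 10).astype(int), lo, hi)


class TestClassificationMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = classification_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_worked_example(self):
        m = classification_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m["Acc"] == pytest.approx(0.700, abs=5e-4)
        assert m["Se"] == pytest.approx(0.600, abs=5e-4)
        assert m["Sp"] == pytest.approx(0.800, abs=5e-4)
        assert m["PPV"] == pytest.approx(0.750, abs=5e-4)
        assert m["F1"] == pytest.approx(0.6667, abs=5e-4)
        assert m["Mcc_norm"] == pytest.approx(0.7041, abs=5e-4)

    def test_exhaustive_against_sklearn_oracle(self):
        """All tables with counts in 0..6 match an independent implementation."""
        from sklearn.metrics import (
            accuracy_score, f1_score, matthews_corrcoef, precision_score,
            recall_score,
        )

        for tp in range(7):
            for tn in range(7):
                for fp in range(7):
                    for fn in range(7):
                        if tp + tn + fp + fn == 0:
                            continue
                        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
                        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
                        m = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
                        assert m["Acc"] == pytest.approx(accuracy_score(y_true, y_pred))
                        if tp + fn:
                            assert m["Se"] == pytest.approx(
                                recall_score(y_true, y_pred, zero_division=0))
                        if tp + fp:
                            assert m["PPV"] == pytest.approx(
                                precision_score(y_true, y_pred, zero_division=0))
                        if 2 * tp + fp + fn:
                            assert m["F1"] == pytest.approx(
                                f1_score(y_true, y_pred, zero_division=0))
                        mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
                        if mcc_den:
                            assert m["Mcc_norm"] == pytest.approx(
                                (matthews_corrcoef(y_true, y_pred) + 1) / 2)
                        else:
                            assert math.isnan(m["Mcc_norm"])

    def test_f1_is_harmonic_mean_of_ppv_and_se(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            m = classification_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            harm = 2 * m["PPV"] * m["Se"] / (m["PPV"] + m["Se"])
            assert m["F1"] == pytest.approx(harm)

    def test_class_swap_changes_f1_but_not_acc_or_mcc(self):
        a = classification_metrics(ConfusionCounts(TP=3, TN=40, FP=5, FN=2))
        b = classification_metrics(ConfusionCounts(TP=40, TN=3, FP=2, FN=5))
        assert a["Acc"] == pytest.approx(b["Acc"])
        assert a["Mcc_norm"] == pytest.approx(b["Mcc_norm"])
        assert a["F1"] != pytest.approx(b["F1"])

    def test_one_class_input_yields_undefined_not_zero(self):
        m = classification_metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert math.isnan(m["Se"])
        assert math.isnan(m["PPV"])
        assert math.isnan(m["Mcc_norm"])
        assert m["Acc"] == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestRemap:
    def test_single_af_window(self):
        stream = remap_to_samples([(_window(100, 5100), AF)], 10000)
        assert stream[100:5100].all()
        assert not stream[:100].any() and not stream[5100:].any()

    def test_overlap_priority_is_af(self):
        decisions = [(_window(0, 6000), NONAF), (_window(3000, 9000), AF)]
        stream = remap_to_samples(decisions, 10000)
        assert stream[3000:9000].all()
        assert not stream[:3000].any()

    def test_no_windows_all_nonaf(self):
        assert not remap_to_samples([], 1000).any()


class TestEpisodes:
    @pytest.mark.parametrize("bits,expected", [
        ("000111100", [(3, 7)]),
        ("000000000", []),
        ("101", [(0, 1), (2, 3)]),
        ("111", [(0, 3)]),
    ])
    def test_maximal_runs(self, bits, expected):
        stream = np.array([c == "1" for c in bits])
        assert [(e.onset, e.offset) for e in episodes_from_labels(stream)] == expected

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.booleans(), min_size=0, max_size=64))
    def test_episodes_partition_af_samples(self, bits):
        stream = np.array(bits, dtype=bool)
        eps = episodes_from_labels(stream)
        rebuilt = np.zeros_like(stream)
        for e in eps:
            assert e.onset < e.offset
            assert not rebuilt[e.onset:e.offset].any()  # non-overlapping
            rebuilt[e.onset:e.offset] = True
        assert np.array_equal(rebuilt, stream)
        # maximality: neighbors of every episode are non-AF
        for e in eps:
            if e.onset > 0:
                assert not stream[e.onset - 1]
            if e.offset < len(stream):
                assert not stream[e.offset]


class TestEC57:
    def test_worked_example(self):
        fs = 1.0
        truth = [Episode(10, 20), Episode(30, 40)]
        det = [Episode(12, 18)]
        m = ec57_metrics(truth, det, fs)
        assert m["Se_Epi"] == pytest.approx(0.5)
        assert m["PPV_Epi"] == pytest.approx(1.0)
        assert m["Se_Dur"] == pytest.approx(0.30)
        assert m["PPV_Dur"] == pytest.approx(1.0)

    def test_perfect_detection(self):
        truth = [Episode(10, 20), Episode(50, 80)]
        m = ec57_metrics(truth, list(truth), 2.0)
        assert all(v == pytest.approx(1.0) for v in m.values())

    def test_disjoint_detection_scores_zero(self):
        m = ec57_metrics([Episode(0, 10)], [Episode(20, 30)], 1.0)
        assert all(v == pytest.approx(0.0) for v in m.values())

    def test_empty_truth_or_detection_yields_undefined(self):
        m = ec57_metrics([], [Episode(0, 5)], 1.0)
        assert math.isnan(m["Se_Epi"]) and math.isnan(m["Se_Dur"])
        m = ec57_metrics([Episode(0, 5)], [], 1.0)
        assert math.isnan(m["PPV_Epi"]) and math.isnan(m["PPV_Dur"])

    def test_1000_random_configs_match_per_sample_oracle(self):
        """Interval arithmetic agrees with a brute-force boolean-array oracle."""
        from scipy import ndimage

        rng = np.random.default_rng(20260929)
        n = 2000
        for _ in range(1000):
            truth_arr = np.zeros(n, dtype=bool)
            det_arr = np.zeros(n, dtype=bool)
            for arr in (truth_arr, det_arr):
                for _ in range(rng.integers(0, 6)):
                    lo = int(rng.integers(0, n - 1))
                    hi = int(rng.integers(lo + 1, min(lo + 400, n) + 1))
                    arr[lo:hi] = True
            truth = episodes_from_labels(truth_arr)
            det = episodes_from_labels(det_arr)
            m = ec57_metrics(truth, det, fs=1.0)

            # oracle: label connected runs, test overlap per run, count samples
            t_lab, t_n = ndimage.label(truth_arr)
            d_lab, d_n = ndimage.label(det_arr)
            tp_epi = sum(
                1 for i in range(1, t_n + 1) if det_arr[t_lab == i].any()
            )
            fp_epi = sum(
                1 for j in range(1, d_n + 1) if not truth_arr[d_lab == j].any()
            )
            inter = int((truth_arr & det_arr).sum())
            if t_n:
                assert m["Se_Epi"] == pytest.approx(tp_epi / t_n)
                assert m["Se_Dur"] == pytest.approx(inter / truth_arr.sum())
            else:
                assert math.isnan(m["Se_Epi"])
            if d_n:
                assert m["PPV_Epi"] == pytest.approx(tp_epi / (tp_epi + fp_epi))
                assert m["PPV_Dur"] == pytest.approx(inter / det_arr.sum())
            else:
                assert math.isnan(m["PPV_Epi"])

    def test_se_dur_equals_window_se_for_tiling_equal_windows(self):
        """With equal-length windows tiling the record, duration sensitivity
        coincides with window-level sensitivity."""
        fs = 500.0
        wlen = 5000
        truth_labels = np.array([AF, NONAF, AF, AF, NONAF, AF])
        pred_labels = np.array([AF, NONAF, NONAF, AF, AF, AF])
        windows = [_window(i * wlen, (i + 1) * wlen) for i in range(6)]
        truth_stream = remap_to_samples(
            [(w, l) for w, l in zip(windows, truth_labels)], 6 * wlen)
        pred_stream = remap_to_samples(
            [(w, l) for w, l in zip(windows, pred_labels)], 6 * wlen)
        m = ec57_metrics(
            episodes_from_labels(truth_stream), episodes_from_labels(pred_stream), fs)
        conf = confusion_from_labels(truth_labels, pred_labels)
        window_se = conf.TP / (conf.TP + conf.FN)
        assert m["Se_Dur"] == pytest.approx(window_se)


class TestBriefEpisodes:
    def test_short_detected_long_missed(self):
        fs = 1.0
        truth = [Episode(0, 5), Episode(100, 125)]  # 5 s and 25 s
        det = [Episode(2, 4)]
        rows = {r["threshold_s"]: r for r in brief_episode_sensitivity(truth, det, fs)}
        assert rows[10.0]["Se_Epi"] == pytest.approx(1.0)
        assert rows[30.0]["Se_Epi"] == pytest.approx(0.5)
        assert rows[math.inf]["Se_Epi"] == pytest.approx(0.5)

    def test_bin_counts_are_cumulative(self):
        rng = np.random.default_rng(5)
        truth = []
        t = 0
        for _ in range(30):
            dur = int(rng.integers(2, 200))
            truth.append(Episode(t, t + dur))
            t += dur + 10
        rows = brief_episode_sensitivity(truth, [], fs=1.0)
        counts = [r["n_episodes"] for r in rows]
        assert counts == sorted(counts)
        assert counts[-1] == len(truth)

    def test_empty_bin_is_undefined(self):
        rows = brief_episode_sensitivity([Episode(0, 50)], [], fs=1.0)
        assert math.isnan(rows[0]["Se_Epi"])  # no episode shorter than 10 s
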