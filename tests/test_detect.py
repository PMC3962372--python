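"""Class decoding, the 5-consecutive-sample rule, outcome scoring, metrics."""

import numpy as np
import pytest

import fallseg as fs
from fallseg.detect import (
    CLS_NA,
    CLS_P,
    CLS_W,
    ClassSequence,
    DetectionOutcome,
    outcomes_to_frame,
    report_to_frame,
)


def _seq(classes, fs_hz=100.0, onset=500):
    return ClassSequence(classes=np.asarray(classes), fs=fs_hz, onset_index=onset)


def _brute_force_runs(classes, run_length):
    """Oracle: scan all windows, then keep one detection per maximal run."""
    det = []
    n = len(classes)
    for i in range(n - run_length + 1):
        window_all_p = all(classes[i + k] == CLS_P for k in range(run_length))
        run_start = i == 0 or classes[i - 1] != CLS_P
        if window_all_p and run_start:
            det.append(i + run_length - 1)
    return det


class TestDecodeClasses:
    def test_clear_one_hot(self):
        raw = np.array([[0.9, -0.9], [-0.9, 0.9]])
        seq = fs.decode_classes(raw, 100.0, 500)
        assert list(seq.classes) == [CLS_W, CLS_P]

    def test_below_threshold_is_uncertain(self):
        seq = fs.decode_classes(np.array([[0.3], [0.2]]), 100.0, 500)
        assert seq.classes[0] == CLS_NA

    def test_exact_tie_is_uncertain(self):
        seq = fs.decode_classes(np.array([[0.7], [0.7]]), 100.0, 500)
        assert seq.classes[0] == CLS_NA

    def test_threshold_is_inclusive(self):
        seq = fs.decode_classes(np.array([[0.5], [-0.5]]), 100.0, 500)
        assert seq.classes[0] == CLS_W

    def test_class_names(self):
        seq = _seq([CLS_W, CLS_P, CLS_NA])
        assert list(seq.names()) == ["W", "P", "NA"]

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            fs.decode_classes(np.zeros((3, 5)), 100.0, 500)


class TestDetectRuns:
    def test_all_walking_no_detection(self):
        assert fs.detect_runs(_seq([CLS_W] * 600)) == []

    def test_four_consecutive_not_enough(self):
        classes = [CLS_W] * 600
        classes[10:14] = [CLS_P] * 4
        assert fs.detect_runs(_seq(classes)) == []

    def test_detection_at_fifth_sample(self):
        classes = [CLS_W] * 600
        classes[520:531] = [CLS_P] * 11
        assert fs.detect_runs(_seq(classes)) == [524]

    def test_uncertainty_breaks_a_run(self):
        classes = [CLS_W] * 600
        classes[100:109] = [CLS_P] * 9
        classes[104] = CLS_NA
        assert fs.detect_runs(_seq(classes)) == []

    def test_one_detection_per_maximal_run(self):
        classes = [CLS_W] * 600
        classes[10:30] = [CLS_P] * 20
        classes[40:45] = [CLS_P] * 5
        assert fs.detect_runs(_seq(classes)) == [14, 44]

    def test_brute_force_oracle(self, rng):
        for _ in range(300):
            classes = rng.choice([CLS_W, CLS_P, CLS_NA], size=120,
                                 p=[0.35, 0.5, 0.15])
            seq = _seq(classes, onset=60)
            assert fs.detect_runs(seq) == _brute_force_runs(classes, 5)

    def test_monotone_in_p_samples(self, rng):
        # promoting a W/NA sample to P never loses the ability to detect,
        # and never delays the first detection
        for _ in range(100):
            classes = rng.choice([CLS_W, CLS_P, CLS_NA], size=80,
                                 p=[0.3, 0.55, 0.15])
            before = fs.detect_runs(_seq(classes, onset=40))
            non_p = np.flatnonzero(classes != CLS_P)
            if non_p.size == 0:
                continue
            flipped = classes.copy()
            flipped[rng.choice(non_p)] = CLS_P
            after = fs.detect_runs(_seq(flipped, onset=40))
            if before:
                assert after and min(after) <= min(before)


class TestLabelOutcome:
    def test_post_onset_detection_time(self):
        out = fs.label_outcome(_seq([CLS_W] * 600), [524])
        assert out.pp_outcome == "TP" and out.wp_outcome == "TN"
        assert out.detection_time == pytest.approx(0.25)   # (524-500+1)/100

    def test_pre_onset_only_is_false_positive_and_miss(self):
        out = fs.label_outcome(_seq([CLS_W] * 600), [100])
        assert out.pp_outcome == "FN" and out.wp_outcome == "FP"
        assert out.detection_time is None

    def test_no_detection(self):
        out = fs.label_outcome(_seq([CLS_W] * 600), [])
        assert out.pp_outcome == "FN" and out.wp_outcome == "TN"

    def test_first_post_onset_detection_defines_dt(self):
        out = fs.label_outcome(_seq([CLS_W] * 600), [560, 510, 590])
        assert out.detection_index == 510
        assert out.detection_time == pytest.approx(0.11)

    def test_straddling_run_assigned_by_fifth_sample(self):
        # P run over samples 498..504: the 5th sample (502) is post-onset,
        # so the run scores TP, not FP
        classes = [CLS_W] * 600
        classes[498:505] = [CLS_P] * 7
        seq = _seq(classes)
        out = fs.label_outcome(seq, fs.detect_runs(seq))
        assert out.pp_outcome == "TP" and out.wp_outcome == "TN"
        assert out.detection_index == 502

    def test_outcome_invariants_enforced(self):
        with pytest.raises(ValueError):
            DetectionOutcome(pp_outcome="FN", wp_outcome="TN", detection_time=0.1)
        with pytest.raises(ValueError):
            DetectionOutcome(pp_outcome="TP", wp_outcome="TN", detection_time=None)


def _make_outcomes(tp, fn, fp, dt=0.3, ptype=None):
    """tp clean hits, fn clean misses, fp missed-and-false-alarm trials."""
    out = []
    for _ in range(tp):
        out.append(DetectionOutcome("TP", "TN", dt, int(500 + dt * 100) - 1, ptype))
    for _ in range(fn):
        out.append(DetectionOutcome("FN", "TN", ptype=ptype))
    for _ in range(fp):
        out.append(DetectionOutcome("FN", "FP", ptype=ptype))
    return out


class TestAggregate:
    def test_direct_formulas(self):
        outcomes = ([DetectionOutcome("TP", "TN", 0.3, 529)] * 3
                    + [DetectionOutcome("FN", "TN")])
        report = fs.aggregate(outcomes)
        assert (report.tp, report.fn, report.tn, report.fp) == (3, 1, 4, 0)
        assert report.sensitivity == pytest.approx(0.75)
        assert report.specificity == pytest.approx(1.0)
        assert report.accuracy == pytest.approx(0.875)

    def test_balanced_accuracy_from_rates(self):
        # full-body operating point: 92.7 % / 98.0 % -> 95.4 % accuracy
        outcomes = ([DetectionOutcome("TP", "TN", 0.35, 534)] * 927
                    + [DetectionOutcome("FN", "TN")] * 53
                    + [DetectionOutcome("FN", "FP")] * 20)
        report = fs.aggregate(outcomes)
        assert report.sensitivity == pytest.approx(0.927)
        assert report.specificity == pytest.approx(0.980)
        assert abs(100 * report.accuracy - 95.4) <= 0.05 + 1e-9  # one-decimal agreement

    def test_constant_detection_times(self):
        outcomes = [DetectionOutcome("TP", "TN", 0.3, 529)] * 5
        report = fs.aggregate(outcomes)
        assert report.mdt_mean == pytest.approx(0.300)
        assert report.mdt_sd == pytest.approx(0.0)

    def test_no_true_positive_mdt_undefined(self):
        report = fs.aggregate([DetectionOutcome("FN", "TN")] * 3)
        assert report.mdt_mean is None and report.mdt_sd is None
        assert report.sensitivity == 0.0 and report.specificity == 1.0

    def test_breakdown_by_perturbation_type(self):
        outcomes = (_make_outcomes(2, 0, 0, dt=0.2, ptype="NE")
                    + _make_outcomes(1, 1, 1, dt=0.4, ptype="SW"))
        report = fs.aggregate(outcomes)
        assert set(report.by_type) == {"NE", "SW"}
        assert report.by_type["NE"].sensitivity == 1.0
        assert report.by_type["SW"].mdt_mean == pytest.approx(0.4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fs.aggregate([])

    def test_tables(self):
        outcomes = _make_outcomes(2, 1, 0, ptype="E")
        report = fs.aggregate(outcomes, combination="F")
        df = report_to_frame({"F": report})
        assert df.loc[0, "combination"] == "F"
        assert df.loc[0, "sensitivity_pct"] == pytest.approx(100 * 2 / 3)
        per_trial = outcomes_to_frame(outcomes)
        assert len(per_trial) == len(outcomes)

    def test_json_writer(self, tmp_path):
        report = fs.aggregate(_make_outcomes(1, 0, 0, ptype="NE"))
        report.to_json(tmp_path / "r.json")
        import json
        raw = json.loads((tmp_path / "r.json").read_text())
        assert raw["tp"] == 1 and "by_type" in raw
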