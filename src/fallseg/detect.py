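"""Per-sample class decoding, the consecutive-sample detection rule, and
performance aggregation.

Network outputs are decoded sample-by-sample into walking (W), perturbation
(P) or uncertainty (NA) with a 0.5 activity threshold. A perturbation is
*detected* when 5 consecutive samples are classified P; a detection is
registered at the 5th sample of the run, so a run straddling the onset is
attributed to whichever phase that 5th sample falls in. Each classified trial
contributes one outcome per phase — TP/FN for the post-onset perturbation
phase, TN/FP for the pre-onset walking phase — and, for true positives, the
detection time from onset to the registering sample (inclusive). Performance
is summarised as sensitivity, specificity and their mean (balanced accuracy),
plus the mean +- SD detection time over true positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CLS_W, CLS_P, CLS_NA = 0, 1, 2
CLASS_NAMES = ("W", "P", "NA")

RUN_LENGTH_DEFAULT = 5
THRESHOLD_DEFAULT = 0.5


@dataclass
class ClassSequence:
    """Per-sample decoded classes of one trial window."""

    classes: np.ndarray            # int array over {CLS_W, CLS_P, CLS_NA}
    fs: float
    onset_index: int

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 1:
            raise ValueError("classes must be a 1-D vector")

    def names(self) -> np.ndarray:
        return np.array(CLASS_NAMES, dtype=object)[self.classes]


@dataclass
class DetectionOutcome:
    """Per-trial, per-phase scoring of one classified trial."""

    pp_outcome: str                       # "TP" or "FN"
    wp_outcome: str                       # "TN" or "FP"
    detection_time: float | None = None   # s, present iff TP
    detection_index: int | None = None
    ptype: str | None = None              # perturbation code, for breakdowns

    def __post_init__(self) -> None:
        if self.pp_outcome not in ("TP", "FN") or self.wp_outcome not in ("TN", "FP"):
            raise ValueError("invalid outcome labels")
        if (self.detection_time is not None) != (self.pp_outcome == "TP"):
            raise ValueError("detection_time present iff TP")
        if self.detection_time is not None and self.detection_time < 0:
            raise ValueError("detection_time must be >= 0")


def decode_classes(raw: np.ndarray, fs: float, onset_index: int,
                   threshold: float = THRESHOLD_DEFAULT) -> ClassSequence:
    """Decode [2 x T] network outputs into W/P/NA per sample.

    A sample gets the arg-max unit's class if that unit's activity reaches
    the threshold; exact ties between the two units, or neither unit reaching
    the threshold, give NA (uncertainty).
    """
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.shape[0] != 2:
        raise ValueError("raw outputs must be [2 x T]")
    top = raw.max(axis=0)
    classes = np.where(raw[1] > raw[0], CLS_P, CLS_W)
    classes = np.where((top < threshold) | (raw[0] == raw[1]), CLS_NA, classes)
    return ClassSequence(classes=classes, fs=fs, onset_index=onset_index)


def detect_runs(seq: ClassSequence,
                run_length: int = RUN_LENGTH_DEFAULT) -> list[int]:
    """Detection indices: the run_length-th sample of each maximal P run.

    Any non-P sample (W or NA) breaks a run; each maximal run of at least
    ``run_length`` consecutive P samples yields exactly one detection.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    is_p = np.concatenate([[False], seq.classes == CLS_P, [False]])
    edges = np.flatnonzero(np.diff(is_p.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]      # runs are [start, end)
    return [int(s + run_length - 1) for s, e in zip(starts, ends)
            if e - s >= run_length]


def label_outcome(seq: ClassSequence, detections: list[int],
                  ptype: str | None = None) -> DetectionOutcome:
    """Score one trial's detections against its perturbation onset.

    Detections before the onset make the walking phase a false positive;
    detections at or after it make the perturbation phase a true positive,
    with the detection time measured to the end of the registering sample
    ((index - onset + 1) / fs), from the first post-onset detection only.
    """
    pre = [d for d in detections if d < seq.onset_index]
    post = [d for d in detections if d >= seq.onset_index]
    wp = "FP" if pre else "TN"
    if post:
        first = min(post)
        dt = (first - seq.onset_index + 1) / seq.fs
        return DetectionOutcome(pp_outcome="TP", wp_outcome=wp,
                                detection_time=dt, detection_index=first,
                                ptype=ptype)
    return DetectionOutcome(pp_outcome="FN", wp_outcome=wp, ptype=ptype)


def classify_trial(raw: np.ndarray, fs: float, onset_index: int,
                   ptype: str | None = None,
                   threshold: float = THRESHOLD_DEFAULT,
                   run_length: int = RUN_LENGTH_DEFAULT) -> DetectionOutcome:
    """decode -> detect -> score, for one trial's raw network outputs."""
    seq = decode_classes(raw, fs, onset_index, threshold)
    return label_outcome(seq, detect_runs(seq, run_length), ptype)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity."""
    return 0.5 * (sensitivity + specificity)


@dataclass
class PerformanceReport:
    """Aggregated counts and metrics over a set of trial outcomes.

    Metrics with a zero denominator are ``None`` (undefined), never silently
    zero. ``by_type`` holds one sub-report per perturbation code when outcome
    metadata allows it.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    mdt_mean: float | None
    mdt_sd: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    n_outcomes: int
    by_type: dict[str, "PerformanceReport"] = field(default_factory=dict)
    combination: str | None = None

    def to_dict(self, include_breakdown: bool = True) -> dict:
        d = {k: getattr(self, k) for k in
             ("combination", "tp", "fp", "tn", "fn", "mdt_mean", "mdt_sd",
              "sensitivity", "specificity", "accuracy", "n_outcomes")}
        if include_breakdown and self.by_type:
            d["by_type"] = {k: v.to_dict(False) for k, v in self.by_type.items()}
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def aggregate(outcomes: list[DetectionOutcome],
              combination: str | None = None,
              _breakdown: bool = True) -> PerformanceReport:
    """Sum outcome counts and compute MDT, sensitivity, specificity, accuracy.

    Sensitivity = TP/(TP+FN) over perturbation-phase outcomes, specificity =
    TN/(TN+FP) over walking-phase outcomes, accuracy = their mean. MDT is the
    mean (+- sample SD) of true-positive detection times.
    """
    if not outcomes:
        raise ValueError("no outcomes to aggregate")
    tp = sum(o.pp_outcome == "TP" for o in outcomes)
    fn = sum(o.pp_outcome == "FN" for o in outcomes)
    fp = sum(o.wp_outcome == "FP" for o in outcomes)
    tn = sum(o.wp_outcome == "TN" for o in outcomes)
    dts = np.array([o.detection_time for o in outcomes
                    if o.detection_time is not None])
    mdt = float(dts.mean()) if dts.size else None
    mdt_sd = float(dts.std(ddof=1)) if dts.size > 1 else (0.0 if dts.size else None)
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    acc = balanced_accuracy(sens, spec) if sens is not None and spec is not None else None
    report = PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn,
                               mdt_mean=mdt, mdt_sd=mdt_sd,
                               sensitivity=sens, specificity=spec, accuracy=acc,
                               n_outcomes=len(outcomes), combination=combination)
    if _breakdown:
        codes = sorted({o.ptype for o in outcomes if o.ptype is not None})
        for code in codes:
            sub = [o for o in outcomes if o.ptype == code]
            report.by_type[code] = aggregate(sub, combination, _breakdown=False)
    return report


def outcomes_to_frame(outcomes: list[DetectionOutcome]) -> pd.DataFrame:
    """Per-trial outcome table (one row per classified trial instance)."""
    return pd.DataFrame({
        "ptype": [o.ptype for o in outcomes],
        "pp_outcome": [o.pp_outcome for o in outcomes],
        "wp_outcome": [o.wp_outcome for o in outcomes],
        "detection_time": [o.detection_time for o in outcomes],
        "detection_index": [o.detection_index for o in outcomes],
    })


def report_to_frame(reports: dict[str, PerformanceReport]) -> pd.DataFrame:
    """Summary table (one row per segment combination), in percent and ms."""
    rows = []
    for name, r in reports.items():
        rows.append({
            "combination": name,
            "mdt_ms": None if r.mdt_mean is None else 1000.0 * r.mdt_mean,
            "mdt_sd_ms": None if r.mdt_sd is None else 1000.0 * r.mdt_sd,
            "sensitivity_pct": None if r.sensitivity is None else 100 * r.sensitivity,
            "specificity_pct": None if r.specificity is None else 100 * r.specificity,
            "accuracy_pct": None if r.accuracy is None else 100 * r.accuracy,
            "tp": r.tp, "fp": r.fp, "tn": r.tn, "fn": r.fn,
        })
    return pd.DataFrame(rows)
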