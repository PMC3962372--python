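"""Segment kinematics: CoM trajectories and global-frame accelerations.

Each of the 15 body segments is reduced to its centre of mass, located along
the proximal-to-distal axis at an anthropometric fraction of segment length
(Zatsiorsky's inertial parameters as adjusted by de Leva). CoM positions are
twice differentiated with three-point central differences to obtain linear
acceleration in the global frame; those 45 acceleration channels are the only
kinematic quantity the detection pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segments import AXES, CHANNELS, SEGMENTS
from .synth import PerturbationType, TrialWindow

#: longitudinal CoM position as a fraction of segment length from the
#: proximal endpoint (de Leva's adjusted male values; overridable)
DE_LEVA_COM_RATIO: dict[str, float] = {
    "HN": 0.5976,
    "T": 0.4502,    # mid-trunk portion
    "P": 0.6115,    # lower-trunk / pelvis portion
    "LA": 0.5772, "RA": 0.5772,
    "LFA": 0.4574, "RFA": 0.4574,
    "LH": 0.7900, "RH": 0.7900,
    "LT": 0.4095, "RT": 0.4095,
    "LS": 0.4459, "RS": 0.4459,
    "LF": 0.4415, "RF": 0.4415,
}


def validate_com_table(table: dict[str, float]) -> dict[str, float]:
    """Check a CoM-ratio table covers all 15 segments with ratios in (0, 1)."""
    missing = set(SEGMENTS) - set(table)
    if missing:
        raise ValueError(f"missing CoM ratios for {sorted(missing)}")
    for seg in SEGMENTS:
        if not 0.0 < table[seg] < 1.0:
            raise ValueError(f"CoM ratio for {seg} must lie in (0, 1)")
    return table


@dataclass
class SegmentTrajectory:
    """Proximal and distal endpoint positions of one segment, [T x 3] in m."""

    proximal: np.ndarray
    distal: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.proximal = np.atleast_2d(np.asarray(self.proximal, dtype=float))
        self.distal = np.atleast_2d(np.asarray(self.distal, dtype=float))
        if self.proximal.shape != self.distal.shape:
            raise ValueError("proximal and distal series must have equal shape")
        if self.proximal.shape[1] != 3:
            raise ValueError("positions must be [T x 3]")
        if len(self.proximal) < 3:
            raise ValueError("need at least 3 samples")
        if not (np.isfinite(self.proximal).all() and np.isfinite(self.distal).all()):
            raise ValueError("non-finite coordinates")


def segment_com(traj: SegmentTrajectory, ratio: float) -> np.ndarray:
    """CoM position series: proximal + ratio * (distal - proximal), per axis."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    return traj.proximal + ratio * (traj.distal - traj.proximal)


def central_diff_accel(pos: np.ndarray, fs: float) -> np.ndarray:
    """Second derivative of a position series by three-point central differences.

    a[t] = (pos[t+1] - 2 pos[t] + pos[t-1]) * fs^2 at interior samples; the two
    boundary samples replicate the nearest interior value so the output keeps
    the input length (and hence the label alignment of a 600-sample window).
    Exact for polynomials of degree <= 3; O((w/fs)^2) phase-free error on a
    sinusoid of angular frequency w.
    """
    pos = np.asarray(pos, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = pos.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    acc = np.empty_like(pos)
    acc[1:-1] = (pos[2:] - 2.0 * pos[1:-1] + pos[:-2]) * fs ** 2
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def com_accelerations(trajectories: dict[str, SegmentTrajectory],
                      ratios: dict[str, float] | None = None) -> np.ndarray:
    """[45 x T] global-frame CoM acceleration from per-segment endpoint series."""
    ratios = validate_com_table(dict(ratios) if ratios else DE_LEVA_COM_RATIO)
    missing = set(SEGMENTS) - set(trajectories)
    if missing:
        raise ValueError(f"missing trajectories for {sorted(missing)}")
    lengths = {len(trajectories[s].proximal) for s in SEGMENTS}
    if len(lengths) != 1:
        raise ValueError("all segment trajectories must have equal length")
    t_len = lengths.pop()
    out = np.empty((len(CHANNELS), t_len))
    for si, seg in enumerate(SEGMENTS):
        traj = trajectories[seg]
        com = segment_com(traj, ratios[seg])
        acc = central_diff_accel(com, traj.fs)   # [T x 3]
        out[si * 3:si * 3 + 3] = acc.T
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def assemble_dataset(trials: list[TrialWindow]) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Column-concatenate trials into the per-subject dataset matrix M.

    Returns ``(M, labels, channels)`` with M sized [45 x sum of samples]
    (45 x 12000 for the standard 20 trials of 600 samples), labels aligned
    column-for-column, and the channel -> (segment, axis) naming tuple.
    """
    if not trials:
        raise ValueError("no trials to assemble")
    n_samp = trials[0].n_samples
    for tr in trials:
        if tr.accel.shape[0] != len(CHANNELS):
            raise ValueError("inconsistent channel count across trials")
        if tr.n_samples != n_samp:
            raise ValueError("inconsistent sample count across trials")
    M = np.concatenate([tr.accel for tr in trials], axis=1)
    labels = np.concatenate([tr.label for tr in trials])
    return M, labels, CHANNELS


def split_dataset(M: np.ndarray, n_trials: int) -> list[np.ndarray]:
    """Inverse of :func:`assemble_dataset`: split M back into per-trial blocks."""
    if M.shape[1] % n_trials != 0:
        raise ValueError("column count not divisible by trial count")
    return [b for b in np.split(M, n_trials, axis=1)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_endpoint_csv(path: str | Path, fs: float) -> dict[str, SegmentTrajectory]:
    """Read endpoint trajectories from a CSV with ``<SEG>_prox_x`` .. columns."""
    df = pd.read_csv(path)
    out = {}
    for seg in SEGMENTS:
        prox = df[[f"{seg}_prox_{a}" for a in AXES]].to_numpy()
        dist = df[[f"{seg}_dist_{a}" for a in AXES]].to_numpy()
        out[seg] = SegmentTrajectory(prox, dist, fs)
    return out


def accel_to_trial(accel: np.ndarray, onset_index: int, fs: float,
                   ptype: PerturbationType, session: int = 1) -> TrialWindow:
    """Wrap a [45 x T] acceleration block into a labelled trial window."""
    n = accel.shape[1]
    label = np.array(["W"] * onset_index + ["P"] * (n - onset_index))
    return TrialWindow(accel=accel, onset_index=onset_index, fs=fs,
                       ptype=ptype, session=session, label=label)
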