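"""Synthetic treadmill-perturbation trials.

Generates per-subject sets of 6-s trial windows of 45-channel segment-CoM
acceleration (15 segments x 3 axes, 100 Hz): 5 s of steady walking followed
by 1 s of a slipping-perturbation response. The walking component is a
quasi-periodic sum of two harmonics of the step cadence with segment-specific
amplitudes (distal segments move more than proximal ones); the perturbation
response is an exponentially damped oscillation whose onset lag and amplitude
are segment-dependent (feet react first and hardest, the trunk later and less)
and whose sign pattern follows the belt-translation direction. Ten
perturbation types cover five belt directions delivered under either foot.

Everything is deterministic given the seeds; per-trial seeds are derived from
the subject's master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .segments import AXES, CHANNELS, SEGMENTS

# ---------------------------------------------------------------------------
# study-design constants
# ---------------------------------------------------------------------------

FS_DEFAULT = 100.0          # Hz
N_PRE = 500                 # walking-phase samples (5 s)
N_POST = 100                # perturbation-phase samples (1 s)
N_SAMPLES = N_PRE + N_POST
FROUDE_DEFAULT = 0.15
G = 9.81                    # m/s^2

#: the ten perturbation codes: five belt directions x two perturbed feet
PERTURBATION_CODES: tuple[str, ...] = (
    "NR", "NE", "E", "SE", "SR", "NL", "NW", "W", "SW", "SL"
)
_LEFT_CODES = frozenset({"NL", "NW", "W", "SW", "SL"})

#: paired codes share a belt direction, differing only in perturbed side
_DIRECTION = {
    "NL": "N", "NR": "N",
    "NW": "N-diag", "NE": "N-diag",
    "W": "transversal", "E": "transversal",
    "SW": "S-diag", "SE": "S-diag",
    "SL": "S", "SR": "S",
}

_SQ = np.sqrt(0.5)
#: (longitudinal, transversal) unit belt-translation vector per code
_DIR_VEC = {
    "NR": (1.0, 0.0), "NL": (1.0, 0.0),
    "NE": (_SQ, -_SQ), "NW": (_SQ, _SQ),
    "E": (0.0, -1.0), "W": (0.0, 1.0),
    "SE": (-_SQ, -_SQ), "SW": (-_SQ, _SQ),
    "SR": (-1.0, 0.0), "SL": (-1.0, 0.0),
}


@dataclass(frozen=True)
class PerturbationType:
    """One of the ten belt-perturbation conditions."""

    code: str
    side: str = field(init=False)
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        if self.code not in PERTURBATION_CODES:
            raise ValueError(f"unknown perturbation code {self.code!r}")
        object.__setattr__(self, "side", "left" if self.code in _LEFT_CODES else "right")
        object.__setattr__(self, "direction", _DIRECTION[self.code])


ALL_PERTURBATIONS: tuple[PerturbationType, ...] = tuple(
    PerturbationType(c) for c in PERTURBATION_CODES
)

# ---------------------------------------------------------------------------
# default signal model parameters
# ---------------------------------------------------------------------------

#: walking-harmonic base amplitude per segment, m/s^2 (distal > proximal)
WALK_AMPLITUDE: dict[str, float] = {
    "HN": 0.5, "T": 0.6, "P": 0.8,
    "LA": 0.9, "RA": 0.9, "LFA": 1.2, "RFA": 1.2, "LH": 1.5, "RH": 1.5,
    "LT": 1.3, "RT": 1.3, "LS": 1.9, "RS": 1.9, "LF": 2.5, "RF": 2.5,
}
_AXIS_SCALE = (1.0, 0.7, 0.5)       # x (longitudinal), y (transversal), z (vertical)
_SECOND_HARMONIC = 0.5              # relative amplitude of the 2x-cadence harmonic

#: default perturbation amplitude multipliers (distal segments hit hardest)
DEFAULT_GAIN: dict[str, float] = {
    "HN": 0.4, "T": 0.45, "P": 0.5,
    "LA": 0.7, "RA": 0.7, "LFA": 0.9, "RFA": 0.9, "LH": 1.3, "RH": 1.3,
    "LT": 0.8, "RT": 0.8, "LS": 1.0, "RS": 1.0, "LF": 1.6, "RF": 1.6,
}

#: default mechanical-chain onset lags of the transient, s
DEFAULT_LATENCY: dict[str, float] = {
    "LF": 0.0, "RF": 0.0,
    "LS": 0.03, "RS": 0.03, "LT": 0.03, "RT": 0.03,
    "P": 0.06, "T": 0.06, "HN": 0.06,
    "LA": 0.08, "RA": 0.08, "LFA": 0.08, "RFA": 0.08, "LH": 0.08, "RH": 0.08,
}

TRANSIENT_AMPLITUDE = 8.0   # m/s^2 peak at gain 1
TRANSIENT_TAU = 0.25        # s, decay time constant
TRANSIENT_FREQ = 6.0        # Hz, oscillation frequency of the recovery response


def froude_speed(leg_length: float, froude: float = FROUDE_DEFAULT) -> float:
    """Walking speed (m/s) for a given leg length at a fixed Froude number.

    Fr = v^2 / (g * L), so v = sqrt(Fr * g * L). Imposing Fr = 0.15 gives all
    subjects the same dynamic similarity regardless of stature.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be positive")
    if froude < 0:
        raise ValueError("froude must be non-negative")
    return float(np.sqrt(froude * G * leg_length))


@dataclass
class SubjectParams:
    """Anthropometric and signal-model parameters of one synthetic subject."""

    leg_length: float = 0.822                 # m
    cadence: float = 1.8                      # step frequency, Hz
    walking_speed: float | None = None        # m/s; derived from Froude 0.15 if None
    noise_sd: float = 0.3                     # m/s^2 per channel
    perturbation_gain: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GAIN))
    transient_latency: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LATENCY))
    fs: float = FS_DEFAULT
    n_pre: int = N_PRE
    n_post: int = N_POST
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walking_speed is None:
            self.walking_speed = froude_speed(self.leg_length)
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for seg in SEGMENTS:
            if self.perturbation_gain.get(seg, 0.0) < 0:
                raise ValueError(f"negative perturbation gain for {seg}")

    @property
    def n_samples(self) -> int:
        return self.n_pre + self.n_post

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SubjectParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class TrialWindow:
    """One labelled 6-s trial: 45-channel acceleration around a perturbation.

    ``accel`` is [45 x n_samples] in m/s^2, channel order ``segments.CHANNELS``;
    ``label`` holds 'W' for the pre-onset samples and 'P' afterwards.
    """

    accel: np.ndarray
    onset_index: int
    fs: float
    ptype: PerturbationType
    session: int
    label: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        if self.accel.ndim != 2 or self.accel.shape[0] != len(CHANNELS):
            raise ValueError(
                f"accel must be [{len(CHANNELS)} x T], got {self.accel.shape}")
        if len(self.label) != self.accel.shape[1]:
            raise ValueError("label length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[1]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _walking_component(params: SubjectParams) -> np.ndarray:
    """Quasi-periodic walking acceleration, [45 x n] — per-subject phases."""
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0, 2 * np.pi, size=(len(CHANNELS), 2))
    t = np.arange(params.n_samples) / params.fs
    out = np.empty((len(CHANNELS), params.n_samples))
    w = 2 * np.pi * params.cadence
    for c, name in enumerate(CHANNELS):
        seg, axis = name.rsplit("_", 1)
        amp = WALK_AMPLITUDE[seg] * _AXIS_SCALE[AXES.index(axis)]
        out[c] = amp * (np.sin(w * t + phases[c, 0])
                        + _SECOND_HARMONIC * np.sin(2 * w * t + phases[c, 1]))
    return out


def _transient_component(params: SubjectParams, ptype: PerturbationType) -> np.ndarray:
    """Perturbation-locked damped oscillation, [45 x n], zero before onset."""
    dx, dy = _DIR_VEC[ptype.code]
    side_sign = 1.0 if ptype.side == "left" else -1.0
    n = params.n_samples
    out = np.zeros((len(CHANNELS), n))
    for si, seg in enumerate(SEGMENTS):
        gain = params.perturbation_gain.get(seg, 0.0)
        if gain == 0.0:
            continue
        lag = params.transient_latency.get(seg, 0.0)
        k0 = params.n_pre + int(round(lag * params.fs))
        if k0 >= n:
            continue
        tp = (np.arange(n - k0)) / params.fs
        env = TRANSIENT_AMPLITUDE * gain * np.exp(-tp / TRANSIENT_TAU)
        wphase = 2 * np.pi * TRANSIENT_FREQ * tp
        base = si * 3
        out[base + 0, k0:] = env * dx * np.sin(wphase)
        out[base + 1, k0:] = env * dy * np.cos(wphase)
        # vertical bounce carries the side sign and is non-zero at onset, so
        # the response is visible instantaneously for every direction
        out[base + 2, k0:] = env * 0.7 * side_sign * np.cos(wphase)
    return out


def generate_trial(params: SubjectParams, ptype: PerturbationType,
                   session: int = 1, seed: int | None = None) -> TrialWindow:
    """Generate one labelled trial window.

    The signal is walking harmonics + white measurement noise + the
    perturbation-locked transient. Deterministic given ``seed`` (noise) and
    ``params.seed`` (per-subject walking phases).
    """
    if not isinstance(ptype, PerturbationType):
        ptype = PerturbationType(str(ptype))
    if seed is None:
        seed = params.seed
    accel = _walking_component(params) + _transient_component(params, ptype)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        accel = accel + rng.normal(0.0, params.noise_sd, size=accel.shape)
    label = np.array(["W"] * params.n_pre + ["P"] * params.n_post)
    return TrialWindow(accel=accel, onset_index=params.n_pre, fs=params.fs,
                       ptype=ptype, session=session, label=label, seed=seed)


def generate_subject(params: SubjectParams) -> list[TrialWindow]:
    """Generate the 20-trial set of one subject: 2 sessions x 10 perturbations.

    Per-trial noise seeds are derived from the subject master seed by XOR with
    the trial index, so the whole set is reproducible from ``params.seed``.
    """
    trials = []
    idx = 0
    for session in (1, 2):
        for ptype in ALL_PERTURBATIONS:
            trial_seed = (params.seed ^ (idx + 1)) & 0x7FFFFFFF
            trials.append(generate_trial(params, ptype, session, trial_seed))
            idx += 1
    return trials


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_trial(trial: TrialWindow, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (one row per sample, 45 channels + label) and a
    ``<prefix>.json`` sidecar with the trial metadata."""
    import pandas as pd

    prefix = Path(prefix)
    df = pd.DataFrame(trial.accel.T, columns=list(CHANNELS))
    df["label"] = trial.label
    df.to_csv(prefix.with_suffix(".csv"), index=False)
    meta = {
        "ptype": trial.ptype.code,
        "side": trial.ptype.side,
        "direction": trial.ptype.direction,
        "onset_index": int(trial.onset_index),
        "fs": float(trial.fs),
        "session": int(trial.session),
        "seed": None if trial.seed is None else int(trial.seed),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_trial(prefix: str | Path) -> TrialWindow:
    """Read a trial written by :func:`write_trial`."""
    import pandas as pd

    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    accel = df[list(CHANNELS)].to_numpy().T
    return TrialWindow(accel=accel, onset_index=meta["onset_index"],
                       fs=meta["fs"], ptype=PerturbationType(meta["ptype"]),
                       session=meta["session"], label=df["label"].to_numpy(),
                       seed=meta.get("seed"))


def write_subject(trials: list[TrialWindow], out_dir: str | Path,
                  subject_id: str = "S00") -> list[Path]:
    """Write a subject's trials as ``<dir>/<id>_t00..t19`` CSV/JSON pairs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefixes = []
    for i, tr in enumerate(trials):
        prefix = out_dir / f"{subject_id}_t{i:02d}"
        write_trial(tr, prefix)
        prefixes.append(prefix)
    return prefixes


def read_subject(in_dir: str | Path, subject_id: str = "S00") -> list[TrialWindow]:
    """Read back all ``<id>_t*.csv`` trials of one subject, in trial order."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob(f"{subject_id}_t*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trials for {subject_id} in {in_dir}")
    return [read_trial(p.with_suffix("")) for p in paths]
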