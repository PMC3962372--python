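"""Independent-component analysis of the segment-acceleration dataset.

Two roles, mirroring how the detection pipeline uses ICA twice:

* the *ranking* pass (ICA1) runs once per subject on the full dataset M to
  decide how many independent components are worth keeping and which body
  segments load most heavily on them — the Total Segment Weight (TSW)
  informativeness statistic and the segment Ranking derived from it;
* the *feature* pass (ICA2) is refit on every outer-fold training set and its
  time-invariant unmixing matrix projects both training and test trials into
  component space for the classifier.

The component count N is chosen as the smallest PCA dimensionality explaining
a configurable fraction of variance (default 95 %). The unmixing itself is
FastICA (log-cosh contrast, deflation) run from several seeded restarts with
the best-negentropy solution kept, so results are reproducible given a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .segments import CHANNEL_SEGMENT, MIDLINE, PARTNER, SEGMENTS

#: E[log cosh(Z)] for standard-normal Z, the Gaussian baseline of the
#: log-cosh negentropy approximation
_GAUSS_LOGCOSH = 0.3745672074914381


@dataclass
class ICAModel:
    """A fitted linear unmixing of C acceleration channels into N components.

    ``unmixing`` (N x C) maps mean-centred channel data to unit-variance
    components; ``mixing`` (C x N) is its pseudo-inverse composed with the
    whitening, mapping components back to channel space.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    channel_means: np.ndarray
    n_components: int
    whitening: str = "PCA whitening to unit component variance"
    negentropy: float = float("nan")

    @property
    def n_channels(self) -> int:
        return self.unmixing.shape[1]


@dataclass
class SegmentRanking:
    """Per-segment informativeness: TSW percentages and the induced ranking."""

    tsw: dict[str, float]
    rank: list[str]
    n_retained: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"tsw_percent": self.tsw, "rank": self.rank,
             "n_retained": self.n_retained}, indent=1))

    def to_csv(self, path: str | Path) -> None:
        lines = ["segment,tsw_percent,rank"]
        order = {s: i + 1 for i, s in enumerate(self.rank)}
        for seg in SEGMENTS:
            lines.append(f"{seg},{self.tsw[seg]:.6f},{order[seg]}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# component-count selection
# ---------------------------------------------------------------------------

def select_n_components(M: np.ndarray, var_threshold: float = 0.95) -> int:
    """Smallest PCA dimensionality explaining >= var_threshold of variance.

    Operates on the mean-centred channel matrix [C x T]; rank-deficient data
    caps the answer at the numerical rank, and the result is always >= 1.
    """
    if not 0.0 < var_threshold <= 1.0:
        raise ValueError("var_threshold must lie in (0, 1]")
    M = np.asarray(M, dtype=float)
    X = M - M.mean(axis=1, keepdims=True)
    s = np.linalg.svd(X, compute_uv=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        return 1
    rank = int((s > s[0] * 1e-10).sum())
    cum = np.cumsum(var) / total
    n = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    return max(1, min(n, rank))


# ---------------------------------------------------------------------------
# fitting and projection
# ---------------------------------------------------------------------------

def _negentropy(sources: np.ndarray) -> float:
    """Log-cosh negentropy proxy summed over unit-variance components."""
    g = np.mean(np.logaddexp(sources, -sources) - np.log(2.0), axis=0)
    return float(np.sum((g - _GAUSS_LOGCOSH) ** 2))


def fit_ica(M: np.ndarray, n_components: int, seed: int = 0,
            restarts: int = 5, max_iter: int = 500, tol: float = 1e-4) -> ICAModel:
    """Unmix a [C x T] channel matrix into ``n_components`` components.

    FastICA (deflation, log-cosh contrast, unit-variance whitening) is run
    ``restarts`` times from seeds derived from ``seed``; the converged restart
    with the highest negentropy proxy wins. Raises if no restart converges.
    """
    M = np.asarray(M, dtype=float)
    C = M.shape[0]
    if not 1 <= n_components <= C:
        raise ValueError(f"n_components must be in [1, {C}]")
    best = None
    failures = []
    for r in range(restarts):
        rs = (seed + 7919 * r) & 0x7FFFFFFF
        ica = FastICA(n_components=n_components, algorithm="deflation",
                      fun="logcosh", whiten="unit-variance",
                      max_iter=max_iter, tol=tol, random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sources = ica.fit_transform(M.T)       # [T x N]
        # deflation reports the worst component's iteration count; hitting
        # the cap means at least one component failed to converge
        if int(np.max(ica.n_iter_)) >= max_iter:
            failures.append(rs)
            continue
        j = _negentropy(sources)
        if best is None or j > best.negentropy:
            best = ICAModel(unmixing=ica.components_.copy(),
                            mixing=ica.mixing_.copy(),
                            channel_means=ica.mean_.copy(),
                            n_components=n_components,
                            negentropy=j)
    if best is None:
        raise RuntimeError(
            f"FastICA failed to converge in all {restarts} restarts "
            f"(seeds {failures}, max_iter={max_iter}, tol={tol})")
    return best


def project(model: ICAModel, X: np.ndarray) -> np.ndarray:
    """Project a [C x T] channel matrix into component space: W (X - mean)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] != model.n_channels:
        raise ValueError(
            f"expected {model.n_channels} channels, got {X.shape[0]}")
    return model.unmixing @ (X - model.channel_means[:, None])


# ---------------------------------------------------------------------------
# segment ranking
# ---------------------------------------------------------------------------

def compute_tsw(model: ICAModel,
                channel_segment: tuple[str, ...] | list[str] = CHANNEL_SEGMENT,
                segments: tuple[str, ...] = SEGMENTS) -> SegmentRanking:
    """Total Segment Weight: cumulative absolute mixing loading per segment.

    Each retained component's mixing column is scaled to unit norm (so no
    component dominates by scale alone), absolute loadings are summed over the
    channels of each segment and over components, and the totals are
    normalized to percentages. The ranking is TSW-descending with ties broken
    by canonical anatomical order. Invariant to component permutation and
    sign — the ICA indeterminacies.
    """
    if len(channel_segment) != model.n_channels:
        raise ValueError("channel map length must match channel count")
    unknown = set(channel_segment) - set(segments)
    if unknown:
        raise ValueError(f"channels mapped to unknown segments {sorted(unknown)}")
    A = np.asarray(model.mixing, dtype=float)
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    W = np.abs(A / norms)                      # [C x N]
    raw = {s: 0.0 for s in segments}
    per_channel = W.sum(axis=1)
    for c, seg in enumerate(channel_segment):
        raw[seg] += float(per_channel[c])
    total = sum(raw.values())
    if total == 0:
        raise ValueError("all mixing weights are zero")
    tsw = {s: 100.0 * raw[s] / total for s in segments}
    rank = sorted(segments, key=lambda s: (-tsw[s], segments.index(s)))
    return SegmentRanking(tsw=tsw, rank=list(rank),
                          n_retained=model.n_components)


def select_bilateral_subset(ranking: SegmentRanking, k_pairs: int) -> list[str]:
    """Top-k bilateral segment groups from a ranking.

    Walks the ranking downwards; a lateral segment pulls in its contralateral
    partner (a fall can hit either side, so sensors are placed symmetrically),
    while midline segments count as single-entry groups. Stops after
    ``k_pairs`` groups; the result is returned in canonical anatomical order.
    """
    if k_pairs < 1:
        raise ValueError("k_pairs must be >= 1")
    chosen: set[str] = set()
    groups = 0
    for seg in ranking.rank:
        if seg in chosen:
            continue
        if seg in MIDLINE:
            chosen.add(seg)
        else:
            chosen.update({seg, PARTNER[seg]})
        groups += 1
        if groups >= k_pairs:
            break
    return [s for s in SEGMENTS if s in chosen]
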