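"""Canonical 15-segment body model vocabulary.

Segment codes follow the usual full-body marker-set conventions: head/neck
(HN), chest (T), abdomen/pelvis (P), upper arms (LA/RA), forearms (LFA/RFA),
hands (LH/RH), thighs (LT/RT), shanks (LS/RS) and feet (LF/RF). Channels are
the three global-frame linear-acceleration components of each segment's
centre of mass, ordered segment-major then axis (x, y, z), 45 in total.
"""

from __future__ import annotations

#: Canonical anatomical order; also the tie-break order for rankings.
SEGMENTS: tuple[str, ...] = (
    "HN", "T", "P",
    "LA", "RA", "LFA", "RFA", "LH", "RH",
    "LT", "RT", "LS", "RS", "LF", "RF",
)

#: Midline segments have no contralateral partner.
MIDLINE: frozenset[str] = frozenset({"HN", "T", "P"})

#: Left->right partner map (and its mirror) for bilateral selection.
_PAIRS = {"LA": "RA", "LFA": "RFA", "LH": "RH", "LT": "RT", "LS": "RS", "LF": "RF"}
PARTNER: dict[str, str] = {**_PAIRS, **{r: l for l, r in _PAIRS.items()}}

AXES: tuple[str, ...] = ("x", "y", "z")

#: 45 channel names, segment-major: HN_x, HN_y, HN_z, T_x, ...
CHANNELS: tuple[str, ...] = tuple(f"{s}_{a}" for s in SEGMENTS for a in AXES)

#: channel index -> segment code
CHANNEL_SEGMENT: tuple[str, ...] = tuple(s for s in SEGMENTS for _ in AXES)


def segment_channels(segment: str) -> list[int]:
    """Indices of the three acceleration channels belonging to *segment*."""
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    base = SEGMENTS.index(segment) * 3
    return [base, base + 1, base + 2]


def subset_channels(segments: list[str] | tuple[str, ...]) -> list[int]:
    """Channel indices for a set of segments, in canonical order."""
    chosen = set(segments)
    unknown = chosen - set(SEGMENTS)
    if unknown:
        raise ValueError(f"unknown segments {sorted(unknown)}")
    return [i for i, s in enumerate(CHANNEL_SEGMENT) if s in chosen]
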