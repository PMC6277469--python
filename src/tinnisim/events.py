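"""Change detection: turn level transitions into N1-like events.

The auditory system is modelled as a differential encoder — it signals
*changes* of level, not absolute level.  Each protocol transition that is
(a) audible, i.e. at least one side reaches the band's audiogram
threshold, and (b) at least one just-noticeable difference in magnitude,
emits a :class:`ChangeEvent` carrying the signed dB change.  Onsets from
silence (ON), offsets to silence (OFF) and audible-to-audible changes
(CHANGE) are the three event subtypes.

For the signed change, silence maps to the band's audibility floor
(threshold clipped at 0 dB): the floor is the only principled zero from
which a first audible level can be measured.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .profiles import ListenerProfile
from .protocols import SILENCE, Level, StimulusProtocol

__all__ = [
    "EventType",
    "ChangeEvent",
    "is_audible_change",
    "classify_event",
    "detect_events",
    "events_to_frame",
    "write_events_csv",
]


class EventType(str, enum.Enum):
    ON = "on"
    OFF = "off"
    CHANGE = "change"


@dataclass(frozen=True)
class ChangeEvent:
    time: float
    band_hz: float
    pre_db: Level
    post_db: Level
    delta_db: float
    subtype: EventType


def _audible(level: Level, threshold: float) -> bool:
    return level is not None and level >= threshold


def _effective(level: Level, threshold: float) -> float:
    """Silence maps to the audibility floor for level arithmetic."""
    return max(threshold, 0.0) if level is None else float(level)


def signed_delta(pre: Level, post: Level, threshold: float) -> float:
    """Signed level change, with silence mapped to the audibility floor."""
    return _effective(post, threshold) - _effective(pre, threshold)


def is_audible_change(pre: Level, post: Level, threshold: float, jnd: float) -> bool:
    """True iff the transition evokes an event: at least one side audible
    and the (floor-referenced) change at least one JND."""
    if not (_audible(pre, threshold) or _audible(post, threshold)):
        return False
    return abs(signed_delta(pre, post, threshold)) >= jnd


def classify_event(pre: Level, post: Level, threshold: float) -> EventType:
    """ON / OFF / CHANGE taxonomy.  Raises on a fully inaudible transition."""
    pre_aud = _audible(pre, threshold)
    post_aud = _audible(post, threshold)
    if not (pre_aud or post_aud):
        raise ValueError(
            f"inaudible transition {pre!r} -> {post!r} at threshold {threshold}"
        )
    if not pre_aud:
        return EventType.ON
    if not post_aud:
        return EventType.OFF
    return EventType.CHANGE


def detect_events(
    protocol: StimulusProtocol, profile: ListenerProfile
) -> list[ChangeEvent]:
    """One event per audible, supra-JND protocol transition per band,
    ordered by time then band.  Constant stretches emit nothing; the
    initial segment is a starting condition, not a transition."""
    events: list[ChangeEvent] = []
    for t_next, prev_seg, seg in zip(
        (s.t for s in protocol.segments[1:]),
        protocol.segments[:-1],
        protocol.segments[1:],
    ):
        for i, band in enumerate(protocol.bands_hz):
            if band not in profile.audiogram:
                raise KeyError(f"profile has no audiogram entry for band {band} Hz")
            thr = profile.threshold(band)
            pre, post = prev_seg.levels[i], seg.levels[i]
            if not is_audible_change(pre, post, thr, profile.jnd):
                continue
            events.append(
                ChangeEvent(
                    time=float(t_next),
                    band_hz=band,
                    pre_db=pre,
                    post_db=post,
                    delta_db=signed_delta(pre, post, thr),
                    subtype=classify_event(pre, post, thr),
                )
            )
    return events


def events_to_frame(events: list[ChangeEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [e.time for e in events],
            "band_hz": [e.band_hz for e in events],
            "pre_db": [e.pre_db for e in events],
            "post_db": [e.post_db for e in events],
            "delta_db": [e.delta_db for e in events],
            "subtype": [e.subtype.value for e in events],
        }
    )


def write_events_csv(events: list[ChangeEvent], path: Union[str, Path]) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.6f")
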