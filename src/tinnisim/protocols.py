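"""Stimulus protocols: piecewise-constant per-band sound-level schedules.

A protocol is the simulator's only input signal: an ordered list of
segments, each holding one level (dB) per frequency band, plus a total
duration.  Silence is an explicit sentinel (``None`` in memory, ``null``
on disk), distinct from a 0 dB level, so that an onset from silence can
be told apart from a change away from a 0 dB tone.

All levels live on a single common dB scale; the perceptual model is
linear in dB (masker loudness adds on top of the tinnitus loudness), so
no loudness (sone) transform is applied anywhere.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "SILENCE",
    "Level",
    "Segment",
    "StimulusProtocol",
    "ProtocolError",
    "make_fig1_protocol",
    "make_masker_protocol",
    "make_pulsating_masker",
    "make_click_train",
    "make_anechoic",
    "make_earplug",
    "read_protocol",
    "write_protocol",
]

#: Sentinel for silence — below any audiogram threshold.
SILENCE = None

Level = Optional[float]


class ProtocolError(ValueError):
    """A protocol violates its schema or invariants."""


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant stretch: starts at ``t`` and holds ``levels``
    (one entry per band; ``None`` is silence) until the next segment."""

    t: float
    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        for lv in self.levels:
            if lv is not None and not math.isfinite(lv):
                raise ProtocolError(f"non-finite level {lv!r} at t={self.t}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant multi-band level schedule.

    Invariants (checked on construction): at least one band; segment start
    times strictly increasing with the first at 0; every segment carries one
    level per band; total duration at least the last start time.
    """

    bands_hz: tuple[float, ...]
    segments: tuple[Segment, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if len(self.bands_hz) == 0:
            raise ProtocolError("protocol needs at least one band (bands_hz is empty)")
        if len(self.segments) == 0:
            raise ProtocolError("protocol needs at least one segment (segments is empty)")
        if self.segments[0].t != 0.0:
            raise ProtocolError(
                f"first segment must start at t=0, got t={self.segments[0].t}"
            )
        prev = -math.inf
        for seg in self.segments:
            if seg.t <= prev:
                raise ProtocolError(
                    f"segment start times must be strictly increasing "
                    f"(t={seg.t} follows t={prev})"
                )
            if len(seg.levels) != len(self.bands_hz):
                raise ProtocolError(
                    f"segment at t={seg.t} has {len(seg.levels)} levels "
                    f"for {len(self.bands_hz)} bands"
                )
            prev = seg.t
        if not math.isfinite(self.duration_s) or self.duration_s < prev:
            raise ProtocolError(
                f"duration_s={self.duration_s} is below last segment start {prev}"
            )

    # -- queries ---------------------------------------------------------

    @property
    def n_bands(self) -> int:
        return len(self.bands_hz)

    def band_index(self, band_hz: float) -> int:
        try:
            return self.bands_hz.index(band_hz)
        except ValueError:
            raise KeyError(f"band {band_hz} Hz not in protocol bands {self.bands_hz}")

    def transition_times(self) -> tuple[float, ...]:
        """Start times of all segments after the first."""
        return tuple(seg.t for seg in self.segments[1:])

    def level_at(self, t: float, band_hz: float) -> Level:
        """Level (dB or SILENCE) of ``band_hz`` at time ``t``."""
        i = self.band_index(band_hz)
        if not 0.0 <= t <= self.duration_s:
            raise ValueError(f"t={t} outside [0, {self.duration_s}]")
        level = self.segments[0].levels[i]
        for seg in self.segments:
            if seg.t <= t:
                level = seg.levels[i]
            else:
                break
        return level

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bands_hz": [_r6(b) for b in self.bands_hz],
            "segments": [
                {
                    "t": _r6(seg.t),
                    "levels_db": [None if lv is None else _r6(lv) for lv in seg.levels],
                }
                for seg in self.segments
            ],
            "duration_s": _r6(self.duration_s),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "StimulusProtocol":
        for field in ("bands_hz", "segments", "duration_s"):
            if field not in doc:
                raise ProtocolError(f"protocol document missing field {field!r}")
        segments = []
        for k, raw in enumerate(doc["segments"]):
            if "t" not in raw or "levels_db" not in raw:
                raise ProtocolError(f"segment #{k} missing 't' or 'levels_db'")
            segments.append(
                Segment(
                    t=float(raw["t"]),
                    levels=tuple(
                        None if lv is None else float(lv) for lv in raw["levels_db"]
                    ),
                )
            )
        return cls(
            bands_hz=tuple(float(b) for b in doc["bands_hz"]),
            segments=tuple(segments),
            duration_s=float(doc["duration_s"]),
        )


def _r6(x: float) -> float:
    """Canonical 6-decimal rounding used for on-disk floats."""
    return round(float(x), 6)


def write_protocol(protocol: StimulusProtocol, path: Union[str, Path]) -> None:
    """Write a protocol as canonical JSON (sorted keys, 6-decimal floats).

    The canonical form makes write → read → write byte-identical.
    """
    text = json.dumps(protocol.to_dict(), sort_keys=True, indent=1)
    Path(path).write_text(text + "\n")


def read_protocol(path: Union[str, Path]) -> StimulusProtocol:
    """Read a protocol JSON file, validating schema and invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ProtocolError(f"malformed protocol JSON in {path}: {exc}") from exc
    return StimulusProtocol.from_dict(doc)


# ---------------------------------------------------------------------------
# Fixture protocols
# ---------------------------------------------------------------------------


def make_fig1_protocol(
    transition_times: Sequence[float] = (0.0, 2.0, 4.0, 6.0),
    levels_db: Sequence[float] = (30.0, 80.0, 100.0, 50.0),
    band_hz: float = 4000.0,
    tail_s: float = 2.0,
) -> StimulusProtocol:
    """The three-step worked-example tone: 30 → 80 → 100 → 50 dB.

    The defaults step at 0/2/4/6 s; the level sequence carries signed
    changes of +50, +20 and −50 dB, which the change detector must recover.
    """
    if len(transition_times) != len(levels_db):
        raise ValueError("transition_times and levels_db must have equal length")
    segs = tuple(
        Segment(t=float(t), levels=(float(lv),))
        for t, lv in zip(transition_times, levels_db)
    )
    return StimulusProtocol(
        bands_hz=(band_hz,),
        segments=segs,
        duration_s=float(transition_times[-1]) + tail_s,
    )


def make_masker_protocol(
    band_hz: float,
    masker_level_db: float,
    masker_duration_s: float,
    pre_silence_s: float = 10.0,
    post_silence_s: float = 120.0,
    silence_level_db: Level = SILENCE,
) -> StimulusProtocol:
    """Steady masker: silence → masker → silence.

    ``silence_level_db`` lets the surround be a faint level instead of the
    silence sentinel (rarely needed; the default is true silence).
    """
    if masker_duration_s <= 0:
        raise ValueError(f"masker_duration_s must be positive, got {masker_duration_s}")
    if pre_silence_s < 0 or post_silence_s < 0:
        raise ValueError("pre/post silence must be non-negative")
    segs = []
    if pre_silence_s > 0:
        segs.append(Segment(0.0, (silence_level_db,)))
    segs.append(Segment(float(pre_silence_s), (float(masker_level_db),)))
    segs.append(Segment(float(pre_silence_s + masker_duration_s), (silence_level_db,)))
    return StimulusProtocol(
        bands_hz=(band_hz,),
        segments=tuple(segs),
        duration_s=float(pre_silence_s + masker_duration_s + post_silence_s),
    )


def make_pulsating_masker(
    band_hz: float,
    masker_level_db: float,
    pulse_depth_db: float,
    pulse_period_s: float,
    masker_duration_s: float,
    pre_silence_s: float = 10.0,
    post_silence_s: float = 120.0,
) -> StimulusProtocol:
    """Masker alternating between ``masker_level`` and ``masker_level −
    pulse_depth`` every half-period.

    With pulse_depth 0 the result is exactly the steady masker.  Each level
    flip is a detectable change that keeps resetting sensory memory, which
    is the point of the pulsating-masker experiment.
    """
    if pulse_depth_db < 0:
        raise ValueError(f"pulse_depth_db must be >= 0, got {pulse_depth_db}")
    if pulse_period_s <= 0:
        raise ValueError(f"pulse_period_s must be positive, got {pulse_period_s}")
    if masker_duration_s <= 0:
        raise ValueError("masker_duration_s must be positive")
    if pulse_period_s >= masker_duration_s:
        raise ValueError(
            f"pulse_period_s={pulse_period_s} must be shorter than "
            f"masker_duration_s={masker_duration_s}"
        )
    if pulse_depth_db == 0:
        return make_masker_protocol(
            band_hz, masker_level_db, masker_duration_s, pre_silence_s, post_silence_s
        )
    half = pulse_period_s / 2.0
    segs = []
    if pre_silence_s > 0:
        segs.append(Segment(0.0, (SILENCE,)))
    t = float(pre_silence_s)
    end = pre_silence_s + masker_duration_s
    k = 0
    while t < end - 1e-12:
        level = masker_level_db if k % 2 == 0 else masker_level_db - pulse_depth_db
        segs.append(Segment(t, (float(level),)))
        t = pre_silence_s + (k + 1) * half
        k += 1
    segs.append(Segment(float(end), (SILENCE,)))
    return StimulusProtocol(
        bands_hz=(band_hz,),
        segments=tuple(segs),
        duration_s=float(end + post_silence_s),
    )


def make_click_train(
    band_hz: float,
    click_level_db: float,
    n_clicks: int,
    click_duration_s: float = 1.0,
    interval_s: float = 11.0,
    start_s: float = 0.0,
    total_duration_s: Optional[float] = None,
) -> StimulusProtocol:
    """``n_clicks`` rectangular level excursions on silence.

    Click *i* occupies [start + i·interval, start + i·interval + click_duration).
    """
    if n_clicks < 0:
        raise ValueError("n_clicks must be >= 0")
    if n_clicks > 0:
        if click_duration_s <= 0:
            raise ValueError("click_duration_s must be positive")
        if interval_s < click_duration_s:
            raise ValueError(
                f"clicks overlap: interval_s={interval_s} < "
                f"click_duration_s={click_duration_s}"
            )
    segs = [Segment(0.0, (SILENCE,))]
    last_end = 0.0
    for i in range(n_clicks):
        on = start_s + i * interval_s
        off = on + click_duration_s
        if on == 0.0:
            segs[0] = Segment(0.0, (float(click_level_db),))
        else:
            segs.append(Segment(float(on), (float(click_level_db),)))
        segs.append(Segment(float(off), (SILENCE,)))
        last_end = off
    if total_duration_s is None:
        total_duration_s = last_end + interval_s if n_clicks else 10.0
    return StimulusProtocol(
        bands_hz=(band_hz,),
        segments=tuple(segs),
        duration_s=float(total_duration_s),
    )


def make_anechoic(
    duration_s: float, bands_hz: Sequence[float] = (4000.0,)
) -> StimulusProtocol:
    """All-band silence for ``duration_s`` — the anechoic-chamber condition."""
    bands = tuple(float(b) for b in bands_hz)
    return StimulusProtocol(
        bands_hz=bands,
        segments=(Segment(0.0, (SILENCE,) * len(bands)),),
        duration_s=float(duration_s),
    )


def make_earplug(
    ambient_levels_db: Mapping[float, float],
    attenuation_db: float,
    duration_s: float,
    fluctuation_db: float = 3.0,
    fluctuation_period_s: float = 5.0,
) -> StimulusProtocol:
    """Ambient environment heard through earplugs.

    Each band's ambient level is reduced by ``attenuation_db``; levels that
    would fall below 0 dB clip to silence.  A square ±``fluctuation_db``
    modulation alternating every ``fluctuation_period_s`` stands in for
    residual environmental sound (earplugs insulate less than a soundproof
    room, so some fluctuating input remains); set ``fluctuation_db=0`` for
    a flat attenuated field.
    """
    if attenuation_db < 0:
        raise ValueError("attenuation_db must be >= 0")
    if fluctuation_period_s <= 0:
        raise ValueError("fluctuation_period_s must be positive")
    bands = tuple(float(b) for b in ambient_levels_db)
    base = []
    for b in bands:
        lv = ambient_levels_db[b]
        lv = None if lv is None else lv - attenuation_db
        base.append(None if (lv is None or lv < 0.0) else float(lv))
    if fluctuation_db == 0 or all(lv is None for lv in base):
        segs = (Segment(0.0, tuple(base)),)
    else:
        segs_list = []
        t = 0.0
        sign = 1.0
        while t < duration_s - 1e-12:
            levels = tuple(
                None if lv is None else max(lv + sign * fluctuation_db, 0.0)
                for lv in base
            )
            segs_list.append(Segment(t, levels))
            t += fluctuation_period_s
            sign = -sign
        segs = tuple(segs_list)
    return StimulusProtocol(bands_hz=bands, segments=segs, duration_s=float(duration_s))
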