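"""The perception-update core: integrate change events into a percept.

Per band, the perceptual level (which doubles as the predicted value —
the two are treated as one state variable) evolves by three rules:

1. **Update.**  Each change event adds its signed dB delta to the
   percept and refills sensory memory (weight w = 1).  This is exactly
   differential-PCM decoding: the percept is the running sum of
   transmitted differences.
2. **Hold.**  While sensory memory lasts (w > 0; it fades over ``t_mem``
   seconds after the last event), the percept is held constant.  The
   memory weight w is reported in trajectories; its decay shape
   (linear by default, or step) does not change the dynamics, only the
   readout, because drift is gated on the moment w reaches zero.
3. **Drift.**  Once memory is exhausted (w = 0) the percept becomes
   uncertain and relaxes exponentially toward the predicted value TL —
   time constant ``tau_recovery`` in silence, ``tau_masker`` while an
   audible stimulus is held.  Listeners without an established TL
   (acute mode) instead ramp upward in silence at ``ramp_rate`` dB/s,
   capped ``drift_ceiling`` dB above the audibility floor; under a held
   audible stimulus they relax toward their (typically zero) TL, which
   reproduces slow fading of long steady tones.

Integration is event-driven with closed-form evolution between events,
so trajectories are exact (no ODE stepping error): samples inside a
memory-hold are bit-identical to the running event sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .events import ChangeEvent, detect_events, is_audible_change
from .profiles import ListenerProfile
from .protocols import SILENCE, Level, StimulusProtocol

__all__ = [
    "BandState",
    "PerceptTrajectory",
    "OracleError",
    "init_state",
    "apply_event",
    "evolve",
    "maybe_correct_tl",
    "simulate",
    "reconstruct_oracle",
]


@dataclass(frozen=True)
class BandState:
    """Per-band state at time ``t``.

    ``t_last_event`` is ``-inf`` for a state whose memory has never been
    filled (e.g. a chronic listener resting in silence): such a state is
    uncertain from the start.
    """

    band_hz: float
    t: float
    percept: float
    t_last_event: float
    tl: float

    def memory_weight(self, profile: ListenerProfile) -> float:
        """Sensory-memory weight w ∈ [0, 1] at the state's own time."""
        if math.isinf(self.t_last_event):
            return 0.0
        age = self.t - self.t_last_event
        if profile.memory_decay == "step":
            return 1.0 if age < profile.t_mem else 0.0
        return float(np.clip(1.0 - age / profile.t_mem, 0.0, 1.0))

    def uncertain(self, profile: ListenerProfile) -> bool:
        return self.memory_weight(profile) == 0.0


def init_state(
    profile: ListenerProfile,
    initial_levels: Optional[Mapping[float, Level]] = None,
) -> dict[float, BandState]:
    """Initial per-band state at t = 0.

    Chronic: percept = TL, uncertain (the resting tinnitus percept).
    Acute/normal: percept = the audible stimulus level at t = 0, or the
    audibility floor if silent/inaudible; memory starts full (the listener
    has just heard the world).
    """
    initial_levels = initial_levels or {}
    states = {}
    for band in profile.bands_hz:
        if profile.mode == "chronic":
            states[band] = BandState(
                band_hz=band,
                t=0.0,
                percept=profile.tl_of(band),
                t_last_event=-math.inf,
                tl=profile.tl_of(band),
            )
        else:
            lv = initial_levels.get(band, SILENCE)
            audible = lv is not None and lv >= profile.threshold(band)
            states[band] = BandState(
                band_hz=band,
                t=0.0,
                percept=float(lv) if audible else profile.floor(band),
                t_last_event=0.0,
                tl=profile.tl_of(band),
            )
    return states


def apply_event(state: BandState, event: ChangeEvent) -> BandState:
    """Perceptual update: add the signed change, refill sensory memory."""
    if event.band_hz != state.band_hz:
        raise ValueError(
            f"event band {event.band_hz} does not match state band {state.band_hz}"
        )
    return replace(
        state,
        t=event.time,
        percept=state.percept + event.delta_db,
        t_last_event=event.time,
    )


def _drift(
    percept0: float,
    t0: float,
    tt: np.ndarray,
    t_last_event: float,
    tl: float,
    driven: bool,
    chronic: bool,
    profile: ListenerProfile,
    floor: float,
) -> np.ndarray:
    """Closed-form percept at times ``tt`` ≥ t0, given percept0 at t0 and no
    events in between.  Exact: samples before uncertainty onset return
    percept0 itself (bit-identical), not a round-tripped formula."""
    t_unc = t_last_event + profile.t_mem  # uncertainty onset
    t_d = max(t0, t_unc)  # drift is already running if t0 past onset
    d = np.maximum(np.asarray(tt, dtype=float) - t_d, 0.0)
    if chronic or driven:
        tau = profile.tau_masker if driven else profile.tau_recovery
        return np.where(d > 0.0, tl + (percept0 - tl) * np.exp(-d / tau), percept0)
    cap = floor + profile.drift_ceiling
    rise = np.minimum(profile.ramp_rate * d, max(cap - percept0, 0.0))
    return percept0 + rise


def evolve(
    state: BandState,
    dt: float,
    profile: ListenerProfile,
    stimulus_level: Level = SILENCE,
) -> BandState:
    """Advance a band state by ``dt`` seconds with no intervening event.

    ``stimulus_level`` is the constant stimulus held over the interval;
    it selects the driven vs silent drift regime.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    band = state.band_hz
    driven = stimulus_level is not None and stimulus_level >= profile.threshold(band)
    new_percept = float(
        _drift(
            state.percept,
            state.t,
            np.array([state.t + dt]),
            state.t_last_event,
            state.tl,
            driven,
            profile.mode == "chronic",
            profile,
            profile.floor(band),
        )[0]
    )
    return replace(state, t=state.t + dt, percept=new_percept)


def maybe_correct_tl(
    state: BandState,
    recent_event_times: Iterable[float],
    profile: ListenerProfile,
) -> BandState:
    """Acute-phase TL correction.

    With enough recent external input (at least ``tl_correction_min_events``
    events inside the trailing ``tl_correction_window``), an acute listener
    re-anchors the integration constant: TL is set to zero and the percept
    drops by the former TL.  Chronic mode never corrects.
    """
    if profile.mode == "chronic" or state.tl == 0.0:
        return state
    lo = state.t - profile.tl_correction_window
    n_recent = sum(1 for te in recent_event_times if lo <= te <= state.t)
    if n_recent < profile.tl_correction_min_events:
        return state
    return replace(state, percept=state.percept - state.tl, tl=0.0)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class PerceptTrajectory:
    """Sampled per-band stimulus, percept and memory-weight traces, with the
    event log that produced them.  Stimulus silence is NaN in the arrays."""

    times: np.ndarray
    bands_hz: tuple[float, ...]
    stimulus: dict[float, np.ndarray]
    percept: dict[float, np.ndarray]
    memory_w: dict[float, np.ndarray]
    events: list[ChangeEvent]
    profile: ListenerProfile

    def band_events(self, band_hz: float) -> list[ChangeEvent]:
        return [e for e in self.events if e.band_hz == band_hz]

    def stimulus_audible(self, band_hz: float) -> np.ndarray:
        s = self.stimulus[band_hz]
        thr = self.profile.threshold(band_hz)
        return ~np.isnan(s) & (s >= thr)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for band in self.bands_hz:
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.times,
                        "band_hz": band,
                        "stimulus_db": self.stimulus[band],
                        "percept_db": self.percept[band],
                        "memory_w": self.memory_w[band],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def _sample_grid(duration: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError(f"sample_step must be positive, got {step}")
    n = int(math.floor(duration / step + 1e-9))
    times = np.arange(n + 1, dtype=float) * step
    if times[-1] < duration - 1e-9:
        times = np.append(times, duration)
    else:
        times[-1] = min(times[-1], duration)
    return times


def simulate(
    protocol: StimulusProtocol,
    profile: ListenerProfile,
    sample_step: float = 0.1,
    seed: Optional[int] = None,
) -> PerceptTrajectory:
    """Run the perception-update model over a protocol.

    Event-driven and exact: detects all audible change events, then applies
    the closed-form hold/drift law on every inter-transition interval.
    ``seed`` is accepted for interface symmetry with stochastic protocol
    generators; the simulation itself is deterministic.
    """
    events = detect_events(protocol, profile)
    times = _sample_grid(protocol.duration_s, sample_step)
    n = len(times)

    # interval boundaries: every protocol transition, plus 0 and the end
    bounds = [0.0] + [t for t in protocol.transition_times() if t <= protocol.duration_s]
    if bounds[-1] < protocol.duration_s:
        bounds.append(protocol.duration_s)

    initial_levels = {b: protocol.level_at(0.0, b) for b in protocol.bands_hz}
    states = init_state(profile, initial_levels)

    stimulus: dict[float, np.ndarray] = {}
    percept: dict[float, np.ndarray] = {}
    memory_w: dict[float, np.ndarray] = {}

    for band in protocol.bands_hz:
        ev_by_time = {e.time: e for e in events if e.band_hz == band}
        event_times: list[float] = []
        st = states[band]
        thr = profile.threshold(band)
        floor = profile.floor(band)
        chronic = profile.mode == "chronic"
        stim_arr = np.empty(n)
        per_arr = np.empty(n)
        w_arr = np.empty(n)

        for j in range(len(bounds) - 1 if bounds[-1] > bounds[0] else 1):
            a = bounds[j]
            b = bounds[j + 1] if j + 1 < len(bounds) else protocol.duration_s
            ev = ev_by_time.get(a)
            if ev is not None:
                st = apply_event(st, ev)
                event_times.append(a)
                st = maybe_correct_tl(st, event_times, profile)
            elif st.t < a:
                st = replace(st, t=a)
            level = protocol.level_at(a, band)
            driven = level is not None and level >= thr

            lo = int(np.searchsorted(times, a, side="left"))
            hi = (
                n
                if j + 2 >= len(bounds)
                else int(np.searchsorted(times, b, side="left"))
            )
            if hi > lo:
                tt = times[lo:hi]
                stim_arr[lo:hi] = np.nan if level is None else level
                per_arr[lo:hi] = _drift(
                    st.percept, a, tt, st.t_last_event, st.tl, driven, chronic,
                    profile, floor,
                )
                if math.isinf(st.t_last_event):
                    w_arr[lo:hi] = 0.0
                else:
                    age = tt - st.t_last_event
                    if profile.memory_decay == "step":
                        w_arr[lo:hi] = (age < profile.t_mem).astype(float)
                    else:
                        w_arr[lo:hi] = np.clip(1.0 - age / profile.t_mem, 0.0, 1.0)
            # advance state to the end of the interval
            if b > a:
                new_p = float(
                    _drift(
                        st.percept, a, np.array([b]), st.t_last_event, st.tl,
                        driven, chronic, profile, floor,
                    )[0]
                )
                st = replace(st, t=b, percept=new_p)

        stimulus[band] = stim_arr
        percept[band] = per_arr
        memory_w[band] = w_arr

    return PerceptTrajectory(
        times=times,
        bands_hz=protocol.bands_hz,
        stimulus=stimulus,
        percept=percept,
        memory_w=memory_w,
        events=events,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# Reconstruction oracle
# ---------------------------------------------------------------------------


class OracleError(ValueError):
    """The protocol/profile pair violates a reconstruction precondition."""


def reconstruct_oracle(
    protocol: StimulusProtocol,
    profile: ListenerProfile,
    sample_step: float = 0.1,
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Brute-force decoder: percept = stimulus level (silence → floor) + TL.

    Valid only where the differential code is lossless, i.e. every level
    change is audible and supra-JND, inter-event gaps stay inside sensory
    memory (no drift), and the integration constant is unambiguous
    (chronic: zero audibility floor and a silent start; acute: TL = 0).
    Raises :class:`OracleError` naming the violated precondition.
    """
    chronic = profile.mode == "chronic"
    times = _sample_grid(protocol.duration_s, sample_step)
    out: dict[float, np.ndarray] = {}
    for i, band in enumerate(protocol.bands_hz):
        thr = profile.threshold(band)
        floor = profile.floor(band)
        tl = profile.tl_of(band)
        if chronic:
            if floor != 0.0:
                raise OracleError(
                    f"chronic reconstruction needs a zero audibility floor "
                    f"(band {band} floor {floor})"
                )
            if protocol.segments[0].levels[i] is not None:
                raise OracleError("chronic reconstruction needs a silent start")
        elif tl != 0.0:
            raise OracleError("acute reconstruction needs tl = 0")

        ev_times = [0.0]
        for prev_seg, seg in zip(protocol.segments[:-1], protocol.segments[1:]):
            pre, post = prev_seg.levels[i], seg.levels[i]
            if pre == post:
                continue
            if not is_audible_change(pre, post, thr, profile.jnd):
                raise OracleError(
                    f"transition at t={seg.t} ({pre!r} -> {post!r}) is not an "
                    f"audible supra-JND change for band {band}"
                )
            ev_times.append(seg.t)
        gaps = np.diff(np.array(ev_times + [protocol.duration_s]))
        if len(gaps) and gaps.max() >= profile.t_mem and not (
            chronic and len(ev_times) == 1
        ):
            raise OracleError(
                f"inter-event gap {gaps.max():g} s is not shorter than "
                f"sensory memory t_mem={profile.t_mem:g} s"
            )

        levels = np.array(
            [
                floor if (lv := protocol.level_at(t, band)) is None else lv
                for t in times
            ]
        )
        out[band] = levels + tl
    return times, out
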