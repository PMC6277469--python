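"""Residual inhibition: masker runs, the two proposed experiments,
recovery-curve fitting, and population simulations.

A steady masker presented ML dB above the tinnitus loudness TL raises the
percept to TL + ML.  Once the masker outlasts sensory memory the percept
becomes uncertain and drifts down toward TL; at masker offset the change
−ML is integrated, leaving the percept at RL < TL — the tinnitus is
transiently *below* its usual loudness (residual inhibition).  RI depth is
TL − RL; RI duration is the time for the percept to climb back within a
tolerance of TL (offset-referenced by default, onset-referenced also
reported).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .events import EventType
from .profiles import ListenerProfile, PopulationSpec, sample_population
from .protocols import (
    SILENCE,
    Segment,
    StimulusProtocol,
    make_anechoic,
    make_masker_protocol,
    make_pulsating_masker,
)
from .state import PerceptTrajectory, simulate

__all__ = [
    "RIResult",
    "RecoveryFit",
    "run_ri_protocol",
    "ri_depth",
    "ri_duration",
    "run_experiment1",
    "run_experiment2",
    "control_drift_curve",
    "fit_recovery_curve",
    "selected_fit",
    "population_anechoic",
    "population_anechoic_fraction",
]


@dataclass(frozen=True)
class RIResult:
    """Metrics of one masker run on one band.

    ``censored`` flags a post-masker window too short to observe full
    recovery; the durations are then lower bounds.
    """

    band_hz: float
    tl: float
    ml: float
    masker_duration: float
    rl: float
    ri_depth: float
    ri_duration_offset: float
    ri_duration_onset: float
    tolerance: float
    censored: bool = False

    def to_dict(self) -> dict:
        return {
            "band_hz": self.band_hz,
            "tl_db": self.tl,
            "ml_db": self.ml,
            "masker_duration_s": self.masker_duration,
            "rl_db": self.rl,
            "ri_depth_db": self.ri_depth,
            "ri_duration_offset_s": self.ri_duration_offset,
            "ri_duration_onset_s": self.ri_duration_onset,
            "tolerance_db": self.tolerance,
            "censored": self.censored,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n")


def _offset_onset_times(traj: PerceptTrajectory, band_hz: float) -> tuple[float, float]:
    """Masker onset = first ON event, offset = first OFF event after it."""
    evs = traj.band_events(band_hz)
    t_on = next((e.time for e in evs if e.subtype == EventType.ON), None)
    if t_on is None:
        raise ValueError("trajectory contains no masker onset (ON) event")
    t_off = next(
        (e.time for e in evs if e.subtype == EventType.OFF and e.time > t_on), None
    )
    if t_off is None:
        raise ValueError("trajectory contains no masker offset (OFF) event")
    return t_on, t_off


def ri_depth(traj: PerceptTrajectory, tl: float, band_hz: Optional[float] = None) -> float:
    """TL minus the percept immediately after the masker offset."""
    band_hz = band_hz if band_hz is not None else traj.bands_hz[0]
    _, t_off = _offset_onset_times(traj, band_hz)
    i = int(np.searchsorted(traj.times, t_off, side="left"))
    return tl - float(traj.percept[band_hz][i])


def ri_duration(
    traj: PerceptTrajectory,
    tl: float,
    tolerance: float = 1.0,
    measure: str = "offset",
    band_hz: Optional[float] = None,
) -> tuple[float, bool]:
    """Time until the tinnitus percept returns within ``tolerance`` of TL.

    The endpoint is read only at silent samples (stimulus inaudible), so
    probe sounds presented during recovery do not spuriously end it.
    Returns ``(duration, censored)``; ``measure`` selects the origin:
    ``"offset"`` (masker off) or ``"onset"`` (masker on).
    """
    if measure not in ("offset", "onset"):
        raise ValueError(f"measure must be 'offset' or 'onset', got {measure!r}")
    band_hz = band_hz if band_hz is not None else traj.bands_hz[0]
    t_on, t_off = _offset_onset_times(traj, band_hz)
    origin = t_off if measure == "offset" else t_on
    after = traj.times >= t_off
    silent = ~traj.stimulus_audible(band_hz)
    recovered = traj.percept[band_hz] >= tl - tolerance
    hit = after & silent & recovered
    if not hit.any():
        return float(traj.times[-1] - origin), True
    return float(traj.times[np.argmax(hit)] - origin), False


def run_ri_protocol(
    profile: ListenerProfile,
    ml: float = 30.0,
    masker_duration: float = 30.0,
    post_window: float = 120.0,
    tolerance: float = 1.0,
    pre_silence: float = 10.0,
    band_hz: Optional[float] = None,
    sample_step: float = 0.1,
) -> RIResult:
    """Steady fully-masking masker run: build, simulate, measure.

    The masker is presented at TL + ML so that it fully masks the tinnitus
    (ML is the loudness added on top of the percept floor, which for the
    reference chronic profile coincides with TL).
    """
    if profile.mode != "chronic":
        raise ValueError("run_ri_protocol needs a chronic profile")
    if ml <= 0:
        raise ValueError(f"ml must be positive, got {ml}")
    band_hz = band_hz if band_hz is not None else profile.bands_hz[0]
    tl = profile.tl_of(band_hz)
    protocol = make_masker_protocol(
        band_hz,
        masker_level_db=tl + ml,
        masker_duration_s=masker_duration,
        pre_silence_s=pre_silence,
        post_silence_s=post_window,
    )
    traj = simulate(protocol, profile, sample_step=sample_step)
    depth = ri_depth(traj, tl, band_hz)
    dur_off, censored = ri_duration(traj, tl, tolerance, "offset", band_hz)
    return RIResult(
        band_hz=band_hz,
        tl=tl,
        ml=ml,
        masker_duration=masker_duration,
        rl=tl - depth,
        ri_depth=depth,
        ri_duration_offset=dur_off,
        ri_duration_onset=dur_off + masker_duration,
        tolerance=tolerance,
        censored=censored,
    )


# ---------------------------------------------------------------------------
# Experiment 1: probe clicks during recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Experiment1Result:
    measurements: pd.DataFrame  # columns: n_clicks, time_after_offset_s, percept_db
    recovery: pd.DataFrame      # columns: n_clicks, recovery_s, censored


def _masker_with_clicks(
    band_hz: float,
    masker_level: float,
    masker_duration: float,
    pre_silence: float,
    click_level: float,
    n_clicks: int,
    click_interval: float,
    click_duration: float,
    total_duration: float,
) -> StimulusProtocol:
    segs = [Segment(0.0, (SILENCE,))]
    segs.append(Segment(pre_silence, (float(masker_level),)))
    t_off = pre_silence + masker_duration
    segs.append(Segment(t_off, (SILENCE,)))
    for i in range(n_clicks):
        on = t_off + (i + 1) * click_interval
        segs.append(Segment(on, (float(click_level),)))
        segs.append(Segment(on + click_duration, (SILENCE,)))
    return StimulusProtocol(
        bands_hz=(band_hz,), segments=tuple(segs), duration_s=total_duration
    )


def run_experiment1(
    profile: ListenerProfile,
    ml: float = 30.0,
    masker_duration: float = 30.0,
    click_level: Optional[float] = None,
    n_clicks: int = 3,
    click_interval: float = 11.0,
    click_duration: float = 1.0,
    measurement_times: Optional[Sequence[float]] = None,
    tolerance: float = 1.0,
    band_hz: Optional[float] = None,
    sample_step: float = 0.1,
) -> Experiment1Result:
    """Probe-click experiment: does stimulation during recovery prolong RI?

    Conditions k = 0..n_clicks present k short clicks (in the tinnitus band,
    above threshold) after masker offset.  Each audible click refills
    sensory memory, freezing the still-suppressed percept, so recovery time
    grows with click count; sub-threshold clicks leave recovery unchanged.
    Percepts are also read at the requested times after offset (default
    0–10 min in 1-min steps), at the first silent sample at/after each.
    """
    if profile.mode != "chronic":
        raise ValueError("run_experiment1 needs a chronic profile")
    band_hz = band_hz if band_hz is not None else profile.bands_hz[0]
    tl = profile.tl_of(band_hz)
    if click_level is None:
        click_level = tl + ml
    if measurement_times is None:
        measurement_times = [60.0 * m for m in range(0, 11)]
    pre_silence = 10.0
    t_off = pre_silence + masker_duration
    total = t_off + max(measurement_times) + 60.0

    meas_rows = []
    rec_rows = []
    for k in range(n_clicks + 1):
        protocol = _masker_with_clicks(
            band_hz, tl + ml, masker_duration, pre_silence,
            click_level, k, click_interval, click_duration, total,
        )
        traj = simulate(protocol, profile, sample_step=sample_step)
        silent = ~traj.stimulus_audible(band_hz)
        for m in measurement_times:
            t_abs = t_off + m
            idx = np.flatnonzero((traj.times >= t_abs) & silent)
            if len(idx) == 0:
                continue
            meas_rows.append(
                {
                    "n_clicks": k,
                    "time_after_offset_s": m,
                    "percept_db": float(traj.percept[band_hz][idx[0]]),
                }
            )
        dur, cens = ri_duration(traj, tl, tolerance, "offset", band_hz)
        rec_rows.append({"n_clicks": k, "recovery_s": dur, "censored": cens})
    return Experiment1Result(
        measurements=pd.DataFrame(meas_rows), recovery=pd.DataFrame(rec_rows)
    )


# ---------------------------------------------------------------------------
# Experiment 2: pulsating vs steady masker
# ---------------------------------------------------------------------------


def run_experiment2(
    profile: ListenerProfile,
    ml: float = 30.0,
    masker_duration: float = 30.0,
    pulse_depth: float = 10.0,
    pulse_period: float = 2.0,
    post_window: float = 120.0,
    tolerance: float = 1.0,
    band_hz: Optional[float] = None,
    sample_step: float = 0.1,
) -> pd.DataFrame:
    """Steady vs pulsating masker of equal nominal level and duration.

    A masker pulsing by ``pulse_depth`` dB every half ``pulse_period``
    keeps evoking change events; with the period inside sensory memory the
    percept never becomes uncertain, never drifts, and RI vanishes —
    whereas the steady masker of the same duration produces positive RI.
    Returns one row per condition with rl and ri_depth.
    """
    if profile.mode != "chronic":
        raise ValueError("run_experiment2 needs a chronic profile")
    if pulse_period >= profile.t_mem:
        raise ValueError(
            f"pulse_period={pulse_period} must be shorter than sensory memory "
            f"t_mem={profile.t_mem} (pulses must keep resetting memory)"
        )
    band_hz = band_hz if band_hz is not None else profile.bands_hz[0]
    tl = profile.tl_of(band_hz)
    rows = []
    for condition in ("steady", "pulsating"):
        if condition == "steady":
            protocol = make_masker_protocol(
                band_hz, tl + ml, masker_duration, 10.0, post_window
            )
        else:
            protocol = make_pulsating_masker(
                band_hz, tl + ml, pulse_depth, pulse_period,
                masker_duration, 10.0, post_window,
            )
        traj = simulate(protocol, profile, sample_step=sample_step)
        depth = ri_depth(traj, tl, band_hz)
        rows.append(
            {"condition": condition, "rl_db": tl - depth, "ri_depth_db": depth}
        )
    return pd.DataFrame(rows)


def control_drift_curve(
    profile: ListenerProfile,
    ml: float = 30.0,
    durations: Iterable[float] = tuple(range(1, 61)),
    tolerance: float = 1.0,
    band_hz: Optional[float] = None,
    sample_step: float = 0.1,
) -> pd.DataFrame:
    """RL as a function of masker duration (the drift-curve control).

    RL stays at TL while the masker fits inside sensory memory, then falls
    as TL − ML·(1 − e^{−(D − t_mem)/tau_masker}).
    Returns columns masker_duration_s, rl_db, ri_depth_db.
    """
    rows = []
    for d in durations:
        res = run_ri_protocol(
            profile, ml=ml, masker_duration=float(d),
            tolerance=tolerance, band_hz=band_hz, sample_step=sample_step,
        )
        rows.append(
            {
                "masker_duration_s": float(d),
                "rl_db": res.rl,
                "ri_depth_db": res.ri_depth,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Recovery-curve fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryFit:
    """One candidate recovery-shape fit.

    families: ``exponential`` y = c − a·e^{−t/tau} (params a, tau, c);
    ``linear`` y = b0 + b1·t; ``logarithmic`` y = b0 + b1·ln(1 + t).
    ``aicc`` is the small-sample corrected information criterion used for
    selection (ties go to the family with fewer parameters).
    """

    family: str
    params: dict
    ssr: float
    aicc: float
    selected: bool = False


def _aicc(ssr: float, n: int, k: int) -> float:
    ssr = max(ssr, 1e-30)  # guard: perfect fits otherwise give -inf
    aic = n * math.log(ssr / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def fit_recovery_curve(
    times: Sequence[float], percepts: Sequence[float]
) -> list[RecoveryFit]:
    """Least-squares fits of the three candidate recovery shapes.

    Returns all three fits ordered [linear, logarithmic, exponential] with
    exactly one ``selected`` by lowest AICc; ties break toward the earlier
    (fewer-/simpler-parameter) family.  Needs ≥ 4 samples with distinct
    times.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(percepts, dtype=float)
    if t.ndim != 1 or len(t) != len(y):
        raise ValueError("times and percepts must be 1-D and equally long")
    if len(t) < 4:
        raise ValueError(f"need at least 4 samples, got {len(t)}")
    if np.ptp(t) == 0:
        raise ValueError("degenerate samples: all times identical")
    order = np.argsort(t)
    t, y = t[order], y[order]
    n = len(t)

    fits: list[RecoveryFit] = []

    # linear
    b1, b0 = np.polyfit(t, y, 1)
    ssr = float(np.sum((y - (b0 + b1 * t)) ** 2))
    fits.append(RecoveryFit("linear", {"b0": float(b0), "b1": float(b1)}, ssr,
                            _aicc(ssr, n, 2)))

    # logarithmic
    x = np.log1p(t - t[0])
    if np.ptp(x) > 0:
        c1, c0 = np.polyfit(x, y, 1)
    else:  # pragma: no cover - ptp(t)>0 implies ptp(x)>0
        c1, c0 = 0.0, float(y.mean())
    ssr = float(np.sum((y - (c0 + c1 * x)) ** 2))
    fits.append(RecoveryFit("logarithmic", {"b0": float(c0), "b1": float(c1)}, ssr,
                            _aicc(ssr, n, 2)))

    # exponential saturation toward an asymptote
    def expo(tt, a, tau, c):
        return c - a * np.exp(-(tt - t[0]) / tau)

    try:
        a0 = max(float(y[-1] - y[0]), 1e-3)
        tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)
        c0e = float(y[-1])
        popt, _ = curve_fit(
            expo, t, y, p0=(a0, tau0, c0e), maxfev=20000,
            bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        )
        ssr = float(np.sum((y - expo(t, *popt)) ** 2))
        params = {"amplitude": float(popt[0]), "tau": float(popt[1]),
                  "offset": float(popt[2])}
        fits.append(RecoveryFit("exponential", params, ssr, _aicc(ssr, n, 3)))
    except RuntimeError:
        fits.append(
            RecoveryFit("exponential", {"amplitude": 0.0, "tau": math.inf,
                                        "offset": float(y.mean())},
                        float(np.sum((y - y.mean()) ** 2)), math.inf)
        )

    best = min(range(len(fits)), key=lambda i: (fits[i].aicc, i))
    return [
        RecoveryFit(f.family, f.params, f.ssr, f.aicc, selected=(i == best))
        for i, f in enumerate(fits)
    ]


def selected_fit(fits: list[RecoveryFit]) -> RecoveryFit:
    return next(f for f in fits if f.selected)


# ---------------------------------------------------------------------------
# Population simulation (anechoic chamber / auditory deprivation)
# ---------------------------------------------------------------------------


def population_anechoic(
    spec: PopulationSpec,
    minutes: float = 5.0,
    ambient_reference: Optional[float] = None,
    sample_step: float = 0.5,
) -> pd.DataFrame:
    """Simulate every sampled listener in a silent chamber.

    Returns one row per individual: ramp_rate, drift_ceiling, peak percept
    (dB, max over bands and time), and whether tinnitus was heard (peak
    above the ambient reference).
    """
    profiles = sample_population(spec)
    duration = minutes * 60.0
    rows = []
    for i, prof in enumerate(profiles):
        ref = ambient_reference if ambient_reference is not None else prof.ambient_reference
        protocol = make_anechoic(duration, bands_hz=prof.bands_hz)
        traj = simulate(protocol, prof, sample_step=sample_step)
        peak = max(float(np.max(traj.percept[b])) for b in prof.bands_hz)
        rows.append(
            {
                "individual": i,
                "ramp_rate_db_per_s": prof.ramp_rate,
                "drift_ceiling_db": prof.drift_ceiling,
                "peak_percept_db": peak,
                "heard_tinnitus": peak > ref,
            }
        )
    return pd.DataFrame(rows)


def population_anechoic_fraction(
    spec: PopulationSpec,
    minutes: float = 5.0,
    ambient_reference: Optional[float] = None,
    sample_step: float = 0.5,
) -> float:
    """Percentage of the sampled population hearing tinnitus within the
    window — the transient-tinnitus-in-silence rate."""
    df = population_anechoic(spec, minutes, ambient_reference, sample_step)
    return 100.0 * float(df["heard_tinnitus"].mean())
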