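"""Listener profiles and population specs.

A :class:`ListenerProfile` bundles the audiogram with every parameter of
the perception-update dynamics:

* ``t_mem`` — sensory-memory duration (s).  Perception is held for this
  long after the last detected change; default 10 s, at the lower end of
  the 10–15 s range reported for auditory sensory memory.
* ``jnd`` — minimum detectable level change (dB); changes smaller than
  this evoke no event.  Default 2 dB, a conventional intensity JND.
* ``tau_masker`` / ``tau_recovery`` — time constants (s) of the
  exponential drift toward the predicted value once perception is
  uncertain, during a held external stimulus and in silence respectively.
  The driven constant is slower because residual fluctuations of a real
  masker keep partially updating perception.
* ``mode`` — ``"chronic"`` (TL fixed, never corrected) or ``"acute"``
  (TL correctable to zero given enough external input; also the model of
  a normal-hearing listener when ``tl`` is 0).
* ``tl`` — tinnitus loudness per band (dB): the erroneous predicted
  value toward which the percept drifts.
* ``ramp_rate`` / ``drift_ceiling`` — upward drift (dB/s) and its cap
  (dB above the audibility floor) for listeners without an established
  TL, i.e. the acute/normal route to transient tinnitus in silence.
* ``ambient_reference`` — dB level a silent-environment percept must
  exceed to count as "tinnitus heard".
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np

__all__ = [
    "ListenerProfile",
    "DistributionSpec",
    "PopulationSpec",
    "sample_population",
    "default_chronic_profile",
    "default_normal_profile",
    "read_profile",
    "write_profile",
]

_MODES = ("acute", "chronic")
_DECAYS = ("linear", "step")


@dataclass(frozen=True)
class ListenerProfile:
    audiogram: Mapping[float, float]
    tl: Mapping[float, float]
    mode: str = "acute"
    t_mem: float = 10.0
    jnd: float = 2.0
    tau_masker: float = 20.0
    tau_recovery: float = 10.0
    ramp_rate: float = 0.12
    drift_ceiling: float = 25.0
    ambient_reference: float = 10.0
    tl_correction_window: float = 30.0
    tl_correction_min_events: int = 3
    memory_decay: str = "linear"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.memory_decay not in _DECAYS:
            raise ValueError(f"memory_decay must be one of {_DECAYS}")
        for name in ("t_mem", "jnd", "tau_masker", "tau_recovery"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.ramp_rate < 0:
            raise ValueError(f"ramp_rate must be >= 0, got {self.ramp_rate}")
        if self.drift_ceiling < 0:
            raise ValueError(f"drift_ceiling must be >= 0, got {self.drift_ceiling}")
        object.__setattr__(self, "audiogram", dict(self.audiogram))
        tl = dict(self.tl)
        for b in self.audiogram:
            tl.setdefault(b, 0.0)
        for b, v in tl.items():
            if v < 0:
                raise ValueError(f"tl must be >= 0, got {v} for band {b}")
        object.__setattr__(self, "tl", tl)

    @property
    def bands_hz(self) -> tuple[float, ...]:
        return tuple(self.audiogram)

    def threshold(self, band_hz: float) -> float:
        return float(self.audiogram[band_hz])

    def floor(self, band_hz: float) -> float:
        """Audibility floor: the principled zero of the percept scale for a
        band — the audiogram threshold, never below 0 dB."""
        return max(self.threshold(band_hz), 0.0)

    def tl_of(self, band_hz: float) -> float:
        return float(self.tl.get(band_hz, 0.0))

    def to_dict(self) -> dict:
        return {
            "audiogram": {str(b): v for b, v in self.audiogram.items()},
            "tl": {str(b): v for b, v in self.tl.items()},
            "mode": self.mode,
            "t_mem": self.t_mem,
            "jnd": self.jnd,
            "tau_masker": self.tau_masker,
            "tau_recovery": self.tau_recovery,
            "ramp_rate": self.ramp_rate,
            "drift_ceiling": self.drift_ceiling,
            "ambient_reference": self.ambient_reference,
            "tl_correction_window": self.tl_correction_window,
            "tl_correction_min_events": self.tl_correction_min_events,
            "memory_decay": self.memory_decay,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ListenerProfile":
        doc = dict(doc)
        doc["audiogram"] = {float(b): float(v) for b, v in doc["audiogram"].items()}
        doc["tl"] = {float(b): float(v) for b, v in doc.get("tl", {}).items()}
        return cls(**doc)


def default_chronic_profile(band_hz: float = 4000.0, tl_db: float = 20.0) -> ListenerProfile:
    """Chronic-tinnitus reference listener.

    The audiogram threshold at the tinnitus band equals TL: chronic tinnitus
    sits in a region of elevated threshold, and with threshold = TL the
    percept floor coincides with the tinnitus loudness, which makes a masker
    presented at TL + ML raise the percept to exactly TL + ML.
    """
    return ListenerProfile(
        audiogram={band_hz: tl_db},
        tl={band_hz: tl_db},
        mode="chronic",
    )


def default_normal_profile(band_hz: float = 4000.0) -> ListenerProfile:
    """Normal-hearing listener: zero thresholds, no established TL."""
    return ListenerProfile(audiogram={band_hz: 0.0}, tl={band_hz: 0.0}, mode="acute")


def write_profile(profile: ListenerProfile, path: Union[str, Path]) -> None:
    Path(path).write_text(
        json.dumps(profile.to_dict(), sort_keys=True, indent=1) + "\n"
    )


def read_profile(path: Union[str, Path]) -> ListenerProfile:
    return ListenerProfile.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """A positive, right-skewed individual-differences distribution.

    ``lognormal`` with location given as the *median* (natural scale) and
    ``sigma`` the standard deviation of the log.  Mean = median·exp(sigma²/2).
    """

    family: str = "lognormal"
    median: float = 1.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.family != "lognormal":
            raise ValueError(f"unsupported distribution family {self.family!r}")
        if not (self.median > 0 and math.isfinite(self.median)):
            raise ValueError(f"median must be positive, got {self.median}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def mean(self) -> float:
        return self.median * math.exp(self.sigma**2 / 2.0)

    @property
    def sd(self) -> float:
        return self.mean * math.sqrt(math.expm1(self.sigma**2))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.lognormal(mean=math.log(self.median), sigma=self.sigma, size=size)


#: Frozen defaults for normal-hearing population heterogeneity.  With these,
#: tinnitus is heard in a 5-min silent chamber iff ramp_rate·290 s and
#: drift_ceiling both exceed the 10 dB ambient reference; the analytic joint
#: probability is Φ(0.831)·Φ(1.833) ≈ 0.77.
DEFAULT_RAMP_RATE_DIST = DistributionSpec("lognormal", median=0.12, sigma=1.5)
DEFAULT_DRIFT_CEILING_DIST = DistributionSpec("lognormal", median=25.0, sigma=0.5)


@dataclass(frozen=True)
class PopulationSpec:
    n: int
    seed: int
    base: ListenerProfile = field(default_factory=default_normal_profile)
    ramp_rate_dist: DistributionSpec = DEFAULT_RAMP_RATE_DIST
    drift_ceiling_dist: DistributionSpec = DEFAULT_DRIFT_CEILING_DIST

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population size n must be >= 1, got {self.n}")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "base": self.base.to_dict(),
            "ramp_rate_dist": vars(self.ramp_rate_dist).copy(),
            "drift_ceiling_dist": vars(self.drift_ceiling_dist).copy(),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PopulationSpec":
        return cls(
            n=int(doc["n"]),
            seed=int(doc["seed"]),
            base=ListenerProfile.from_dict(doc["base"]),
            ramp_rate_dist=DistributionSpec(**doc.get("ramp_rate_dist", {})),
            drift_ceiling_dist=DistributionSpec(**doc.get("drift_ceiling_dist", {})),
        )


def sample_population(spec: PopulationSpec) -> list[ListenerProfile]:
    """Draw ``spec.n`` listener profiles, heterogeneous in ramp_rate and
    drift_ceiling.

    Each individual gets its own child random stream (seed-sequence spawn by
    index), so the draw for listener *i* does not depend on how many others
    are sampled before it.
    """
    children = np.random.SeedSequence(spec.seed).spawn(spec.n)
    profiles = []
    for child in children:
        rng = np.random.default_rng(child)
        profiles.append(
            replace(
                spec.base,
                ramp_rate=float(spec.ramp_rate_dist.sample(rng)),
                drift_ceiling=float(spec.drift_ceiling_dist.sample(rng)),
            )
        )
    return profiles
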