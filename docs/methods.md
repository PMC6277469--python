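# Methods

## Model

Hearing is modelled per frequency band as a differential code plus a
decoder with a fallible prior. Three rules, applied band-independently
(bands never interact):

1. **Update.** A stimulus-level transition that (a) reaches the band's
   audiogram threshold on at least one side and (b) changes the level by
   at least one just-noticeable difference emits a change event carrying
   the signed dB difference. The percept adds the event's delta and
   sensory memory refills (weight w = 1). Silence is a sentinel, not
   0 dB; for the subtraction it maps to the *audibility floor*
   max(threshold, 0) — the only principled zero from which a first
   audible level can be measured. Events are instantaneous at the
   transition: the ~100 ms evoked-response latency is far below the
   seconds-scale dynamics modelled here, and gradual ramps are not
   supported (protocols are piecewise constant).
2. **Hold.** Sensory memory decays over `t_mem` (default 10 s, the lower
   end of the 10–15 s range reported for auditory sensory memory). While
   it lasts the percept is held constant. The reported weight trace
   decays linearly by default (a `step` shape is available); the choice
   affects only the readout, because drift is gated on the *moment* w
   reaches zero. The continuous-in-w alternative (drift rate scaled by
   1 − w) was rejected: it contradicts the model's own structural
   predictions — maskers shorter than `t_mem` must produce exactly zero
   residual inhibition, and percepts must be exactly reconstructible
   whenever changes arrive faster than `t_mem`.
3. **Drift.** Once uncertain, the percept relaxes exponentially toward
   the predicted value TL, `dP/dt = (TL − P)/τ`. Exponential relaxation
   is the minimal law with TL as a fixed point; it yields RI depth
   proportional to masker loudness and a saturating RI duration, both
   desired qualitative signatures. τ is `tau_recovery` (default 10 s)
   in silence and `tau_masker` (default 20 s) while an audible stimulus
   is held — a held real-world masker still fluctuates slightly and
   those micro-updates brake the drift, which we fold into a slower time
   constant instead of simulating micro-fluctuations. Listeners without
   an established TL (acute mode; a normal listener is acute with
   TL = 0) ramp upward in silence at `ramp_rate` dB/s, capped
   `drift_ceiling` dB above the floor, since no target exists yet; under
   a *driven* uncertain period they relax toward their TL with
   `tau_masker`, which doubles as slow loudness adaptation to long
   steady tones. The percept and the predicted value are deliberately
   one state variable; the hierarchical-inference picture collapses to a
   two-level abstraction (event present = full-precision error, event
   absent = zero precision via the memory gate).

**Acute TL correction.** If at least `tl_correction_min_events` (3)
events arrive within the trailing `tl_correction_window` (30 s), an acute
listener re-anchors the integration constant: TL := 0 and the percept
drops by the former TL. Chronic mode never corrects. The acute→chronic
transition itself is not modelled; a profile is one or the other.

**Integration is exact.** The simulator is event-driven with closed-form
evolution between protocol transitions (hold, exponential, or capped
linear ramp), not a fixed-step ODE solver. Samples inside a memory hold
return the running event sum itself, bit-identical — this is what makes
the reconstruction-oracle tests exact rather than approximate.

## Default listener profiles

| parameter | default | meaning |
|---|---|---|
| t_mem | 10 s | sensory-memory duration |
| jnd | 2 dB | minimum detectable level change (conventional intensity JND) |
| tau_masker | 20 s | drift constant under a held stimulus |
| tau_recovery | 10 s | drift constant in silence |
| ramp_rate | 0.12 dB/s | upward drift without a TL (acute/normal, silence) |
| drift_ceiling | 25 dB | cap on that drift, above the floor |
| ambient_reference | 10 dB | percept level counting as "tinnitus heard" in silence |

The reference chronic profile has TL = 20 dB at 4 kHz with the audiogram
threshold elevated to the same 20 dB. Threshold = TL is a modelling
commitment, not a coincidence: chronic tinnitus sits in a band of hearing
loss, and with the floor at TL a masker presented at TL + ML raises the
percept to exactly TL + ML and its offset integrates −ML, which is the
arithmetic the residual-inhibition analysis assumes ("fully masking" means
ML exceeds TL by at least one JND). The time constants were calibrated
once against the external anchor that suppression lasts ≈ 40 s after a
30-s stimulus: with the defaults, depth = 30·(1 − e^(−20/20)) ≈ 18.96 dB
and offset RI duration = t_mem + tau_recovery·ln(depth/1 dB) ≈ 39.4 s.
They are frozen; the acceptance checks re-measure them, they do not refit
them.

## Residual-inhibition metrics

RI depth = TL − RL, with RL the percept just after the masker-offset
event. RI duration is the first time the percept re-enters a 1 dB
tolerance band below TL (no tolerance is standard in the literature; 1 dB
is our choice and a parameter), measured from masker offset by default —
the offset measure is what the ≈ 40 s anchor refers to and the only one
with a clean plateau — with the onset-referenced measure also reported
(offset value + masker duration). The endpoint is read only at samples
where the stimulus is inaudible, so probe sounds presented during
recovery cannot spuriously terminate it. A post-masker window too short
to observe recovery flags the result as censored (durations become lower
bounds) rather than failing.

Recovery-curve fitting compares linear, logarithmic (b₀ + b₁·ln(1+t)) and
exponential-saturation (c − a·e^(−t/τ)) shapes by least squares and
selects by small-sample-corrected AICc, ties broken toward fewer
parameters (ordering linear, logarithmic, exponential). Perfect fits are
floored at SSR = 1e-30 so the criterion stays finite; a non-converging
exponential fit is reported with infinite AICc instead of raising.

## Population simulation

Individual differences enter through `ramp_rate` and `drift_ceiling`,
drawn log-normally (positive, right-skewed): ramp_rate median 0.12 dB/s
(σ_log = 1.5), drift_ceiling median 25 dB (σ_log = 0.5). In a 5-minute
silent chamber a listener hears tinnitus iff
min(ramp_rate·(300 − t_mem), drift_ceiling) exceeds the 10 dB ambient
reference; the analytic rate under the defaults is
Φ(0.831)·Φ(1.833) ≈ 77%, chosen once to sit inside the 64–94% range
reported for anechoic-chamber studies and then frozen. Sampling forks one
seed-sequence child per individual by index, so draws are reproducible
and order-independent.

## What the synthetic protocols do and do not capture

Protocols are piecewise-constant dB schedules per band: they capture the
timing and magnitude structure of level changes, which is all the model
consumes. They do not capture waveforms, spectra within a band, binaural
cues, realistic ambient soundscapes (the earplug fixture's ±3 dB square
fluctuation every 5 s is a placeholder, and the ambient levels in the
deprivation scenarios are configuration, not claims), N1 amplitude
saturation or adaptation, or slow cumulative effects of repeated masking.
Passing tests therefore validate the model's internal logic and its
structural predictions under idealized stimulation, not its fit to any
listener's audiometric data.

## Numerical choices and edge cases

- Default sampling step 0.1 s (dynamics are seconds-scale); RI durations
  are quantized to it. Population runs use 0.5 s (the anechoic percept is
  a single closed-form arc).
- The reconstruction oracle demands: every distinct-level transition
  audible and supra-JND, inter-event gaps < t_mem, and an unambiguous
  integration constant (chronic: zero floor and a silent start; acute:
  TL = 0). Its property tests draw levels and times on a 0.25 grid, so
  all sums are exact dyadic arithmetic and equality can be asserted
  bit-for-bit.
- A transition at exactly t = 0 or t = duration is a boundary condition,
  not an event (the first segment is the starting state).
- The drift never overshoots TL (asymptotic approach is assumed; the
  alternative is unconstrained by anything the model states).
- `evolve` rejects non-positive dt; protocols reject non-finite levels,
  unordered times and missing band levels by name.

## Known limitations

Single-scale dB arithmetic (no loudness transform); no cross-band
interaction in RI (frequency specificity emerges from per-band gating
only); acute→chronic transition not modelled; gradual level ramps
unsupported; the "repeated masking slowly reduces tinnitus" observation
has no mechanism here.
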