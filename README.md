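# tinnisim

An event-driven simulator of the **perception-update model of tinnitus**,
for psychoacousticians and computational-neuroscience researchers who want
to explore, and design experiments around, the idea that tinnitus is a
decoding artifact of change-based hearing rather than aberrant neural
activity per se.

## The model

The auditory system is treated as a differential encoder (the analogy is
differential PCM): cortical N1-like responses carry the *signed change* of
sound level, ΔL = L(t⁺) − L(t⁻), not absolute level. Perception is the
running integral of these changes,

    P(t) = P(t₀) + Σ ΔLᵢ ,

held between events by auditory sensory memory (duration `t_mem` ≈ 10 s).
Changes are gated: an event fires only if the transition reaches the
band's audiogram threshold and exceeds a just-noticeable difference
(`jnd`, default 2 dB). When no audible change arrives for longer than
`t_mem`, the percept becomes uncertain and drifts exponentially toward a
*predicted* value — the tinnitus loudness TL:

    dP/dt = (TL − P) / τ       once memory is exhausted,

with τ = `tau_recovery` in silence and a slower `tau_masker` under a held
stimulus. In chronic tinnitus TL is fixed (an erroneous integration
constant: a driven listener perceives stimulus + TL); in the acute phase
enough external input re-anchors the constant and TL is corrected to zero.
Normal-hearing listeners deprived of input (anechoic chamber, earplugs)
instead drift upward at an individual `ramp_rate` toward a `drift_ceiling`,
which is how transient tinnitus in silence arises in the model.

Residual inhibition (RI) follows directly: a masker at TL + ML raises the
percept to TL + ML; once it outlasts sensory memory the percept drifts
down; at masker offset the change −ML is integrated, leaving the percept
at RL < TL (RI depth = TL − RL) until it drifts back to TL (RI duration).

The package provides protocol generators (steady/pulsating maskers, click
trains, the three-step demonstration tone, anechoic/earplug scenarios),
the change detector, the exact closed-form integrator, RI metrics,
recovery-curve fitting (linear / logarithmic / exponential, AICc
selection), the two proposed validation experiments, and seeded
population simulations with log-normal individual differences.

## Worked example

Encode the three-step tone (30 → 80 → 100 → 50 dB) for an unimpaired
listener:

```
$ tinnisim fig1 --out out
 time_s  band_hz  pre_db  post_db  delta_db subtype
    2.0   4000.0    30.0     80.0      50.0  change
    4.0   4000.0    80.0    100.0      20.0  change
    6.0   4000.0   100.0     50.0     -50.0  change
```

Each transition evokes one event whose signed magnitude (+50, +20, −50 dB)
is the level *change*, not the absolute level — integrating them
reconstructs the stimulus exactly.

A residual-inhibition run on the default chronic profile (TL = 20 dB at
4 kHz, masker 30 dB above TL for 30 s):

```
$ tinnisim ri --out out
TL 20 dB, ML 30 dB, RL 1.04 dB | RI depth 18.96 dB, RI duration (offset) 39.5 s
```

The percept drops to RL ≈ 1 dB at masker offset (depth 18.96 dB =
ML·(1 − e^(−20 s/τ_masker))) and takes ≈ 40 s to climb back within 1 dB of
TL. A pulsating masker of the same nominal level abolishes RI, because its
pulses keep refilling sensory memory and the percept never drifts:

```
$ tinnisim exp2 --out out
condition     rl_db  ri_depth_db
   steady  1.036383    18.963617
pulsating 20.000000     0.000000
```

And a heterogeneous population of 1000 normal-hearing listeners in a
silent chamber:

```
$ tinnisim population --n 1000 --seed 1 --out out
77.9% of 1000 simulated listeners heard tinnitus within 5 min of silence
```

Library use mirrors the CLI:

```python
import tinnisim as ts

chronic = ts.default_chronic_profile()          # TL = 20 dB at 4 kHz
res = ts.run_ri_protocol(chronic, ml=30.0, masker_duration=30.0)
res.ri_depth, res.ri_duration_offset            # (18.96, 39.5)
```

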