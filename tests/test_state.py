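"""The perceptual integrator: update, hold, drift, correction, oracle."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings

import tinnisim as ts
from tinnisim.events import ChangeEvent, EventType
from tinnisim.state import BandState, OracleError

from conftest import lossless_protocols


class TestInitState:
    def test_chronic_rests_at_tl_and_uncertain(self, chronic_profile):
        st = ts.init_state(chronic_profile)[4000.0]
        assert st.percept == 20.0
        assert st.uncertain(chronic_profile)
        assert st.memory_weight(chronic_profile) == 0.0

    def test_acute_in_silence_rests_at_floor_with_zero_tl(self, normal_profile):
        st = ts.init_state(normal_profile)[4000.0]
        assert st.percept == 0.0
        assert st.tl == 0.0

    def test_acute_with_audible_stimulus_tracks_it(self, normal_profile):
        st = ts.init_state(normal_profile, {4000.0: 30.0})[4000.0]
        assert st.percept == 30.0

    def test_chronic_multi_band_independent_tls(self):
        prof = ts.ListenerProfile(
            audiogram={1000.0: 0.0, 4000.0: 20.0},
            tl={1000.0: 5.0, 4000.0: 20.0},
            mode="chronic",
        )
        states = ts.init_state(prof)
        assert states[1000.0].percept == 5.0
        assert states[4000.0].percept == 20.0


def _event(t, delta, subtype=EventType.CHANGE):
    return ChangeEvent(time=t, band_hz=4000.0, pre_db=None, post_db=None,
                       delta_db=delta, subtype=subtype)


class TestApplyEvent:
    def test_masker_onset_adds_ml_on_top_of_tl(self, chronic_profile):
        st = ts.init_state(chronic_profile)[4000.0]
        st2 = ts.apply_event(st, _event(10.0, 40.0))
        assert st2.percept == 60.0  # TL + ML
        assert st2.memory_weight(chronic_profile) == 1.0

    def test_offset_subtracts_after_drift(self, chronic_profile):
        st = BandState(4000.0, t=40.0, percept=45.0, t_last_event=10.0, tl=20.0)
        st2 = ts.apply_event(st, _event(40.0, -40.0))
        assert st2.percept == 5.0  # RL

    def test_any_event_refills_memory(self, chronic_profile):
        st = BandState(4000.0, t=100.0, percept=20.0, t_last_event=-math.inf, tl=20.0)
        st2 = ts.apply_event(st, _event(100.0, 3.0))
        assert st2.memory_weight(chronic_profile) == 1.0
        assert not st2.uncertain(chronic_profile)

    def test_band_mismatch_rejected(self, chronic_profile):
        st = ts.init_state(chronic_profile)[4000.0]
        bad = ChangeEvent(5.0, 1000.0, None, None, 10.0, EventType.ON)
        with pytest.raises(ValueError, match="band"):
            ts.apply_event(st, bad)


class TestEvolve:
    def test_memory_weight_hits_zero_exactly_at_t_mem(self, chronic_profile):
        st = BandState(4000.0, t=0.0, percept=50.0, t_last_event=0.0, tl=20.0)
        st2 = ts.evolve(st, chronic_profile.t_mem, chronic_profile,
                        stimulus_level=50.0)
        assert st2.memory_weight(chronic_profile) == 0.0
        assert st2.percept == 50.0  # held throughout memory

    def test_percept_held_while_memory_lasts(self, chronic_profile):
        st = BandState(4000.0, t=0.0, percept=50.0, t_last_event=0.0, tl=20.0)
        for dt in (1.0, 4.0, 4.9):
            assert ts.evolve(st, dt, chronic_profile, 50.0).percept == 50.0

    def test_uncertain_drift_is_exponential_toward_tl(self, chronic_profile):
        """Fully uncertain chronic percept at TL + 30 dB relaxes by a factor
        e^-1 over one time constant (closed form vs the integrator)."""
        prof = replace(chronic_profile, tau_masker=20.0)
        st = BandState(4000.0, t=0.0, percept=50.0, t_last_event=-math.inf, tl=20.0)
        st2 = ts.evolve(st, 20.0, prof, stimulus_level=50.0)
        assert st2.percept == pytest.approx(20.0 + 30.0 * math.exp(-1.0), abs=1e-6)

    def test_silent_drift_uses_recovery_time_constant(self, chronic_profile):
        prof = replace(chronic_profile, tau_recovery=10.0)
        st = BandState(4000.0, t=0.0, percept=5.0, t_last_event=-math.inf, tl=20.0)
        st2 = ts.evolve(st, 10.0, prof, stimulus_level=None)
        assert st2.percept == pytest.approx(20.0 - 15.0 * math.exp(-1.0), abs=1e-6)

    def test_chronic_silence_converges_to_tl(self, chronic_profile):
        st = BandState(4000.0, t=0.0, percept=5.0, t_last_event=-math.inf, tl=20.0)
        st2 = ts.evolve(st, 1e4, chronic_profile, None)
        assert st2.percept == pytest.approx(20.0, abs=1e-9)

    def test_acute_silence_ramps_to_ceiling(self, normal_profile):
        prof = replace(normal_profile, ramp_rate=0.5, drift_ceiling=15.0)
        st = BandState(4000.0, t=0.0, percept=0.0, t_last_event=-math.inf, tl=0.0)
        assert ts.evolve(st, 10.0, prof, None).percept == pytest.approx(5.0)
        assert ts.evolve(st, 1000.0, prof, None).percept == pytest.approx(15.0)

    def test_rejects_nonpositive_dt(self, chronic_profile):
        st = ts.init_state(chronic_profile)[4000.0]
        with pytest.raises(ValueError, match="dt"):
            ts.evolve(st, 0.0, chronic_profile)


class TestTlCorrection:
    def test_acute_with_enough_input_zeroes_tl(self):
        prof = ts.ListenerProfile(audiogram={4000.0: 0.0}, tl={4000.0: 15.0},
                                  mode="acute")
        st = BandState(4000.0, t=25.0, percept=75.0, t_last_event=25.0, tl=15.0)
        st2 = ts.maybe_correct_tl(st, [5.0, 15.0, 25.0], prof)
        assert st2.tl == 0.0
        assert st2.percept == 60.0  # tinnitus contribution removed

    def test_chronic_never_corrects(self, chronic_profile):
        st = BandState(4000.0, t=25.0, percept=75.0, t_last_event=25.0, tl=20.0)
        st2 = ts.maybe_correct_tl(st, [5.0, 15.0, 25.0], chronic_profile)
        assert st2.tl == 20.0
        assert st2.percept == 75.0

    def test_too_few_events_leave_tl(self):
        prof = ts.ListenerProfile(audiogram={4000.0: 0.0}, tl={4000.0: 15.0},
                                  mode="acute")
        st = BandState(4000.0, t=25.0, percept=75.0, t_last_event=25.0, tl=15.0)
        assert ts.maybe_correct_tl(st, [25.0], prof).tl == 15.0

    def test_events_outside_window_ignored(self):
        prof = ts.ListenerProfile(audiogram={4000.0: 0.0}, tl={4000.0: 15.0},
                                  mode="acute", tl_correction_window=30.0)
        st = BandState(4000.0, t=100.0, percept=75.0, t_last_event=100.0, tl=15.0)
        assert ts.maybe_correct_tl(st, [5.0, 10.0, 100.0], prof).tl == 15.0


class TestSimulate:
    def test_fig1_percept_tracks_stimulus(self, normal_profile):
        p = ts.make_fig1_protocol()
        traj = ts.simulate(p, normal_profile)
        times, oracle = ts.reconstruct_oracle(p, normal_profile)
        assert np.array_equal(traj.percept[4000.0], oracle[4000.0])

    def test_chronic_silence_stays_at_tl(self, chronic_profile):
        p = ts.make_anechoic(300.0)
        traj = ts.simulate(p, chronic_profile)
        assert np.all(traj.percept[4000.0] == 20.0)

    def test_driven_chronic_carries_tl_as_integral_constant(self):
        """With audible changes more frequent than sensory memory, the
        chronic percept equals stimulus + TL at every driven sample."""
        prof = ts.ListenerProfile(audiogram={4000.0: 0.0}, tl={4000.0: 20.0},
                                  mode="chronic")
        levels = [None, 40.0, 55.0, 45.0, 60.0, 50.0]
        segs = tuple(ts.Segment(5.0 * i, (lv,)) for i, lv in enumerate(levels))
        p = ts.StimulusProtocol(bands_hz=(4000.0,), segments=segs, duration_s=30.0)
        traj = ts.simulate(p, prof, sample_step=0.25)
        driven = ~np.isnan(traj.stimulus[4000.0])
        assert np.array_equal(
            traj.percept[4000.0][driven], traj.stimulus[4000.0][driven] + 20.0
        )

    def test_memory_gate_holds_percept_between_events(self, chronic_profile):
        p = ts.make_masker_protocol(4000.0, 50.0, 30.0, 10.0, 60.0)
        traj = ts.simulate(p, chronic_profile)
        t = traj.times
        hold = (t >= 10.0) & (t < 10.0 + chronic_profile.t_mem)
        assert np.all(traj.percept[4000.0][hold] == 50.0)

    def test_drift_contraction_in_chronic_silence(self, chronic_profile):
        p = ts.make_masker_protocol(4000.0, 50.0, 30.0, 10.0, 200.0)
        traj = ts.simulate(p, chronic_profile)
        after = traj.times >= 40.0
        gap = np.abs(traj.percept[4000.0][after] - 20.0)
        assert np.all(np.diff(gap) <= 1e-12)

    def test_trajectory_is_bit_deterministic(self, chronic_profile):
        p = ts.make_masker_protocol(4000.0, 50.0, 30.0)
        a = ts.simulate(p, chronic_profile, seed=1)
        b = ts.simulate(p, chronic_profile, seed=1)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.percept[4000.0], b.percept[4000.0])
        assert np.array_equal(a.memory_w[4000.0], b.memory_w[4000.0])

    def test_memory_weight_decays_linearly(self, chronic_profile):
        p = ts.make_masker_protocol(4000.0, 50.0, 30.0, 10.0, 60.0)
        traj = ts.simulate(p, chronic_profile)
        t = traj.times
        inside = (t >= 10.0) & (t <= 20.0)
        expected = np.clip(1.0 - (t[inside] - 10.0) / 10.0, 0.0, 1.0)
        assert np.allclose(traj.memory_w[4000.0][inside], expected)

    def test_trajectory_csv_round_trip(self, tmp_path, chronic_profile):
        import pandas as pd

        p = ts.make_masker_protocol(4000.0, 50.0, 30.0)
        traj = ts.simulate(p, chronic_profile)
        path = tmp_path / "traj.csv"
        traj.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == [
            "time_s", "band_hz", "stimulus_db", "percept_db", "memory_w"
        ]
        assert len(df) == len(traj.times)


class TestReconstructionOracle:
    def test_fig1_piecewise_levels(self, normal_profile):
        times, oracle = ts.reconstruct_oracle(ts.make_fig1_protocol(), normal_profile)
        assert oracle[4000.0][0] == 30.0
        assert oracle[4000.0][np.searchsorted(times, 2.0)] == 80.0
        assert oracle[4000.0][np.searchsorted(times, 4.0)] == 100.0
        assert oracle[4000.0][-1] == 50.0

    def test_zero_tl_oracle_is_raw_stimulus(self, normal_profile):
        p = ts.make_fig1_protocol()
        times, oracle = ts.reconstruct_oracle(p, normal_profile)
        assert np.array_equal(
            oracle[4000.0], [p.level_at(t, 4000.0) for t in times]
        )

    def test_rejects_gap_exceeding_memory(self, normal_profile):
        segs = (ts.Segment(0.0, (30.0,)), ts.Segment(2.0, (60.0,)))
        p = ts.StimulusProtocol(bands_hz=(4000.0,), segments=segs, duration_s=50.0)
        with pytest.raises(OracleError, match="gap"):
            ts.reconstruct_oracle(p, normal_profile)

    def test_rejects_sub_jnd_transition(self, normal_profile):
        segs = (ts.Segment(0.0, (30.0,)), ts.Segment(2.0, (31.0,)))
        p = ts.StimulusProtocol(bands_hz=(4000.0,), segments=segs, duration_s=4.0)
        with pytest.raises(OracleError, match="JND"):
            ts.reconstruct_oracle(p, normal_profile)

    def test_rejects_chronic_with_elevated_floor(self, chronic_profile):
        p = ts.make_masker_protocol(4000.0, 60.0, 5.0, 2.0, 4.0)
        with pytest.raises(OracleError, match="floor"):
            ts.reconstruct_oracle(p, chronic_profile)


@settings(max_examples=200, deadline=None)
@given(lossless_protocols())
def test_simulate_equals_reconstruction_oracle(case):
    """Differential-PCM correctness: the event-driven integrator decodes the
    stimulus exactly (bit-identical) whenever every change is audible and
    gaps stay inside sensory memory."""
    protocol, profile = case
    traj = ts.simulate(protocol, profile, sample_step=0.25)
    times, oracle = ts.reconstruct_oracle(protocol, profile, sample_step=0.25)
    assert np.array_equal(traj.times, times)
    assert np.array_equal(traj.percept[4000.0], oracle[4000.0])
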