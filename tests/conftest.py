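import hypothesis.strategies as st
import pytest
from hypothesis import assume

import tinnisim as ts


@pytest.fixture
def chronic_profile():
    """Reference chronic listener: TL = threshold = 20 dB at 4 kHz."""
    return ts.default_chronic_profile()


@pytest.fixture
def normal_profile():
    return ts.default_normal_profile()


def _effective(level, floor=0.0):
    return floor if level is None else level


@st.composite
def lossless_protocols(draw):
    """Random (protocol, profile) pairs on which the differential code is
    lossless: zero audibility floor, every consecutive level change at
    least one JND (2 dB), all inter-event gaps shorter than sensory memory
    (10 s).  Levels and times sit on a 0.25 grid so integration is exact
    in binary floating point.
    """
    chronic = draw(st.booleans())
    tl = draw(st.integers(0, 160)) * 0.25 if chronic else 0.0
    n_seg = draw(st.integers(2, 8))

    def level_values():
        return st.one_of(st.none(), st.integers(8, 480).map(lambda k: k * 0.25))

    levels = [None if chronic else draw(level_values())]
    for _ in range(n_seg - 1):
        nxt = draw(level_values())
        assume(nxt != levels[-1])
        assume(abs(_effective(nxt) - _effective(levels[-1])) >= 2.0)
        levels.append(nxt)

    gaps = [draw(st.integers(1, 19)) * 0.5 for _ in range(n_seg)]
    seg_times = [0.0]
    for g in gaps[:-1]:
        seg_times.append(seg_times[-1] + g)
    protocol = ts.StimulusProtocol(
        bands_hz=(4000.0,),
        segments=tuple(
            ts.Segment(tt, (lv,)) for tt, lv in zip(seg_times, levels)
        ),
        duration_s=seg_times[-1] + gaps[-1],
    )
    profile = ts.ListenerProfile(
        audiogram={4000.0: 0.0},
        tl={4000.0: tl},
        mode="chronic" if chronic else "acute",
    )
    return protocol, profile
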