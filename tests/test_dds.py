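import math

import pytest
from hypothesis import given, settings, strategies as st

from g2mcycle.dds import DdsState, dds_signal, dds_value


@pytest.mark.parametrize("mcc, expected_dds, arrested", [
    (0.30, 0.0, False),                    # below activation: silent
    (0.50, 200 * (0.50 - 0.36), False),    # activation branch
    (0.70, 200 * (0.70 - 0.60), True),     # arrest branch
])
def test_piecewise_branches(mcc, expected_dds, arrested):
    state = dds_signal(mcc, t=0.0)
    assert state.dds == pytest.approx(expected_dds)
    assert state.sig == pytest.approx(expected_dds)
    assert state.arrest_triggered is arrested


def test_negative_inputs_rejected():
    with pytest.raises(ValueError):
        dds_signal(-0.1, t=0.0)
    with pytest.raises(ValueError):
        dds_signal(0.1, t=-1.0)


def test_signal_decay_is_negligible_but_present():
    fresh = dds_signal(0.5, t=0.0)
    aged = dds_signal(0.5, t=1000.0)
    assert aged.sig < fresh.sig
    assert aged.sig == pytest.approx(fresh.sig * math.exp(-1e-8 * 1000.0))


def test_arrest_flag_latches():
    arrested = dds_signal(0.7, t=0.0)
    relaxed = dds_signal(0.2, t=1.0, prior=arrested)
    assert relaxed.arrest_triggered  # stays set until explicitly re-armed
    assert relaxed.dds == 0.0


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(min_value=0.0, max_value=0.599999))
def test_continuous_below_arrest_boundary(mcc):
    """DDS is continuous on [0, 0.6): the activation branch meets zero at
    0.36 from above, and nowhere below 0.6 does a jump occur."""
    h = 1e-9
    lo = dds_value(max(mcc - h, 0.0))
    hi = dds_value(min(mcc + h, 0.6 - 1e-12))
    assert abs(hi - lo) < 1e-5


def test_jump_at_arrest_boundary():
    below = dds_value(0.6)
    above = dds_value(0.6 + 1e-9)
    assert below == pytest.approx(200 * 0.24)
    assert above == pytest.approx(0.0, abs=1e-5)
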