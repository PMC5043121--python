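import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dodgekin.events import (FilterConfig, ReachEvent, detect_contact,
                             detect_onset, movement_time, savgol_smooth,
                             savgol_velocity)
from dodgekin.synthetic import minimum_jerk

CFG = FilterConfig()
HALF = CFG.window_length // 2


def _brute_onset(speed, peak, fraction=0.05):
    thr = fraction * speed[peak]
    for i in range(peak, -1, -1):
        if speed[i] <= thr:
            return i
    return None


def _brute_contact(speed, peak, fraction=0.05):
    thr = fraction * speed[peak]
    for i in range(peak, len(speed)):
        if speed[i] <= thr:
            return i
    return None


# ---------------------------------------------------------------- smoothing

def test_constant_series_preserved():
    x = np.full(100, 3.7)
    np.testing.assert_allclose(savgol_smooth(x, CFG), 3.7, atol=1e-12)


def test_quartic_reproduced_on_interior():
    t = np.arange(200) * 0.01
    x = t**4
    out = savgol_smooth(x, CFG)
    interior = slice(HALF, -HALF)
    np.testing.assert_allclose(out[interior], x[interior], rtol=1e-10)


@settings(max_examples=30, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=5, max_size=5))
def test_polynomials_up_to_degree_four_preserved(coeffs):
    """The filter is exact for its own polynomial order on interior samples."""
    t = np.linspace(-1, 1, 120)
    x = np.polyval(coeffs, t)
    out = savgol_smooth(x, CFG)
    interior = slice(HALF, -HALF)
    np.testing.assert_allclose(out[interior], x[interior],
                               atol=1e-10 * max(1.0, np.abs(x).max()))


def test_white_noise_variance_reduced(rng):
    x = rng.normal(size=4000)
    assert savgol_smooth(x, CFG).var() < x.var()


def test_short_series_raises():
    with pytest.raises(ValueError):
        savgol_smooth(np.zeros(40), CFG)


# ------------------------------------------------------------ differentiation

def test_linear_ramp_speed():
    t = np.arange(150) * CFG.sample_interval
    pos = np.zeros((150, 3))
    pos[:, 0] = 0.8 * t
    speed = savgol_velocity(pos, CFG)
    np.testing.assert_allclose(speed[HALF:-HALF], 0.8, atol=1e-10)


def test_cubic_derivative_matches_analytic():
    t = np.arange(200) * CFG.sample_interval
    pos = (t**3)[:, None]
    speed = savgol_velocity(pos, CFG)
    np.testing.assert_allclose(speed[HALF:-HALF], 3 * t[HALF:-HALF]**2,
                               atol=1e-9)


def test_circular_motion_speed():
    r, omega = 0.3, 2.0
    t = np.arange(600) * CFG.sample_interval
    pos = np.stack([r * np.cos(omega * t), r * np.sin(omega * t),
                    np.zeros_like(t)], axis=1)
    speed = savgol_velocity(pos, CFG)
    np.testing.assert_allclose(speed[HALF:-HALF], r * omega, rtol=1e-3)


# ------------------------------------------------------------------ events

def test_onset_is_last_zero_before_rise():
    # zero until sample 9, then a bell rising immediately above threshold
    speed = np.concatenate([np.zeros(10), np.linspace(0.5, 2.0, 20),
                            np.linspace(2.0, 0.5, 20)])
    peak = int(np.argmax(speed))
    res = detect_onset(speed, peak)
    assert res.found and res.index == 9


def test_min_jerk_events_match_brute_force_scan():
    _, speed = minimum_jerk(0.5, 100.0)
    speed = speed * 0.8  # 0.4 m amplitude reach
    peak = int(np.argmax(speed))
    assert detect_onset(speed, peak).index == _brute_onset(speed, peak)
    assert detect_contact(speed, peak).index == _brute_contact(speed, peak)


def test_symmetric_profile_events_equidistant_from_peak():
    _, speed = minimum_jerk(0.6, 100.0)
    peak = int(np.argmax(speed))
    on = detect_onset(speed, peak).index
    off = detect_contact(speed, peak).index
    assert peak - on == off - peak


def test_onset_degenerate_always_above_threshold():
    speed = np.linspace(1.0, 2.0, 50)
    with pytest.warns(UserWarning):
        res = detect_onset(speed, 49)
    assert res == (0, False)


def test_contact_degenerate_monotone_rise():
    speed = np.linspace(0.5, 2.0, 50)
    with pytest.warns(UserWarning):
        res = detect_contact(speed, 49)
    assert res == (49, False)


def test_event_ordering_invariant(rng):
    for _ in range(25):
        speed = np.abs(rng.normal(size=200)).cumsum()
        speed = np.concatenate([speed, speed[::-1]]) / speed.max()
        peak = int(np.argmax(speed))
        on = detect_onset(speed, peak).index
        off = detect_contact(speed, peak).index
        assert on <= peak <= off


@settings(max_examples=30, derandomize=True)
@given(st.floats(0.02, 0.3), st.floats(0.31, 0.9))
def test_threshold_monotonicity(f_low, f_high):
    """A larger threshold fraction never moves onset earlier nor contact later."""
    _, speed = minimum_jerk(0.5, 100.0)
    peak = int(np.argmax(speed))
    assert detect_onset(speed, peak, f_low).index <= \
        detect_onset(speed, peak, f_high).index
    assert detect_contact(speed, peak, f_low).index >= \
        detect_contact(speed, peak, f_high).index


def test_empty_series_raises():
    with pytest.raises(ValueError):
        detect_onset(np.array([]), 0)


# ----------------------------------------------------------- movement time

@pytest.mark.parametrize("onset,contact,expected_ms",
                         [(10, 58, 480.0), (25, 25, 0.0), (0, 66, 660.0)])
def test_movement_time_arithmetic(onset, contact, expected_ms):
    ev = ReachEvent(onset_index=onset, peak_index=contact,
                    contact_index=contact, peak_speed=1.0)
    assert movement_time(ev, 100.0) == pytest.approx(expected_ms)


def test_event_invariants_enforced():
    with pytest.raises(ValueError):
        ReachEvent(onset_index=10, peak_index=5, contact_index=20,
                   peak_speed=1.0)
    with pytest.raises(ValueError):
        ReachEvent(onset_index=0, peak_index=1, contact_index=2,
                   peak_speed=0.0)
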