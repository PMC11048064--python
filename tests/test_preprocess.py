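"""Signal-conditioning primitives: norms, filtering, RMS, onset detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mobiseg.errors import (
    InsufficientDataError,
    InvalidSignalError,
    InvalidSpecError,
    NoMovementError,
)
from mobiseg.preprocess import (
    FilterSpec,
    bump_bounds,
    lowpass_filter,
    onset_offset,
    resultant_magnitude,
    rms,
)

FS = 100.0


class TestResultantMagnitude:
    @pytest.mark.parametrize(
        "sample, expected",
        [([(3.0, 4.0, 0.0)], [5.0]), ([(0.0, 0.0, 0.0)], [0.0])],
    )
    def test_known_norms(self, sample, expected):
        assert resultant_magnitude(sample) == pytest.approx(expected)

    def test_matches_per_element_norm(self, rng):
        v = rng.normal(size=(100, 3))
        expected = [np.sqrt(a**2 + b**2 + c**2) for a, b, c in v]
        np.testing.assert_allclose(resultant_magnitude(v), expected, rtol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidSignalError):
            resultant_magnitude([(1.0, np.nan, 0.0)])

    def test_rejects_wrong_shape(self):
        with pytest.raises(InvalidSignalError):
            resultant_magnitude([(1.0, 2.0)])

    @settings(max_examples=50, derandomize=True)
    @given(
        v=arrays(float, (20, 3), elements=st.floats(-1e3, 1e3)),
        perm=st.permutations([0, 1, 2]),
        signs=st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3),
    )
    def test_invariant_under_axis_permutation_and_sign(self, v, perm, signs):
        transformed = v[:, perm] * np.array(signs)
        np.testing.assert_allclose(
            resultant_magnitude(transformed), resultant_magnitude(v), rtol=1e-9, atol=1e-9
        )


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 7.3)
        y = lowpass_filter(x, FilterSpec(), FS)
        np.testing.assert_allclose(y, 7.3, atol=1e-6)

    @pytest.mark.parametrize("f0", [10.0, 20.0])
    def test_stopband_attenuation_matches_butterworth_response(self, f0):
        # A stopband tone through a 4th-order 5 Hz low-pass applied forward
        # and backward is attenuated by the squared magnitude response
        # 1 / (1 + r^(2*order)), where r is the bilinear-transform-warped
        # frequency ratio tan(pi f/fs) / tan(pi fc/fs) of the digital
        # filter (~ f/fc well below Nyquist). The tone amplitude is read
        # off by quadrature projection over an integer number of periods,
        # away from the edges.
        t = np.arange(0, 6.0, 1 / FS)
        x = np.sin(2 * np.pi * f0 * t)
        y = lowpass_filter(x, FilterSpec(), FS)
        mid = slice(200, 400)
        n = mid.stop - mid.start
        amp = np.hypot(
            2 * np.dot(y[mid], np.sin(2 * np.pi * f0 * t[mid])) / n,
            2 * np.dot(y[mid], np.cos(2 * np.pi * f0 * t[mid])) / n,
        )
        r = np.tan(np.pi * f0 / FS) / np.tan(np.pi * 5.0 / FS)
        assert amp == pytest.approx(1.0 / (1.0 + r**8), rel=0.05)
        # and agrees with the analog prototype response to within its warp
        assert amp == pytest.approx(1.0 / (1.0 + (f0 / 5.0) ** 8), rel=0.7)

    def test_zero_phase_impulse_response_is_symmetric(self):
        x = np.zeros(401)
        x[200] = 1.0
        y = lowpass_filter(x, FilterSpec(), FS)
        np.testing.assert_allclose(y, y[::-1], atol=1e-9)

    def test_zero_phase_has_no_lag(self):
        # Cross-correlation between a band-limited input and its filtered
        # output peaks at zero lag.
        t = np.arange(0, 5.0, 1 / FS)
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_filter(x, FilterSpec(), FS)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[20:-20], y[20 + k : len(y) - 20 + k]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_causal_option_delays_the_signal(self):
        x = np.zeros(401)
        x[200] = 1.0
        y = lowpass_filter(x, FilterSpec(zero_phase=False), FS)
        assert int(np.argmax(y)) > 200

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidSpecError):
            lowpass_filter(np.zeros(100), FilterSpec(cutoff_hz=60.0), FS)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            lowpass_filter(np.zeros(10), FilterSpec(), FS)


class TestRms:
    @pytest.mark.parametrize(
        "x, expected", [([1, -1, 1, -1], 1.0), ([0, 0, 0], 0.0), ([3.0], 3.0)]
    )
    def test_known_values(self, x, expected):
        assert rms(x) == pytest.approx(expected)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=257)
        expected = np.sqrt(sum(v * v for v in x) / len(x))
        assert rms(x) == pytest.approx(expected, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            rms([])

    @settings(max_examples=50, derandomize=True)
    @given(
        x=arrays(float, 30, elements=st.floats(-1e3, 1e3)),
        c=st.floats(-10, 10),
        perm=st.permutations(range(30)),
    )
    def test_scale_equivariance_and_permutation_invariance(self, x, c, perm):
        assert rms(c * x) == pytest.approx(abs(c) * rms(x), rel=1e-9, abs=1e-9)
        assert rms(x[list(perm)]) == pytest.approx(rms(x), rel=1e-12)


class TestOnsetOffset:
    def test_flat_series_raises_no_movement(self):
        with pytest.raises(NoMovementError):
            onset_offset(np.zeros(500), FS, min_delta=0.1)

    def test_step_onset_recovered(self, rng):
        t = np.arange(0, 5.0, 1 / FS)
        x = rng.normal(0, 0.05, t.size)
        x[t >= 2.0] += 10.0
        onset, _ = onset_offset(x, FS)
        assert onset / FS == pytest.approx(2.0, abs=0.05)

    def test_burst_offset_recovered(self, rng):
        t = np.arange(0, 5.0, 1 / FS)
        x = rng.normal(0, 0.05, t.size)
        x[(t >= 1.0) & (t < 3.0)] += 10.0
        onset, offset = onset_offset(x, FS)
        assert onset / FS == pytest.approx(1.0, abs=0.05)
        assert offset / FS == pytest.approx(3.0, abs=0.05)
        assert onset < offset

    def test_brief_spike_ignored(self):
        x = np.zeros(500)
        x[250:253] = 10.0  # 30 ms << the 100 ms sustain requirement
        with pytest.raises(NoMovementError):
            onset_offset(x, FS, min_delta=0.1)

    def test_series_shorter_than_baseline_rejected(self):
        with pytest.raises(InsufficientDataError):
            onset_offset(np.zeros(30), FS, baseline_window_s=0.5)


class TestBumpBounds:
    @pytest.mark.parametrize("start, dur, amp, base", [(2.0, 1.5, 80.0, 0.0), (3.0, 2.5, 90.0, 10.0)])
    def test_raised_cosine_bounds_exact(self, start, dur, amp, base):
        t = np.arange(0, 8.0, 1 / FS)
        inside = (t >= start) & (t <= start + dur)
        x = np.full(t.size, base)
        x[inside] += 0.5 * amp * (1 - np.cos(2 * np.pi * (t[inside] - start) / dur))
        peak = int(np.argmax(x))
        b = bump_bounds(x, FS, peak, base=base)
        assert b.onset == pytest.approx(start, abs=0.02)
        assert b.end == pytest.approx(start + dur, abs=0.02)
        assert b.apex == pytest.approx(start + dur / 2, abs=0.02)
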