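import numpy as np
import pytest

import spikephase as sp

FS = 44000.0
BAND = (300.0, 6000.0)


def _direct_form_sos(sos, x):
    """Independent oracle: direct-form II transposed recursion per section."""
    y = np.asarray(x, dtype=np.float64)
    for b0, b1, b2, a0, a1, a2 in sos:
        out = np.empty_like(y)
        z1 = z2 = 0.0
        for n, xn in enumerate(y):
            yn = b0 * xn + z1
            z1 = b1 * xn - a1 * yn + z2
            z2 = b2 * xn - a2 * yn
            out[n] = yn
        y = out
    return y


class TestDesignFilter:
    def test_butterworth_minus_3db_at_edges(self, nlp_filter):
        mags = sp.magnitude_response(nlp_filter, np.array(BAND))
        assert np.allclose(mags, 1 / np.sqrt(2), atol=1e-6)

    def test_butterworth_passband_flat(self, nlp_filter):
        assert sp.magnitude_response(nlp_filter, [1500.0])[0] > 0.99

    def test_fir_taps_symmetric(self, lp_filter):
        taps = lp_filter.taps
        assert len(taps) == 21
        assert np.array_equal(taps, taps[::-1])

    def test_band_edge_validation(self):
        with pytest.raises(sp.ValidationError):
            sp.FilterSpec("NLP", "butterworth", 4, (300.0, 22000.0), FS)

    def test_four_poles(self, nlp_filter):
        assert nlp_filter.poles().size == 4


class TestApplyCausal:
    def test_strict_causality(self, nlp_filter):
        x = np.zeros(500)
        x[100] = 1.0
        out = sp.apply_causal(sp.ContinuousSignal(x, FS), nlp_filter)
        assert np.all(out.samples[:100] == 0)
        assert out.n_samples == 500

    def test_sinusoid_delayed_by_phase_delay(self, nlp_filter):
        # a steady-state sinusoid is shifted by the phase delay -phi/omega
        f0 = 1000.0
        t = np.arange(int(0.2 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        y = sp.apply_causal(sp.ContinuousSignal(x, FS), nlp_filter).samples
        mid = slice(4000, 8000)
        lags = np.arange(-40, 41)
        xc = [np.dot(y[mid], np.roll(x, lag)[mid]) for lag in lags]
        i = int(np.argmax(xc))
        best = lags[i] + 0.5 * (xc[i - 1] - xc[i + 1]) / (xc[i - 1] - 2 * xc[i] + xc[i + 1])
        phase = sp.phase_response(nlp_filter, [f0])[0]
        expected = -phase / (2 * np.pi * f0 / FS)
        assert abs(best - expected) <= 0.5

    def test_tone_burst_delayed_by_group_delay(self, nlp_filter):
        # the *envelope* of a narrow-band burst is shifted by the group delay
        from scipy.signal import hilbert

        f0 = 1000.0
        t = np.arange(int(0.2 * FS)) / FS
        env = np.exp(-((t - 0.1) ** 2) / (2 * 0.002**2))
        x = env * np.cos(2 * np.pi * f0 * (t - 0.1))
        y = sp.apply_causal(sp.ContinuousSignal(x, FS), nlp_filter).samples
        ex, ey = np.abs(hilbert(x)), np.abs(hilbert(y))
        lags = np.arange(-20, 31)
        xc = [np.dot(ey, np.roll(ex, lag)) for lag in lags]
        i = int(np.argmax(xc))
        best = lags[i] + 0.5 * (xc[i - 1] - xc[i + 1]) / (xc[i - 1] - 2 * xc[i] + xc[i + 1])
        expected = sp.group_delay(nlp_filter, [f0])[0]
        assert abs(best - expected) <= 0.5

    def test_matches_direct_form_oracle(self, nlp_filter, rng):
        x = rng.standard_normal(2000)
        ours = sp.apply_causal(sp.ContinuousSignal(x, FS), nlp_filter).samples
        oracle = _direct_form_sos(nlp_filter.sos, x)
        assert np.linalg.norm(ours - oracle) <= 1e-9 * np.linalg.norm(oracle)

    def test_fs_mismatch(self, nlp_filter):
        with pytest.raises(sp.ValidationError):
            sp.apply_causal(sp.ContinuousSignal(np.zeros(10), fs=1000.0), nlp_filter)


class TestApplyZeroPhase:
    def test_zero_lag_on_interior_sinusoid(self, zp_filter):
        f0 = 1000.0
        t = np.arange(int(0.2 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        y = sp.apply_zero_phase(sp.ContinuousSignal(x, FS), zp_filter).samples
        mid = slice(4000, 8000)
        lags = np.arange(-20, 21)
        xc = [np.dot(y[mid], np.roll(x, lag)[mid]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_gain_is_h_squared(self, zp_filter):
        f0 = 1000.0
        t = np.arange(int(0.5 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        y = sp.apply_zero_phase(sp.ContinuousSignal(x, FS), zp_filter).samples
        mid = slice(8000, len(x) - 8000)
        gain = np.sqrt(np.mean(y[mid] ** 2) / np.mean(x[mid] ** 2))
        # ZP magnitude_response already reports |H|^2
        assert gain == pytest.approx(sp.magnitude_response(zp_filter, [f0])[0], rel=1e-3)

    def test_dc_removed(self, zp_filter):
        x = np.full(int(0.2 * FS), 5.0)
        y = sp.apply_zero_phase(sp.ContinuousSignal(x, FS), zp_filter).samples
        assert np.max(np.abs(y[4000:-4000])) < 1e-6

    def test_requires_recursive(self, lp_filter):
        with pytest.raises(sp.ValidationError):
            sp.apply_zero_phase(sp.ContinuousSignal(np.zeros(100), FS), lp_filter)

    def test_equivalence_to_reversed_causal_composition(self, nlp_filter, zp_filter, rng):
        # forward pass + reversed second pass == scipy's filtfilt route,
        # away from the edges
        x = rng.standard_normal(int(FS))
        sig = sp.ContinuousSignal(x, FS)
        route_a = sp.apply_zero_phase(sig, zp_filter).samples
        causal = sp.apply_causal(sig, nlp_filter)
        route_b = sp.correct_continuous(causal, nlp_filter).samples
        interior = slice(2000, -2000)
        diff = np.linalg.norm(route_a[interior] - route_b[interior])
        assert diff <= 1e-9 * np.linalg.norm(route_a[interior])


class TestPhaseResponse:
    def test_zp_identically_zero(self, zp_filter):
        freqs = np.linspace(100, 10000, 50)
        assert np.all(sp.phase_response(zp_filter, freqs) == 0)

    def test_fir_phase_exactly_linear_in_passband(self, lp_filter):
        freqs = np.linspace(400, 5500, 200)
        phase = sp.phase_response(lp_filter, freqs)
        coeffs = np.polyfit(freqs, phase, 1)
        residual = phase - np.polyval(coeffs, freqs)
        assert np.max(np.abs(residual)) < 1e-9

    def test_butterworth_phase_nonlinear(self, nlp_filter):
        freqs = np.linspace(300, 6000, 400)
        phase = sp.phase_response(nlp_filter, freqs)
        coeffs = np.polyfit(freqs, phase, 1)
        residual = phase - np.polyval(coeffs, freqs)
        assert np.max(np.abs(residual)) > 0.1

    def test_out_of_range_rejected(self, nlp_filter):
        with pytest.raises(sp.ValidationError):
            sp.phase_response(nlp_filter, [0.0])


class TestGroupDelay:
    def test_fir_constant_half_order(self, lp_filter):
        freqs = np.linspace(400, 5500, 100)
        assert np.allclose(sp.group_delay(lp_filter, freqs), 10.0, atol=1e-6)

    def test_zp_zero(self, zp_filter):
        assert np.all(sp.group_delay(zp_filter, [500.0, 2000.0]) == 0)

    def test_butterworth_delay_varies(self, nlp_filter):
        freqs = np.linspace(300, 6000, 200)
        assert np.std(sp.group_delay(nlp_filter, freqs)) > 0


class TestFig2Property:
    """Summing three passband sinusoids: ZP superimposes on the input, LP is
    a pure shift, NLP is not a shift of the input."""

    @pytest.fixture(scope="class")
    def three_tone(self):
        t = np.arange(int(0.5 * FS)) / FS
        x = sum(np.sin(2 * np.pi * f * t) for f in (500.0, 1000.0, 2000.0))
        return sp.ContinuousSignal(x, FS)

    @staticmethod
    def _min_shift_distance(y, x, max_shift=200):
        interior = slice(5000, -5000)
        best = np.inf
        for lag in range(-max_shift, max_shift + 1):
            d = np.linalg.norm(y[interior] - np.roll(x, lag)[interior])
            best = min(best, d / np.linalg.norm(x[interior]))
        return best

    def test_zp_superimposes(self, three_tone, zp_filter):
        y = sp.apply_zero_phase(three_tone, zp_filter).samples
        interior = slice(5000, -5000)
        d = np.linalg.norm(y[interior] - three_tone.samples[interior])
        assert d / np.linalg.norm(three_tone.samples[interior]) < 0.05

    def test_lp_is_pure_shift(self, three_tone, lp_filter):
        y = sp.apply_causal(three_tone, lp_filter).samples
        x = three_tone.samples
        interior = slice(5000, -5000)
        d = np.linalg.norm(y[interior] - np.roll(x, 10)[interior])
        # magnitude response shrinks the tones slightly; rescale first
        scale = np.dot(y[interior], np.roll(x, 10)[interior]) / np.dot(
            np.roll(x, 10)[interior], np.roll(x, 10)[interior]
        )
        d_scaled = np.linalg.norm(y[interior] - scale * np.roll(x, 10)[interior])
        assert d_scaled / np.linalg.norm(x[interior]) < 0.05
        assert d / np.linalg.norm(x[interior]) < 0.2

    def test_nlp_is_not_a_shift(self, three_tone, nlp_filter):
        y = sp.apply_causal(three_tone, nlp_filter).samples
        assert self._min_shift_distance(y, three_tone.samples) > 0.05
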