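"""Artifact interpolation, zero-phase filtering, bad-channel exclusion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpmosc.preprocess import (
    bandpass_filter,
    exclude_bad_channels,
    interpolate_artifact,
    notch_filter,
    notch_freqs_for_site,
)

from .conftest import make_recording, sinusoid_recording

SPAN = (0.0, 0.070)


def _amp(rec, freq):
    """Amplitude of a sinusoidal component, interior samples only."""
    t = rec.times
    interior = (t > -1.5) & (t < 5.5)
    x = rec.data[0, 0, interior]
    ref = np.exp(2j * np.pi * freq * t[interior])
    return 2 * np.abs(np.mean(x * ref))


class TestInterpolateArtifact:
    def test_linear_ramp_is_fixed_point(self):
        t = -2.0 + np.arange(2400) / 300.0
        ramp = (3.0 * t + 1.0)[None, None, :]
        rec = make_recording(ramp)
        out = interpolate_artifact(rec, SPAN)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-12)

    def test_spike_on_flat_background_is_flattened(self):
        t = -2.0 + np.arange(2400) / 300.0
        b = 4.2
        data = np.full((1, 1, t.size), b)
        spike = (t >= 0) & (t <= 0.07)
        data[0, 0, spike] += 10 * b
        out = interpolate_artifact(make_recording(data), SPAN)
        np.testing.assert_allclose(out.data[0, 0], b, atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_two_point_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fs = 300.0
        data = rng.standard_normal((2, 3, 2400))
        rec = make_recording(data, sampling_rate=fs)
        out = interpolate_artifact(rec, SPAN)
        t = rec.times
        inside = np.nonzero((t >= SPAN[0]) & (t <= SPAN[1]))[0]
        i0, i1 = inside[0] - 1, inside[-1] + 1
        for tr in range(2):
            for ch in range(3):
                expect = np.interp(
                    t[inside], [t[i0], t[i1]], [data[tr, ch, i0], data[tr, ch, i1]]
                )
                np.testing.assert_allclose(out.data[tr, ch, inside], expect, atol=1e-12)
        # everything outside the span is untouched, exactly
        outside = np.setdiff1d(np.arange(t.size), inside)
        np.testing.assert_array_equal(out.data[..., outside], data[..., outside])

    def test_span_at_epoch_boundary_is_rejected(self):
        rec = make_recording(np.zeros((1, 1, 2400)))
        with pytest.raises(ValueError):
            interpolate_artifact(rec, (-2.0, 0.07))


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = sinusoid_recording(10.0)
        out = bandpass_filter(rec, 1.0, 200.0)
        assert _amp(out, 10.0) == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_removed(self):
        rec = sinusoid_recording(0.2)
        out = bandpass_filter(rec, 1.0, 200.0)
        assert _amp(out, 0.2) < 0.1  # >= 90% attenuation at 0.2 Hz

    def test_refiltering_white_noise_matches_response_prediction(self):
        # idempotence in the passband: a second pass removes only the
        # residual transition-band energy.  The expected RMS change is
        # derived from the designed filter's own magnitude response
        # (zero-phase application squares it) and the measured change
        # must match that prediction.
        from scipy import signal as sps

        fs = 600.0
        sos = sps.butter(4, [1.0, 200.0], btype="bandpass", fs=fs, output="sos")
        w, h = sps.sosfreqz(sos, worN=8192, fs=fs)
        h2 = np.abs(h) ** 2  # one zero-phase pass
        predicted = np.sqrt(np.trapezoid(h2**4, w) / np.trapezoid(h2**2, w))
        rng = np.random.default_rng(0)
        rec = make_recording(rng.standard_normal((1, 1, 4800)), sampling_rate=fs)
        once = bandpass_filter(rec, 1.0, 200.0)
        twice = bandpass_filter(once, 1.0, 200.0)
        interior = slice(300, -300)
        rms1 = np.sqrt(np.mean(once.data[0, 0, interior] ** 2))
        rms2 = np.sqrt(np.mean(twice.data[0, 0, interior] ** 2))
        assert rms2 / rms1 == pytest.approx(predicted, abs=0.01)
        assert 1 - rms2 / rms1 < 0.05  # the change is small

    def test_idempotent_for_in_band_tone(self):
        rec = sinusoid_recording(10.0)
        once = bandpass_filter(rec, 1.0, 200.0)
        twice = bandpass_filter(once, 1.0, 200.0)
        assert _amp(twice, 10.0) == pytest.approx(_amp(once, 10.0), rel=1e-3)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 1, 2400))
        y = rng.standard_normal((1, 1, 2400))
        fa, fb = 2.0, -0.7
        out_sum = bandpass_filter(make_recording(fa * x + fb * y), 1.0, 120.0)
        out_x = bandpass_filter(make_recording(x), 1.0, 120.0)
        out_y = bandpass_filter(make_recording(y), 1.0, 120.0)
        np.testing.assert_allclose(
            out_sum.data, fa * out_x.data + fb * out_y.data, atol=1e-9
        )

    def test_upper_edge_at_nyquist_rejected(self):
        rec = make_recording(np.zeros((1, 1, 2400)))
        with pytest.raises(ValueError):
            bandpass_filter(rec, 1.0, 150.0)  # Nyquist at fs=300


class TestNotch:
    def test_line_frequency_removed(self):
        rec = sinusoid_recording(60.0)
        out = notch_filter(rec, [60.0])
        assert _amp(out, 60.0) <= 0.05

    def test_distant_tone_untouched(self):
        rec = sinusoid_recording(10.0)
        out = notch_filter(rec, [60.0])
        assert _amp(out, 10.0) == pytest.approx(1.0, rel=0.02)

    @pytest.mark.parametrize("f", [58.0, 62.0])
    def test_neighboring_bands_preserved(self, f):
        rec = sinusoid_recording(f)
        out = notch_filter(rec, [60.0])
        assert _amp(out, f) == pytest.approx(1.0, rel=0.10)

    def test_site_mapping(self):
        assert notch_freqs_for_site("MNI") == (60.0, 120.0, 180.0)
        assert notch_freqs_for_site("Donders") == (50.0, 100.0, 150.0, 200.0)
        with pytest.raises(KeyError):
            notch_freqs_for_site("elsewhere")

    def test_frequency_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((1, 1, 2400)))  # fs=300
        with pytest.raises(ValueError):
            notch_filter(rec, [180.0])


class TestBadChannels:
    def test_outlier_rms_channel_excluded(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((3, 5, 1200))
        data[:, 2, :] *= 100.0
        rec = make_recording(data)
        out = exclude_bad_channels(rec)
        assert out.excluded_channels == ["ch03"]
        assert out.n_channels == 4
        assert "ch03" not in out.channel_names

    def test_clean_data_keeps_all_channels(self):
        rng = np.random.default_rng(3)
        rec = make_recording(rng.standard_normal((3, 5, 1200)))
        out = exclude_bad_channels(rec)
        assert out.excluded_channels == []
        assert out.n_channels == 5

    def test_unknown_explicit_channel_errors(self):
        rec = make_recording(np.zeros((1, 2, 600)))
        with pytest.raises(KeyError):
            exclude_bad_channels(rec, channels=["nope"])

    def test_cannot_exclude_everything(self):
        rec = make_recording(np.ones((1, 2, 600)))
        with pytest.raises(ValueError):
            exclude_bad_channels(rec, channels=["ch01", "ch02"])
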