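"""Morlet decomposition, baseline z-scoring, averaging, evoked means."""

import math

import numpy as np
import pytest
from scipy.signal import fftconvolve

from cpmosc.tfr import (
    Spectrogram,
    WaveletSpec,
    average_z,
    edge_mask,
    evoked_average,
    morlet_tfr,
    sigma_t,
    zscore_baseline,
)

from .conftest import make_recording, sinusoid_recording


def test_sigma_t_closed_form():
    expected_1hz = 3.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    assert sigma_t(1.0) == pytest.approx(expected_1hz, abs=1e-12)
    assert sigma_t(20.0) == pytest.approx(expected_1hz / 20.0, abs=1e-12)


def test_zero_signal_gives_zero_magnitudes():
    rec = make_recording(np.zeros((2, 1, 2400)))
    sp = morlet_tfr(rec, freqs=np.arange(5.0, 40.0, 5.0))
    assert np.allclose(sp.values, 0.0, atol=1e-12)


def test_unit_sinusoid_plateau_and_off_band_rejection():
    rec = sinusoid_recording(10.0)
    sp = morlet_tfr(rec)
    interior = (sp.times > -0.5) & (sp.times < 4.5)
    plateau = sp.values[0, 0, np.argmin(np.abs(sp.freqs - 10.0)), interior]
    assert plateau.mean() == pytest.approx(1.0, rel=0.02)
    off = sp.values[0, 0, np.argmin(np.abs(sp.freqs - 40.0)), interior]
    assert off.max() < 0.01


def test_magnitude_linear_in_amplitude():
    sp1 = morlet_tfr(sinusoid_recording(10.0, amplitude=1.0), freqs=np.array([10.0]))
    sp2 = morlet_tfr(sinusoid_recording(10.0, amplitude=2.0), freqs=np.array([10.0]))
    interior = (sp1.times > -0.5) & (sp1.times < 4.5)
    ratio = sp2.values[0, 0, 0, interior].mean() / sp1.values[0, 0, 0, interior].mean()
    assert ratio == pytest.approx(2.0, rel=0.02)


@pytest.mark.parametrize("f0", [5.0, 10.0, 20.0, 40.0])
def test_frequency_localization(f0):
    rec = sinusoid_recording(f0)
    sp = morlet_tfr(rec)
    interior = (sp.times > -0.5) & (sp.times < 4.5)
    profile = sp.values[0, 0, :, interior].mean(axis=0)
    assert sp.freqs[np.argmax(profile)] == pytest.approx(f0)


def test_matches_direct_convolution_oracle():
    # independent oracle: time-domain complex Morlet convolution with
    # the same reflection padding
    rng = np.random.default_rng(4)
    fs = 300.0
    x = rng.standard_normal(2400)
    rec = make_recording(x[None, None, :], sampling_rate=fs)
    freqs = np.array([6.0, 11.0, 23.0])
    sp = morlet_tfr(rec, freqs=freqs)
    pad = int(np.ceil(5 * sigma_t(freqs.min()) * fs))
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -2 - pad : -1]])
    for j, f in enumerate(freqs):
        st_ = sigma_t(f)
        half = int(np.ceil(5 * st_ * fs))
        tt = np.arange(-half, half + 1) / fs
        w = np.exp(-(tt**2) / (2 * st_**2)) * np.exp(2j * np.pi * f * tt)
        w *= 2.0 / (st_ * np.sqrt(2 * np.pi) * fs)
        y = np.abs(fftconvolve(xp, w, mode="same"))[pad : pad + x.size]
        np.testing.assert_allclose(sp.values[0, 0, j], y, atol=2e-4)


def test_decimated_grid_keeps_plateau_and_spacing():
    rec = sinusoid_recording(10.0)
    sp = morlet_tfr(rec, decim=4)
    steps = np.diff(sp.times)
    assert np.allclose(steps, steps[0])
    assert steps[0] == pytest.approx(4 / 600.0, rel=0.2)
    interior = (sp.times > -0.5) & (sp.times < 4.5)
    plateau = sp.values[0, 0, np.argmin(np.abs(sp.freqs - 10.0)), interior]
    assert plateau.mean() == pytest.approx(1.0, rel=0.02)


def test_frequency_at_or_above_nyquist_rejected():
    rec = make_recording(np.zeros((1, 1, 2400)))  # fs = 300
    with pytest.raises(ValueError):
        morlet_tfr(rec, freqs=np.array([150.0]))


def test_edge_mask_flags_only_low_frequency_borders():
    freqs = np.array([2.0, 30.0])
    times = np.linspace(-2.0, 6.0, 241)
    m = edge_mask(freqs, times)
    assert m[0].sum() > m[1].sum()  # wider wavelets flag more bins
    assert not m[:, 120].any()  # epoch centre is clean


class TestZScore:
    def _random_spect(self, rng, n_trials=3, n_ch=2, n_f=4, n_t=240):
        values = np.abs(rng.standard_normal((n_trials, n_ch, n_f, n_t))) + 0.5
        times = np.linspace(-2.0, 6.0, n_t)
        return Spectrogram(
            values=values,
            freqs=np.arange(1.0, n_f + 1),
            times=times,
            dims=("trial", "channel"),
        )

    def test_baseline_bins_have_mean_zero_sd_one(self):
        z = zscore_baseline(self._random_spect(np.random.default_rng(5)))
        mask = z.time_slice(-1.5, -0.5)
        base = z.values[..., mask]
        assert np.abs(base.mean(axis=-1)).max() < 1e-9
        assert np.abs(base.std(axis=-1, ddof=1) - 1.0).max() < 1e-9

    def test_z_value_arithmetic(self):
        # baseline mean 2, sd 0.5; a post-stimulus value of 3.5 -> z = 3
        n_t = 240
        times = np.linspace(-2.0, 6.0, n_t)
        values = np.full((1, 1, 1, n_t), 2.0)
        bmask = (times >= -1.5) & (times <= -0.5)
        idx = np.nonzero(bmask)[0]
        # +-d on an even number of baseline bins (any leftover bin stays
        # at 2.0) gives baseline mean exactly 2 and sd(ddof=1) exactly 0.5
        m = idx.size
        k = m // 2
        d = 0.5 * math.sqrt((m - 1) / (2 * k))
        signs = np.tile([1.0, -1.0], k)
        values[0, 0, 0, idx[: 2 * k]] = 2.0 + d * signs
        post = np.argmin(np.abs(times - 2.0))
        values[0, 0, 0, post] = 3.5
        sp = Spectrogram(values=values, freqs=np.array([10.0]), times=times,
                         dims=("trial", "channel"))
        z = zscore_baseline(sp)
        assert z.values[0, 0, 0, post] == pytest.approx(3.0, abs=1e-9)

    def test_constant_trace_raises_naming_location(self):
        n_t = 240
        times = np.linspace(-2.0, 6.0, n_t)
        values = np.abs(np.random.default_rng(6).standard_normal((1, 2, 2, n_t))) + 1
        values[0, 1, 0, :] = 7.0  # constant -> zero baseline variance
        sp = Spectrogram(values=values, freqs=np.array([5.0, 6.0]), times=times,
                         dims=("trial", "channel"))
        with pytest.raises(ValueError, match="zero baseline variance"):
            zscore_baseline(sp)


class TestAveraging:
    def _zmaps(self, values, times=None):
        n_t = values.shape[-1]
        times = times if times is not None else np.linspace(-2.0, 6.0, n_t)
        sp = Spectrogram(values=np.asarray(values, float),
                         freqs=np.arange(1.0, values.shape[-2] + 1),
                         times=times, dims=("trial",))
        return sp

    def test_single_trial_average_is_identity(self):
        rng = np.random.default_rng(7)
        sp = self._zmaps(np.abs(rng.standard_normal((1, 3, 240))) + 0.5)
        z = zscore_baseline(sp)
        avg = average_z(z, "trial")
        np.testing.assert_array_equal(avg.values, z.values[0])

    def test_opposite_maps_cancel(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((1, 3, 240))
        sp = self._zmaps(np.concatenate([v, -v], axis=0))
        avg = sp.mean_over("trial")
        np.testing.assert_allclose(avg.values, 0.0, atol=1e-12)

    def test_null_trial_average_shrinks_baseline_sd_like_sqrt_n(self):
        # central-limit check: averaging n independent z-maps leaves
        # baseline mean 0 but shrinks the sd to ~ 1/sqrt(n)
        rng = np.random.default_rng(9)
        n = 100
        sp = self._zmaps(np.abs(rng.standard_normal((n, 2, 480))) + 0.5)
        z = zscore_baseline(sp)
        avg = average_z(z, "trial")
        mask = avg.time_slice(-1.5, -0.5)
        sd = avg.values[..., mask].std(axis=-1, ddof=1)
        assert np.all(np.abs(sd - 1 / math.sqrt(n)) < 0.35 / math.sqrt(n))


class TestEvokedAverage:
    def test_constant_offset_trials_vanish(self):
        data = np.full((4, 2, 2400), 3.3)
        rec = make_recording(data)
        np.testing.assert_allclose(evoked_average(rec), 0.0, atol=1e-12)

    def test_single_trial_is_baseline_corrected_itself(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((1, 1, 2400))
        rec = make_recording(data)
        out = evoked_average(rec)
        mask = rec.times <= 0.0
        expected = data[0] - data[0][:, mask].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_transient_recovered_as_trials_accumulate(self):
        rng = np.random.default_rng(11)
        fs = 300.0
        t = -2.0 + np.arange(2400) / fs
        transient = 2.0 * np.exp(-((t - 0.15) ** 2) / (2 * 0.02**2))
        data = rng.standard_normal((200, 1, 2400)) + transient[None, None, :]
        out = evoked_average(make_recording(data, sampling_rate=fs))
        peak = out[0, np.argmin(np.abs(t - 0.15))]
        assert peak == pytest.approx(2.0, abs=0.25)
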