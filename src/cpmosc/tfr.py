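"""Morlet wavelet time-frequency decomposition and baseline z-scoring.

The mother wavelet is defined by its central frequency ``fc`` (1 Hz) and
its temporal full width at half maximum ``fwhm_tc`` (3 s); at analysis
frequency f the temporal Gaussian standard deviation scales as

    sigma_t(f) = fwhm_tc / (2 sqrt(2 ln 2)) * fc / f

Wavelets are amplitude-normalized so a unit-amplitude sinusoid at f
yields a plateau magnitude of 1 at the f bin.  Convolution is computed
in the frequency domain: the epoch is reflection-padded by half the
longest wavelet support, Fourier-transformed once, multiplied by each
wavelet's spectrum (a Gaussian centred on f), and the product -- which
is nonzero only in a narrow band around f -- is inverted with a small
FFT.  This yields the exact band-limited complex envelope on a uniform,
optionally decimated time grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, ifft, next_fast_len

from .containers import EpochedRecording

__all__ = [
    "WaveletSpec",
    "Spectrogram",
    "ZSpectrogram",
    "sigma_t",
    "morlet_tfr",
    "zscore_baseline",
    "average_z",
    "grand_average",
    "evoked_average",
    "edge_mask",
]


@dataclass
class WaveletSpec:
    """Morlet wavelet family: central frequency (Hz) and temporal FWHM (s)
    of the mother wavelet."""

    central_frequency: float = 1.0
    fwhm_tc: float = 3.0

    def __post_init__(self) -> None:
        if self.central_frequency <= 0 or self.fwhm_tc <= 0:
            raise ValueError("central_frequency and fwhm_tc must be > 0")


def sigma_t(freq: float, spec: WaveletSpec = WaveletSpec()) -> float:
    """Temporal Gaussian sd (s) of the wavelet at ``freq``."""
    s_fc = spec.fwhm_tc / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return s_fc * spec.central_frequency / freq


@dataclass
class Spectrogram:
    """Magnitude time-frequency map with named leading axes.

    ``values`` has shape ``(*leading, n_freqs, n_times)`` where the
    leading axes are named by ``dims`` (e.g. ``("trial", "channel")``).
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    dims: tuple[str, ...] = ()
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != len(self.dims) + 2:
            raise ValueError(
                f"values ndim {self.values.ndim} does not match dims {self.dims} + (freq, time)"
            )
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("frequency and time grids must be strictly increasing")

    @property
    def time_step(self) -> float:
        return float(self.times[1] - self.times[0])

    def axis_of(self, dim: str) -> int:
        return self.dims.index(dim)

    def mean_over(self, dim: str) -> "Spectrogram":
        """Element-wise average over one named leading axis."""
        ax = self.axis_of(dim)
        out = dict(
            values=self.values.mean(axis=ax),
            freqs=self.freqs,
            times=self.times,
            dims=tuple(d for i, d in enumerate(self.dims) if i != ax),
            channel_names=None if dim == "channel" else self.channel_names,
        )
        if isinstance(self, ZSpectrogram):
            out["baseline_window"] = self.baseline_window
        return type(self)(**out)

    def time_slice(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask over the time grid for [t0, t1]."""
        return (self.times >= t0) & (self.times <= t1)

    def freq_slice(self, f0: float, f1: float) -> np.ndarray:
        return (self.freqs >= f0) & (self.freqs <= f1)


@dataclass
class ZSpectrogram(Spectrogram):
    """Spectrogram in baseline z-score units."""

    baseline_window: tuple[float, float] = (-1.5, -0.5)


def _wavelet_band(
    freq: float, fs: float, n_fft: int, spec: WaveletSpec, n_sigma: float = 5.0
) -> tuple[int, np.ndarray]:
    """Spectrum of the analytic Morlet wavelet at ``freq`` on the rfft
    grid of ``n_fft``, restricted to its support band.

    Returns (first bin index, complex spectral gains over the band).
    The wavelet's continuous spectrum is a Gaussian centred at ``freq``
    with sd ``sigma_f = 1 / (2 pi sigma_t)``; bins beyond ``n_sigma``
    sds carry < 1e-5 of the peak gain and are dropped.  The gain is
    scaled so a unit sinusoid at ``freq`` has plateau magnitude 1.
    """
    st = sigma_t(freq, spec)
    sf = 1.0 / (2.0 * math.pi * st)
    df = fs / n_fft
    k0 = max(0, int(math.floor((freq - n_sigma * sf) / df)))
    k1 = min(n_fft // 2, int(math.ceil((freq + n_sigma * sf) / df)))
    f_bins = np.arange(k0, k1 + 1) * df
    # Continuous-time wavelet w(t) = s * exp(-t^2 / 2 st^2) exp(i 2 pi f t),
    # s = 2 / (st sqrt(2 pi)); FT: W(nu) = s * st sqrt(2 pi) exp(-2 pi^2 st^2 (nu-f)^2)
    #                                    = 2 exp(-(nu - f)^2 / (2 sf^2)).
    # Discrete conv multiplies by fs relative to the continuous integral,
    # and the analysis normalization divides by fs again, so the gains
    # apply directly to the signal's DFT coefficients.
    gains = 2.0 * np.exp(-((f_bins - freq) ** 2) / (2.0 * sf**2))
    return k0, gains.astype(complex)


def morlet_tfr(
    rec: EpochedRecording,
    freqs: np.ndarray | None = None,
    spec: WaveletSpec = WaveletSpec(),
    decim: int = 1,
    channels: list[str] | None = None,
    dtype=np.float64,
) -> Spectrogram:
    """Per-trial Morlet magnitude spectrograms.

    Parameters
    ----------
    rec : EpochedRecording
        Epoched data; all trials and the selected channels are analysed.
    freqs : array-like of float, optional
        Analysis frequencies in Hz (default 1..60 in 1-Hz steps, capped
        below Nyquist).
    spec : WaveletSpec
        Mother-wavelet definition.
    decim : int
        Approximate decimation factor of the output time grid relative
        to the sampling rate.  The grid is never decimated below twice
        the widest wavelet bandwidth, so the envelope is preserved.
    channels : list of str, optional
        Subset of channels to analyse (default: all).

    Returns
    -------
    Spectrogram with dims ("trial", "channel") and values of shape
    (n_trials, n_channels, n_freqs, n_times).
    """
    fs = rec.sampling_rate
    nyq = fs / 2.0
    if freqs is None:
        freqs = np.arange(1.0, min(61.0, nyq))
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= nyq):
        raise ValueError(f"analysis frequencies must be < Nyquist ({nyq} Hz)")
    if np.any(freqs <= 0):
        raise ValueError("analysis frequencies must be positive")

    ch_idx = rec.channel_index(channels)
    x = rec.data[:, ch_idx, :]
    n_trials, n_ch, n_samp = x.shape
    x2 = x.reshape(-1, n_samp)

    # Reflection padding by half the longest wavelet support mitigates
    # edge ringing; epochs shorter than one wavelet support are refused.
    f_min = freqs.min()
    half_support = int(math.ceil(5.0 * sigma_t(f_min, spec) * fs))
    if n_samp < 2:
        raise ValueError("epoch too short")
    pad = min(half_support, n_samp - 1)
    if half_support > n_samp:
        raise ValueError(
            f"epoch ({n_samp / fs:.2f} s) shorter than half the wavelet support "
            f"at {f_min} Hz ({half_support / fs:.2f} s)"
        )
    xpad = np.concatenate(
        [x2[:, pad:0:-1], x2, x2[:, -2 : -2 - pad : -1]], axis=1
    )
    n_pad = xpad.shape[1]
    n_fft = next_fast_len(n_pad + 2 * half_support)
    X = rfft(xpad, n=n_fft, axis=1)

    # Shared decimated grid: M output samples over the n_fft circle.
    bands = [_wavelet_band(f, fs, n_fft, spec) for f in freqs]
    max_band = max(len(g) for _, g in bands)
    m_out = next_fast_len(max(max_band * 2, int(math.ceil(n_fft / max(decim, 1)))))
    m_out = min(m_out, n_fft)

    # Output time grid (padded coordinates), then sliced to the epoch.
    t_step = n_fft / (m_out * fs)
    t_out = np.arange(m_out) * t_step - pad / fs + rec.t_start
    keep = (t_out >= rec.t_start - 1e-9) & (
        t_out <= rec.t_start + (n_samp - 1) / fs + 1e-9
    )
    times = t_out[keep]

    values = np.empty((x2.shape[0], len(freqs), keep.sum()), dtype=dtype)
    scale = m_out / n_fft
    for j, (k0, gains) in enumerate(bands):
        z = X[:, k0 : k0 + len(gains)] * gains[None, :]
        env = ifft(z, n=m_out, axis=1)
        values[:, j, :] = scale * np.abs(env[:, keep])

    values = values.reshape(n_trials, n_ch, len(freqs), -1)
    return Spectrogram(
        values=values,
        freqs=freqs,
        times=times,
        dims=("trial", "channel"),
        channel_names=[rec.channel_names[i] for i in ch_idx],
    )


def edge_mask(
    freqs: np.ndarray,
    times: np.ndarray,
    spec: WaveletSpec = WaveletSpec(),
    epoch_span: tuple[float, float] = (-2.0, 6.0),
    n_sigma: float = 1.0,
) -> np.ndarray:
    """Boolean (freq, time) mask of bins within ``n_sigma`` wavelet sds
    of an epoch edge (True = potentially edge-contaminated)."""
    freqs = np.asarray(freqs, float)
    times = np.asarray(times, float)
    st = np.array([sigma_t(f, spec) for f in freqs])
    near_lo = times[None, :] < epoch_span[0] + n_sigma * st[:, None]
    near_hi = times[None, :] > epoch_span[1] - n_sigma * st[:, None]
    return near_lo | near_hi


def zscore_baseline(
    spect: Spectrogram, baseline: tuple[float, float] = (-1.5, -0.5)
) -> ZSpectrogram:
    """Z-score each (trial, channel, freq) magnitude trace against its
    own pre-stimulus baseline mean and sd.

    Raises if the baseline sd is zero for any (channel, freq).
    """
    mask = spect.time_slice(*baseline)
    if not mask.any():
        raise ValueError(f"baseline {baseline} outside time grid")
    base = spect.values[..., mask]
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, ddof=1, keepdims=True)
    zero = np.nonzero(sd == 0)
    if zero[0].size:
        first = tuple(int(ax[0]) for ax in zero)
        raise ValueError(
            f"zero baseline variance at index {first[:-1]} "
            f"(..., channel, freq) -- cannot z-score a constant trace"
        )
    z = (spect.values - mu) / sd
    return ZSpectrogram(
        values=z,
        freqs=spect.freqs,
        times=spect.times,
        dims=spect.dims,
        channel_names=spect.channel_names,
        baseline_window=baseline,
    )


def average_z(z: ZSpectrogram, dim: str = "trial") -> ZSpectrogram:
    """Element-wise average of per-trial z-maps over a named axis."""
    return z.mean_over(dim)


def grand_average(maps: list[ZSpectrogram]) -> ZSpectrogram:
    """Average a list of z-maps sharing grids (e.g. across participants
    and conditions), keeping explicit what level is being averaged."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or not (
            np.allclose(m.freqs, first.freqs) and np.allclose(m.times, first.times)
        ):
            raise ValueError("mismatched spectrogram grids")
    return ZSpectrogram(
        values=np.mean([m.values for m in maps], axis=0),
        freqs=first.freqs,
        times=first.times,
        dims=first.dims,
        channel_names=first.channel_names,
        baseline_window=first.baseline_window,
    )


def evoked_average(
    rec: EpochedRecording, baseline: tuple[float, float] = (-2.0, 0.0)
) -> np.ndarray:
    """Phase-locked evoked response: trial average corrected to its own
    pre-stimulus baseline mean.  Returns (n_channels, n_samples)."""
    if rec.n_trials < 1:
        raise ValueError("no trials")
    avg = rec.data.mean(axis=0)
    times = rec.times
    mask = (times >= baseline[0]) & (times <= baseline[1])
    return avg - avg[:, mask].mean(axis=1, keepdims=True)
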