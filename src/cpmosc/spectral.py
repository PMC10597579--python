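"""Pre-stimulus baseline power spectra.

Welch periodograms of the [-2, 0] s pre-stimulus segment of each trial
(1-s Hann segments, 50% overlap), averaged over trials and analysis
channels, restricted to [1, 60] Hz and normalized to unit total power.
The relative spectra feed per-frequency permutation t-tests with FDR
correction (stats module) for condition and group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EpochedRecording
from .ersp import ALPHA, BETA, Band
from . import stats as _stats

__all__ = ["PsdResult", "baseline_psd", "compare_baselines"]


@dataclass
class PsdResult:
    """Relative baseline power spectrum for one participant x condition."""

    freqs: np.ndarray
    rel_power: np.ndarray  # fractions; sums to 1 over the analysis range
    peak_freq: dict[str, float] = field(default_factory=dict)
    band_power: dict[str, float] = field(default_factory=dict)
    total_power: float = 0.0  # unnormalized, signal-units^2


def _detrended(freqs: np.ndarray, power: np.ndarray, bands: list[Band]) -> np.ndarray:
    """Residual of a log-log linear (1/f-like) fit excluding the bands."""
    keep = np.ones_like(freqs, dtype=bool)
    for b in bands:
        keep &= ~((freqs >= b.f_lo) & (freqs <= b.f_hi))
    lf = np.log(freqs)
    lp = np.log(np.maximum(power, 1e-300))
    coef = np.polyfit(lf[keep], lp[keep], 1)
    return lp - np.polyval(coef, lf)


def baseline_psd(
    rec: EpochedRecording,
    baseline: tuple[float, float] = (-2.0, 0.0),
    f_range: tuple[float, float] = (1.0, 60.0),
    segment: float = 1.0,
    overlap: float = 0.5,
    channels: list[str] | None = None,
    bands: tuple[Band, ...] = (ALPHA, BETA),
    detrend_peaks: bool = False,
) -> PsdResult:
    """Welch relative power spectrum of the pre-stimulus baseline.

    ``peak_freq`` is the frequency of maximal relative power within each
    band (on the 1/f-detrended spectrum when ``detrend_peaks``);
    ``band_power`` is the summed relative power over the band.
    """
    fs = rec.sampling_rate
    times = rec.times
    mask = (times >= baseline[0]) & (times < baseline[1])
    nperseg = int(round(segment * fs))
    if mask.sum() < nperseg:
        raise ValueError(
            f"baseline segment ({mask.sum()} samples) shorter than one "
            f"Welch segment ({nperseg} samples)"
        )
    ch = rec.channel_index(channels)
    x = rec.data[:, ch, :][:, :, mask]
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), axis=-1,
    )
    psd = psd.mean(axis=(0, 1))  # average trials and channels
    sel = (freqs >= f_range[0]) & (freqs <= f_range[1])
    freqs, psd = freqs[sel], psd[sel]
    total = float(psd.sum())
    rel = psd / total
    peak_source = _detrended(freqs, rel, list(bands)) if detrend_peaks else rel
    peak_freq, band_power = {}, {}
    for b in bands:
        bmask = (freqs >= b.f_lo) & (freqs <= b.f_hi)
        peak_freq[b.name] = float(freqs[bmask][np.argmax(peak_source[bmask])])
        band_power[b.name] = float(rel[bmask].sum())
    return PsdResult(
        freqs=freqs, rel_power=rel, peak_freq=peak_freq,
        band_power=band_power, total_power=total,
    )


def compare_baselines(
    results_a: list[PsdResult],
    results_b: list[PsdResult],
    paired: bool,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
):
    """Per-frequency-bin permutation t-tests with FDR correction.

    ``results_a`` / ``results_b`` hold one PsdResult per unit
    (participant); paired comparisons (conditions) require matched
    ordering.  Returns the stats-module map-test result with fields
    ``p``, ``q`` and ``mask`` over frequency bins.
    """
    if len(results_a) < 2 or len(results_b) < 2:
        raise ValueError("need at least 2 units per cell")
    f0 = results_a[0].freqs
    for r in list(results_a) + list(results_b):
        if r.freqs.shape != f0.shape or not np.allclose(r.freqs, f0):
            raise ValueError("mismatched frequency grids")
    a = np.stack([r.rel_power for r in results_a])
    b = np.stack([r.rel_power for r in results_b])
    return _stats.permutation_ttest_maps(
        a, b, paired=paired, n_perm=n_perm, alpha=alpha, seed=seed
    )
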