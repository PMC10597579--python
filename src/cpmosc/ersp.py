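"""Event-related spectral perturbation (ERSP) windows and measures.

Band-limited windows of supra-threshold deviation are detected once on
the grand-average z-spectrogram (threshold 0.5 z in absolute value) and
then held fixed; per-participant scalars are the mean z inside the
window (magnitude) and the length of the longest supra-threshold run of
the 500-ms-smoothed band trace (duration, threshold 2 z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tfr import ZSpectrogram

__all__ = [
    "Band",
    "ALPHA",
    "BETA",
    "ErspWindow",
    "ErspMeasures",
    "band_trace",
    "detect_windows",
    "pick_window",
    "ersp_magnitude",
    "ersp_duration",
    "ersp_location_map",
    "moving_average",
]


@dataclass(frozen=True)
class Band:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"need f_lo < f_hi; got [{self.f_lo}, {self.f_hi}]")


ALPHA = Band("alpha", 8.0, 13.0)
BETA = Band("beta", 15.0, 30.0)


@dataclass(frozen=True)
class ErspWindow:
    """A detected band-limited interval of supra-threshold deviation.

    ``sign`` is +1 for synchronization (ERS) and -1 for
    desynchronization (ERD).
    """

    band: Band
    sign: int
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 (ERS) or -1 (ERD)")
        if not self.t_start <= self.t_end:
            raise ValueError("need t_start <= t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ErspMeasures:
    participant_id: str
    group: str
    condition: str
    name: str  # e.g. "beta_ers"
    band: Band
    sign: int
    magnitude: float  # z units
    duration: float  # seconds


def band_trace(z: ZSpectrogram, band: Band) -> np.ndarray:
    """Mean z over the band's frequencies; channels (if present) are
    averaged first, so the result is a 1-D time trace."""
    values = z.values
    for dim in z.dims:
        if dim not in ("trial", "channel"):
            raise ValueError(f"unexpected leading axis {dim!r}")
        values = values.mean(axis=0)
    fmask = z.freq_slice(band.f_lo, band.f_hi)
    if not fmask.any():
        raise ValueError(f"band {band.name} outside frequency grid")
    return values[fmask, :].mean(axis=0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop) index pairs, stop exclusive."""
    idx = np.nonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))[0]
    return list(zip(idx[0::2], idx[1::2]))


def detect_windows(
    grand_avg: ZSpectrogram, band: Band, threshold: float = 0.5
) -> list[ErspWindow]:
    """Detect ERSP windows on a grand-average z-map.

    The band-mean trace is thresholded at ``|z| >= threshold``; each
    maximal sign-constant contiguous run becomes one window (positive
    and negative excursions are detected separately, so a rapid
    ERD-to-ERS transition cannot fuse into one window).  Runs peaking
    before stimulus onset (t = 0) are discarded as baseline
    fluctuation; a run that merely leaks a few bins before onset --
    wavelet smoothing spreads genuinely post-stimulus responses
    backward in time -- is kept with its start clipped to 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    trace = band_trace(grand_avg, band)
    out: list[ErspWindow] = []
    for sign, mask in ((+1, trace >= threshold), (-1, trace <= -threshold)):
        for start, stop in _runs(mask):
            peak = start + int(np.argmax(sign * trace[start:stop]))
            if grand_avg.times[peak] < 0:
                continue
            out.append(
                ErspWindow(
                    band=band,
                    sign=sign,
                    t_start=max(float(grand_avg.times[start]), 0.0),
                    t_end=float(grand_avg.times[stop - 1]),
                )
            )
    out.sort(key=lambda w: w.t_start)
    return out


def pick_window(
    windows: list[ErspWindow], sign: int, latency: float | None = None
) -> ErspWindow | None:
    """Select the single window used for fixed-range measures.

    Among windows of the requested sign, prefer the one containing the
    canonical ``latency`` (early for ERD, late for ERS); fall back to
    the longest.  Returns None when no window matches.
    """
    cands = [w for w in windows if w.sign == sign]
    if not cands:
        return None
    if latency is not None:
        containing = [w for w in cands if w.t_start <= latency <= w.t_end]
        if containing:
            return max(containing, key=lambda w: w.duration)
    return max(cands, key=lambda w: w.duration)


def ersp_magnitude(z: ZSpectrogram, window: ErspWindow) -> float:
    """Mean z over the window's band x time range (x channels)."""
    fmask = z.freq_slice(window.band.f_lo, window.band.f_hi)
    tmask = z.time_slice(window.t_start, window.t_end)
    if not fmask.any() or not tmask.any():
        raise ValueError("window selects no spectrogram bins")
    sel = z.values[..., fmask, :][..., tmask]
    return float(sel.mean())


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average of window length ``n`` samples, shrinking
    at the edges (each output is the mean of the available samples)."""
    if n <= 1:
        return x.astype(float)
    half_l = (n - 1) // 2
    half_r = n - 1 - half_l
    c = np.concatenate(([0.0], np.cumsum(x, dtype=float)))
    idx = np.arange(len(x))
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, len(x))
    return (c[hi] - c[lo]) / (hi - lo)


def ersp_duration(
    z: ZSpectrogram,
    band: Band,
    sign: int,
    smooth_window: float = 0.5,
    threshold: float = 2.0,
) -> float:
    """Duration (s) of the longest post-stimulus supra-threshold run.

    The band-mean trace is smoothed with a centred moving average of
    ``smooth_window`` seconds (shrinking at the trace edges); the
    duration is the length of the longest contiguous run with
    ``sign * trace >= threshold`` whose first sample is at or after
    t = 0.  Returns 0 when no run qualifies.
    """
    trace = band_trace(z, band)
    dt = z.time_step
    n = max(1, int(round(smooth_window / dt)))
    if n % 2 == 0:
        n += 1  # symmetric centred window
    smoothed = moving_average(trace, n)
    best = 0
    for start, stop in _runs(sign * smoothed >= threshold):
        if z.times[start] < 0:
            continue
        best = max(best, stop - start)
    return best * dt


def ersp_location_map(z: ZSpectrogram, window: ErspWindow) -> np.ndarray:
    """Per-channel ERSP magnitude (desk-scale stand-in for a cortical
    vertex map).  ``z`` must retain its channel axis; a trial axis, if
    present, is averaged first.  Returns shape (n_channels,)."""
    if "channel" not in z.dims:
        raise ValueError("z-map has no channel axis")
    if "trial" in z.dims:
        z = z.mean_over("trial")
    fmask = z.freq_slice(window.band.f_lo, window.band.f_hi)
    tmask = z.time_slice(window.t_start, window.t_end)
    sel = z.values[:, fmask, :][:, :, tmask]
    return sel.mean(axis=(1, 2))
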