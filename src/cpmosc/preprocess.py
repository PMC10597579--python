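"""Time-series conditioning of epoched recordings.

Stimulus-artifact interpolation, zero-phase bandpass and notch
filtering, and bad-channel exclusion.  All filters are applied
forward-backward so ERSP latencies are not shifted.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EpochedRecording

SITE_LINE_FREQS = {
    "MNI": (60.0, 120.0, 180.0),
    "Donders": (50.0, 100.0, 150.0, 200.0),
}


def notch_freqs_for_site(site: str) -> tuple[float, ...]:
    """Power-line frequencies (fundamental + harmonics) for a site label."""
    try:
        return SITE_LINE_FREQS[site]
    except KeyError:
        raise KeyError(
            f"unknown site {site!r}; expected one of {sorted(SITE_LINE_FREQS)}"
        ) from None


def interpolate_artifact(
    rec: EpochedRecording, span: tuple[float, float] = (0.0, 0.070)
) -> EpochedRecording:
    """Replace samples inside ``span`` (closed interval) by linear
    interpolation.

    The straight line joins the last clean sample before the span and
    the first clean sample after it, independently per trial and
    channel; the span endpoints themselves are treated as contaminated
    (a stimulus artifact covers its own onset sample).  All samples
    outside the span are returned unchanged, exactly.
    """
    times = rec.times
    lo, hi = span
    if lo <= times[0] or hi >= times[-1]:
        raise ValueError(
            f"artifact span {span} reaches an epoch boundary; "
            "an anchor sample is required on both sides"
        )
    inside = np.nonzero((times >= lo) & (times <= hi))[0]
    if inside.size == 0:
        return rec.copy_with(data=rec.data.copy())
    i0 = inside[0] - 1   # last clean sample before the span
    i1 = inside[-1] + 1  # first clean sample after the span
    data = rec.data.copy()
    frac = (times[inside] - times[i0]) / (times[i1] - times[i0])
    left = data[:, :, i0][:, :, None]
    right = data[:, :, i1][:, :, None]
    data[:, :, inside] = left + frac[None, None, :] * (right - left)
    return rec.copy_with(data=data)


def bandpass_filter(rec: EpochedRecording, lo: float = 1.0, hi: float = 200.0) -> EpochedRecording:
    """Zero-phase 4th-order Butterworth bandpass."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < lo < hi:
        raise ValueError(f"need 0 < lo < hi; got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"upper edge {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.sampling_rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return rec.copy_with(data=data)


def notch_filter(
    rec: EpochedRecording, line_freqs, q: float = 60.0
) -> EpochedRecording:
    """Zero-phase IIR notch at each line frequency.

    ``q`` is the per-pass quality factor of each second-order notch; the
    default keeps bands 2 Hz away from the line frequency within 10%
    after the forward-backward (squared-magnitude) application.
    """
    nyq = rec.sampling_rate / 2.0
    data = rec.data
    for f0 in np.atleast_1d(line_freqs):
        if f0 >= nyq:
            raise ValueError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(f0, q, fs=rec.sampling_rate)
        data = signal.filtfilt(b, a, data, axis=-1)
    return rec.copy_with(data=data)


def notch_filter_site(rec: EpochedRecording, site: str | None = None, q: float = 60.0) -> EpochedRecording:
    """Notch filter using the line frequencies of ``site`` (default: the
    recording's own site label), skipping harmonics above Nyquist."""
    freqs = notch_freqs_for_site(site or rec.site)
    freqs = [f for f in freqs if f < rec.sampling_rate / 2.0]
    return notch_filter(rec, freqs, q=q)


def exclude_bad_channels(
    rec: EpochedRecording,
    channels: list[str] | None = None,
    rms_z_threshold: float = 5.0,
) -> EpochedRecording:
    """Drop poor-quality channels from the data.

    With an explicit ``channels`` list, those channels are removed (an
    unknown name raises).  Otherwise channels whose per-channel RMS has a
    robust z-score (median / 1.4826 * MAD) above ``rms_z_threshold`` are
    removed -- a reproducible stand-in for manual sensor inspection.
    Excluded names are appended to ``excluded_channels`` metadata.
    """
    if channels is not None:
        idx = rec.channel_index(list(channels))  # raises on unknown names
        bad = set(int(i) for i in idx)
    else:
        rms = np.sqrt(np.mean(rec.data**2, axis=(0, 2)))
        med = np.median(rms)
        # Scale floor at 10% of the median RMS: with few channels the MAD
        # can collapse to numerical noise and flag benign physiological
        # channel-to-channel differences.
        scale = max(1.4826 * np.median(np.abs(rms - med)), 0.1 * med)
        if scale == 0:
            bad = set()
        else:
            z = (rms - med) / scale
            bad = set(np.nonzero(z > rms_z_threshold)[0].tolist())
    if not bad:
        return rec.copy_with(data=rec.data.copy())
    keep = [i for i in range(rec.n_channels) if i not in bad]
    if not keep:
        raise ValueError("exclusion would leave zero channels")
    return rec.copy_with(
        data=rec.data[:, keep, :],
        channel_names=[rec.channel_names[i] for i in keep],
        excluded_channels=rec.excluded_channels
        + [rec.channel_names[i] for i in sorted(bad)],
    )


def preprocess_recording(
    rec: EpochedRecording,
    artifact_span: tuple[float, float] = (0.0, 0.070),
    band: tuple[float, float] = (1.0, 200.0),
    site: str | None = None,
    bad_channel_z: float | None = 5.0,
) -> EpochedRecording:
    """Standard conditioning chain: interpolate artifact, bandpass,
    notch for the site's power line, exclude bad channels."""
    out = interpolate_artifact(rec, artifact_span)
    nyq = rec.sampling_rate / 2.0
    hi = min(band[1], 0.9 * nyq)
    if not 0 < band[0] < hi:
        raise ValueError(f"invalid passband ({band[0]}, {hi}) at fs={rec.sampling_rate}")
    # One combined zero-phase cascade (bandpass + notches) -- identical
    # response to applying the filters in sequence, one data pass.
    sos = [signal.butter(4, [band[0], hi], btype="bandpass", fs=rec.sampling_rate, output="sos")]
    for f0 in notch_freqs_for_site(site or rec.site):
        if f0 < nyq:
            b, a = signal.iirnotch(f0, 60.0, fs=rec.sampling_rate)
            sos.append(signal.tf2sos(b, a))
    data = signal.sosfiltfilt(np.vstack(sos), out.data, axis=-1)
    out = out.copy_with(data=data)
    if bad_channel_z is not None:
        out = exclude_bad_channels(out, rms_z_threshold=bad_channel_z)
    return out
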