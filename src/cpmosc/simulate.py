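"""Synthetic epoched-trial generator with known injected oscillatory effects.

Emulates the structure of a two-group, three-condition conditioned pain
modulation (CPM) experiment: for each participant and condition block, a
set of independent epochs spanning [-2, 6] s around stimulus onset.  Each
epoch is 1/f background noise plus sustained alpha and beta oscillations
whose amplitude is multiplicatively modulated after the stimulus:

* alpha-ERD  -- amplitude dip (1 - d) over a fixed post-stimulus window,
* beta-ERD   -- early amplitude dip in the beta band,
* beta-ERS   -- late amplitude surge (1 + g) in the beta band ("beta
  rebound"), whose gain g carries the condition and group effects,

plus a large deterministic stimulus artifact over the first ~70 ms and an
optional phase-locked evoked transient.  Modulation is applied only on a
designated subset of "response" channels so that spatial maps have
structure; the background oscillations themselves are present everywhere.

With all condition and group modulators equal to one the generative law
is identical across cells (an exchangeable null), which is the basis for
the type-I-error calibration of the downstream statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import Dataset, EpochedRecording, EPOCH_SPAN

__all__ = [
    "OscillationSpec",
    "NoiseSpec",
    "ArtifactSpec",
    "EvokedSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_dataset",
]


@dataclass
class OscillationSpec:
    """One band-limited oscillation and its event-related modulation.

    ``erd_window`` / ``ers_window`` give the full-effect interval; a
    raised-cosine ramp of ``SimulationConfig.ramp`` seconds is appended
    *outside* each end, so the mean envelope inside the window equals the
    nominal modulated level exactly.
    """

    freq: float
    amplitude: float
    erd_depth: float = 0.0
    erd_window: tuple[float, float] | None = None
    ers_gain: float = 0.0
    ers_window: tuple[float, float] | None = None


@dataclass
class NoiseSpec:
    one_over_f_exponent: float = 1.0
    amplitude: float = 1.0


@dataclass
class ArtifactSpec:
    span: tuple[float, float] = (0.0, 0.070)
    amplitude: float = 15.0


@dataclass
class EvokedSpec:
    amplitude: float = 1.0
    latency: float = 0.12
    width: float = 0.02


def _default_alpha() -> OscillationSpec:
    return OscillationSpec(
        freq=10.0, amplitude=1.0, erd_depth=0.5, erd_window=(0.32, 0.76)
    )


def _default_beta() -> OscillationSpec:
    return OscillationSpec(
        freq=20.0,
        amplitude=1.0,
        erd_depth=0.6,
        erd_window=(0.16, 0.55),
        ers_gain=0.8,
        ers_window=(0.61, 3.68),
    )


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment.

    Defaults reproduce the study layout: 2 groups x 17 participants x 3
    condition blocks, ~3-minute blocks of stimuli at 6-10 s intervals
    (22 trials per block at the ~8 s mean interval), epochs of [-2, 6] s.
    ``condition_modulation`` and ``group_modulation`` multiply the
    beta-ERS gain only; the desynchronizations are left unmodulated, as
    in the experimental findings this generator is designed to emulate.
    """

    n_per_group: int = 17
    groups: tuple[str, str] = ("CP", "HC")
    conditions: tuple[str, ...] = ("before", "during", "after")
    trials_per_block: int = 22
    sampling_rate: float = 600.0
    epoch_span: tuple[float, float] = EPOCH_SPAN
    n_channels: int = 12
    n_response_channels: int = 4
    alpha_osc: OscillationSpec = field(default_factory=_default_alpha)
    beta_osc: OscillationSpec = field(default_factory=_default_beta)
    condition_modulation: dict[str, float] = field(
        default_factory=lambda: {"before": 1.0, "during": 0.6, "after": 0.8}
    )
    group_modulation: dict[str, float] = field(
        default_factory=lambda: {"CP": 0.9, "HC": 1.0}
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    evoked: EvokedSpec | None = field(default_factory=EvokedSpec)
    inter_subject_sd: float = 0.2
    ramp: float = 0.1
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_span[1] - self.epoch_span[0]) * self.sampling_rate))

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i + 1:02d}" for i in range(self.n_channels)]

    @property
    def response_channels(self) -> list[str]:
        return self.channel_names[: self.n_response_channels]

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.n_response_channels <= self.n_channels:
            raise ValueError("n_response_channels must be in [1, n_channels]")
        lo, hi = self.epoch_span
        for osc in (self.alpha_osc, self.beta_osc):
            if not 0.0 <= osc.erd_depth <= 1.0:
                raise ValueError(f"erd_depth must be in [0, 1]; got {osc.erd_depth}")
            if osc.ers_gain < 0:
                raise ValueError(f"ers_gain must be >= 0; got {osc.ers_gain}")
            for win in (osc.erd_window, osc.ers_window):
                if win is None:
                    continue
                if not (lo <= win[0] < win[1] <= hi):
                    raise ValueError(
                        f"modulation window {win} outside epoch span {self.epoch_span}"
                    )
        a0, a1 = self.artifact.span
        if not (lo <= a0 < a1 <= hi):
            raise ValueError("artifact span outside epoch span")
        for cond in self.conditions:
            if cond not in self.condition_modulation:
                raise ValueError(f"no condition_modulation entry for {cond!r}")
        for grp in self.groups:
            if grp not in self.group_modulation:
                raise ValueError(f"no group_modulation entry for {grp!r}")


@dataclass
class GroundTruth:
    """Realized per-participant x condition effect parameters.

    One record per participant x condition, with the effective (subject-
    and condition-modulated) beta-ERS gain and the ERD depths actually
    injected, plus the injected window bounds and the seed.
    """

    records: list[dict]
    windows: dict[str, tuple[float, float]]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        windows = {k: tuple(v) for k, v in d["windows"].items()}
        return cls(records=list(d["records"]), windows=windows, seed=int(d["seed"]))


def one_over_f_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    n_samples: int,
    sampling_rate: float,
    exponent: float,
    amplitude: float,
) -> np.ndarray:
    """Stationary 1/f^exponent (power) noise, unit variance before scaling.

    White Gaussian noise is shaped in the frequency domain; the shaping
    filter is normalized so the output variance equals ``amplitude**2``
    in expectation.
    """
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain /= math.sqrt(np.mean(gain[1:] ** 2))
    spec *= gain
    return amplitude * np.fft.irfft(spec, n=n_samples, axis=-1)


def _ramped_window(
    times: np.ndarray, window: tuple[float, float], ramp: float, inside: bool = False
) -> np.ndarray:
    """Indicator of ``window`` with raised-cosine ramps.

    With ``inside=False`` the plateau covers all of [t0, t1] and the
    ramps roll off outside it (so the mean modulation inside the window
    equals the nominal level exactly).  With ``inside=True`` the ramps
    lie within the window and the modulation's support is exactly
    [t0, t1] (so no modulated energy leaks into adjacent windows).
    """
    t0, t1 = window
    w = np.zeros_like(times)
    if inside:
        lo, hi = t0 + ramp, t1 - ramp
        w[(times >= lo) & (times <= hi)] = 1.0
        if ramp > 0:
            up = (times >= t0) & (times < lo)
            w[up] = 0.5 * (1 + np.cos(np.pi * (lo - times[up]) / ramp))
            down = (times > hi) & (times <= t1)
            w[down] = 0.5 * (1 + np.cos(np.pi * (times[down] - hi) / ramp))
    else:
        w[(times >= t0) & (times <= t1)] = 1.0
        if ramp > 0:
            up = (times >= t0 - ramp) & (times < t0)
            w[up] = 0.5 * (1 + np.cos(np.pi * (t0 - times[up]) / ramp))
            down = (times > t1) & (times <= t1 + ramp)
            w[down] = 0.5 * (1 + np.cos(np.pi * (times[down] - t1) / ramp))
    return w


def _envelope(
    times: np.ndarray,
    osc: OscillationSpec,
    erd_depth: float,
    ers_gain: float,
    ramp: float,
) -> np.ndarray:
    # ERD ramps sit outside the window (mean envelope inside the window
    # is exactly (1 - depth)); ERS ramps sit inside so the surge's
    # support is exactly the injected window and the condition-modulated
    # energy cannot contaminate the neighbouring ERD measurement range.
    env = np.ones_like(times)
    if osc.erd_window is not None and erd_depth > 0:
        env *= 1.0 - erd_depth * _ramped_window(times, osc.erd_window, ramp)
    if osc.ers_window is not None and ers_gain > 0:
        env *= 1.0 + ers_gain * _ramped_window(times, osc.ers_window, ramp, inside=True)
    return env


def _sites_for_group(n: int) -> list[str]:
    """Assign recording sites in the study's ~11:6 MNI:Donders proportion."""
    n_mni = int(round(n * 11 / 17))
    return ["MNI"] * n_mni + ["Donders"] * (n - n_mni)


def generate_dataset(config: SimulationConfig) -> tuple[Dataset, GroundTruth]:
    """Generate one full synthetic experiment.

    Returns the dataset (one :class:`EpochedRecording` per participant x
    condition) and the ground truth of realized injected effects.
    Deterministic: identical (config, seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = config.n_samples
    times = config.epoch_span[0] + np.arange(n_samples) / fs
    ch_names = config.channel_names
    n_resp = config.n_response_channels

    # Per-subject multiplicative dispersion of effect sizes, drawn first
    # in a fixed order so trial noise does not perturb subject effects.
    participants: list[tuple[str, str, str]] = []  # (pid, group, site)
    subject_factors: dict[str, dict[str, float]] = {}
    for group in config.groups:
        sites = _sites_for_group(config.n_per_group)
        for k in range(config.n_per_group):
            pid = f"{group}{k + 1:02d}"
            participants.append((pid, group, sites[k]))
            fac = rng.normal(1.0, config.inter_subject_sd, size=3)
            fac = np.clip(fac, 0.0, None)
            subject_factors[pid] = {
                "alpha_erd": float(fac[0]),
                "beta_erd": float(fac[1]),
                "beta_ers": float(fac[2]),
            }

    windows = {}
    if config.alpha_osc.erd_window is not None:
        windows["alpha_erd"] = tuple(config.alpha_osc.erd_window)
    if config.beta_osc.erd_window is not None:
        windows["beta_erd"] = tuple(config.beta_osc.erd_window)
    if config.beta_osc.ers_window is not None:
        windows["beta_ers"] = tuple(config.beta_osc.ers_window)

    artifact_shape = np.zeros(n_samples)
    a0, a1 = config.artifact.span
    in_art = (times >= a0) & (times < a1)
    artifact_shape[in_art] = config.artifact.amplitude * np.sin(
        np.pi * (times[in_art] - a0) / (a1 - a0)
    )

    evoked_shape = np.zeros(n_samples)
    if config.evoked is not None and config.evoked.amplitude != 0:
        ev = config.evoked
        evoked_shape = ev.amplitude * np.exp(-((times - ev.latency) ** 2) / (2 * ev.width**2))

    recordings: dict[tuple[str, str], EpochedRecording] = {}
    records: list[dict] = []
    for pid, group, site in participants:
        fac = subject_factors[pid]
        for cond in config.conditions:
            alpha_depth = float(np.clip(config.alpha_osc.erd_depth * fac["alpha_erd"], 0, 1))
            beta_depth = float(np.clip(config.beta_osc.erd_depth * fac["beta_erd"], 0, 1))
            beta_gain = float(
                config.beta_osc.ers_gain
                * config.condition_modulation[cond]
                * config.group_modulation[group]
                * fac["beta_ers"]
            )
            records.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "condition": cond,
                    "alpha_erd_depth": alpha_depth,
                    "beta_erd_depth": beta_depth,
                    "beta_ers_gain": beta_gain,
                }
            )

            env_alpha = _envelope(times, config.alpha_osc, alpha_depth, 0.0, config.ramp)
            env_beta = _envelope(times, config.beta_osc, beta_depth, beta_gain, config.ramp)
            flat = np.ones_like(times)

            data = one_over_f_noise(
                rng,
                (config.trials_per_block, config.n_channels),
                n_samples,
                fs,
                config.noise.one_over_f_exponent,
                config.noise.amplitude,
            )
            for osc, env in ((config.alpha_osc, env_alpha), (config.beta_osc, env_beta)):
                if osc.amplitude == 0:
                    continue
                phases = rng.uniform(
                    0, 2 * np.pi, size=(config.trials_per_block, config.n_channels)
                )
                # cos(wt + phi) via the angle-addition identity: the two
                # carrier waveforms are shared across trials and channels.
                cos_t = np.cos(2 * np.pi * osc.freq * times)
                sin_t = np.sin(2 * np.pi * osc.freq * times)
                carrier = (
                    np.cos(phases)[:, :, None] * cos_t[None, None, :]
                    - np.sin(phases)[:, :, None] * sin_t[None, None, :]
                )
                envs = np.where(
                    (np.arange(config.n_channels) < n_resp)[None, :, None], env, flat
                )
                data += osc.amplitude * envs * carrier
            data += artifact_shape
            data[:, :n_resp, :] += evoked_shape

            recordings[(pid, cond)] = EpochedRecording(
                participant_id=pid,
                group=group,
                condition=cond,
                sampling_rate=fs,
                t_start=config.epoch_span[0],
                data=data,
                channel_names=list(ch_names),
                site=site,
            )

    truth = GroundTruth(records=records, windows=windows, seed=config.seed)
    return Dataset(recordings=recordings, ground_truth=truth), truth
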