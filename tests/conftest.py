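import numpy as np
import pytest

from cpmosc.containers import EpochedRecording
from cpmosc.simulate import (
    ArtifactSpec,
    EvokedSpec,
    NoiseSpec,
    OscillationSpec,
    SimulationConfig,
    generate_dataset,
)


def make_recording(
    data: np.ndarray,
    sampling_rate: float = 300.0,
    t_start: float = -2.0,
    **kwargs,
) -> EpochedRecording:
    """Wrap a raw (trials, channels, samples) array in a recording."""
    data = np.asarray(data, dtype=float)
    defaults = dict(
        participant_id="p01",
        group="HC",
        condition="before",
        channel_names=[f"ch{i + 1:02d}" for i in range(data.shape[1])],
    )
    defaults.update(kwargs)
    return EpochedRecording(
        sampling_rate=sampling_rate, t_start=t_start, data=data, **defaults
    )


def sinusoid_recording(
    freq: float,
    amplitude: float = 1.0,
    sampling_rate: float = 600.0,
    n_trials: int = 1,
    n_channels: int = 1,
) -> EpochedRecording:
    n = int(round(8 * sampling_rate))
    t = -2.0 + np.arange(n) / sampling_rate
    x = amplitude * np.cos(2 * np.pi * freq * t)
    return make_recording(
        np.tile(x, (n_trials, n_channels, 1)), sampling_rate=sampling_rate
    )


def small_config(**overrides) -> SimulationConfig:
    """Desk-scale simulation defaults for fast unit tests."""
    kwargs = dict(
        n_per_group=2,
        trials_per_block=6,
        sampling_rate=300.0,
        n_channels=6,
        n_response_channels=4,
        seed=7,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated experiment shared across read-only tests."""
    return generate_dataset(small_config())


def noise_free_config(**overrides) -> SimulationConfig:
    """Deterministic oscillations only: no noise, artifact or evoked."""
    kwargs = dict(
        noise=NoiseSpec(amplitude=0.0),
        artifact=ArtifactSpec(amplitude=0.0),
        evoked=None,
        inter_subject_sd=0.0,
    )
    kwargs.update(overrides)
    return small_config(**kwargs)
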