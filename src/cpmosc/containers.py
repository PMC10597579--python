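"""Core in-memory containers for epoched electrophysiological data.

The unit of analysis is one participant x condition block of epoched
trials (trials x channels x samples), with time locked to the test
stimulus at t = 0 and epochs spanning [-2, 6] s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

GROUPS = ("CP", "HC")
CONDITIONS = ("before", "during", "after")

EPOCH_SPAN = (-2.0, 6.0)


@dataclass
class EpochedRecording:
    """Epoched trials for one participant in one experimental condition.

    Attributes
    ----------
    participant_id : str
        Unique participant label.
    group : str
        Between-subject group, ``"CP"`` (chronic pain) or ``"HC"``
        (pain-free control).
    condition : str
        Within-subject block label: ``"before"``, ``"during"`` or
        ``"after"`` (relative to the conditioning stimulus).
    sampling_rate : float
        Samples per second.
    t_start : float
        Time of the first sample relative to stimulus onset (seconds).
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Field values on an arbitrary consistent scale.
    channel_names : list of str
        One name per channel, aligned with axis 1 of ``data``.
    site : str
        Recording site label; determines power-line frequencies.
    excluded_channels : list of str
        Channels removed from analysis (kept for bookkeeping only).
    """

    participant_id: str
    group: str
    condition: str
    sampling_rate: float
    t_start: float
    data: np.ndarray
    channel_names: list[str]
    site: str = "MNI"
    excluded_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channels in data but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, t = 0 at stimulus onset."""
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate

    def time_index(self, t: float) -> int:
        """Index of the sample nearest to time ``t`` (seconds)."""
        return int(round((t - self.t_start) * self.sampling_rate))

    def channel_index(self, names: list[str] | None) -> np.ndarray:
        """Indices of ``names`` in the channel axis (all channels if None)."""
        if names is None:
            return np.arange(self.n_channels)
        lookup = {c: i for i, c in enumerate(self.channel_names)}
        missing = [c for c in names if c not in lookup]
        if missing:
            raise KeyError(f"unknown channel(s): {missing}")
        return np.array([lookup[c] for c in names], dtype=int)

    def copy_with(self, **kwargs) -> "EpochedRecording":
        return replace(self, **kwargs)


@dataclass
class Dataset:
    """A collection of recordings keyed by (participant_id, condition)."""

    recordings: dict[tuple[str, str], EpochedRecording]
    ground_truth: "object | None" = None

    def __iter__(self) -> Iterator[EpochedRecording]:
        return iter(self.recordings.values())

    def __len__(self) -> int:
        return len(self.recordings)

    def get(self, participant_id: str, condition: str) -> EpochedRecording:
        return self.recordings[(participant_id, condition)]

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid, _ in self.recordings:
            seen.setdefault(pid, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, cond in self.recordings:
            seen.setdefault(cond, None)
        return list(seen)

    def group_of(self, participant_id: str) -> str:
        for (pid, _), rec in self.recordings.items():
            if pid == participant_id:
                return rec.group
        raise KeyError(participant_id)

    def map_recordings(self, fn) -> "Dataset":
        """Apply ``fn`` to every recording, returning a new Dataset."""
        return Dataset(
            recordings={k: fn(r) for k, r in self.recordings.items()},
            ground_truth=self.ground_truth,
        )
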