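"""YAML-friendly construction of configuration dataclasses."""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .ersp import Band
from .pipeline import AnalysisConfig, RatingSpec
from .simulate import (
    ArtifactSpec,
    EvokedSpec,
    NoiseSpec,
    OscillationSpec,
    SimulationConfig,
)
from .tfr import WaveletSpec

__all__ = ["simulation_config_from_dict", "analysis_config_from_dict"]


def _build(cls, d: dict[str, Any]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise KeyError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def simulation_config_from_dict(d: dict[str, Any]) -> SimulationConfig:
    d = dict(d)
    for key, cls in (
        ("alpha_osc", OscillationSpec),
        ("beta_osc", OscillationSpec),
        ("noise", NoiseSpec),
        ("artifact", ArtifactSpec),
        ("evoked", EvokedSpec),
    ):
        if key in d and isinstance(d[key], dict):
            sub = {
                k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
            }
            d[key] = cls(**sub)
    return _build(SimulationConfig, d)


def analysis_config_from_dict(d: dict[str, Any]) -> AnalysisConfig:
    d = dict(d)
    if "simulation" in d and isinstance(d["simulation"], dict):
        d["simulation"] = simulation_config_from_dict(d["simulation"])
    for key, cls in (
        ("alpha_band", Band),
        ("beta_band", Band),
        ("wavelet", WaveletSpec),
        ("ratings", RatingSpec),
    ):
        if key in d and isinstance(d[key], dict):
            d[key] = cls(**d[key])
    if "tfr_freqs" in d and d["tfr_freqs"] is not None:
        d["tfr_freqs"] = np.asarray(d["tfr_freqs"], dtype=float)
    cfg = _build(AnalysisConfig, d)
    for key in ("sensor_roi", "brain_roi"):
        val = getattr(cfg, key)
        if val is not None:
            setattr(cfg, key, list(val))
    return cfg
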