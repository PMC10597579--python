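"""HDF5 container for epoched datasets.

Layout::

    /participants/<id>/<condition>/data   (trials x channels x samples)
        attrs: sampling_rate, t_start, group, site,
               channel_names, excluded_channels
    /  attrs: ground_truth (JSON, optional)

Round trips are lossless: arrays are stored as float64 and metadata is
validated on read, with an error naming any missing required key.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .containers import Dataset, EpochedRecording
from .simulate import GroundTruth

REQUIRED_ATTRS = ("sampling_rate", "t_start", "group", "site", "channel_names")


def write_dataset(dataset: Dataset, path: str) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("participants")
        for (pid, cond), rec in dataset.recordings.items():
            g = root.require_group(pid).create_group(cond)
            g.create_dataset("data", data=rec.data)
            g.attrs["sampling_rate"] = rec.sampling_rate
            g.attrs["t_start"] = rec.t_start
            g.attrs["group"] = rec.group
            g.attrs["site"] = rec.site
            g.attrs["channel_names"] = list(rec.channel_names)
            g.attrs["excluded_channels"] = list(rec.excluded_channels)
        if dataset.ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(dataset.ground_truth.to_dict())


def read_dataset(path: str) -> Dataset:
    recordings: dict[tuple[str, str], EpochedRecording] = {}
    with h5py.File(path, "r") as f:
        if "participants" not in f:
            raise KeyError(f"{path}: missing /participants group")
        for pid, pgroup in f["participants"].items():
            for cond, g in pgroup.items():
                if "data" not in g:
                    raise KeyError(f"{path}:/participants/{pid}/{cond}: missing data")
                for key in REQUIRED_ATTRS:
                    if key not in g.attrs:
                        raise KeyError(
                            f"{path}:/participants/{pid}/{cond}: "
                            f"missing required attribute {key!r}"
                        )
                names = [
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in g.attrs["channel_names"]
                ]
                excluded = [
                    c.decode() if isinstance(c, bytes) else str(c)
                    for c in g.attrs.get("excluded_channels", [])
                ]
                recordings[(pid, cond)] = EpochedRecording(
                    participant_id=pid,
                    group=str(g.attrs["group"]),
                    condition=cond,
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    t_start=float(g.attrs["t_start"]),
                    data=np.asarray(g["data"]),
                    channel_names=names,
                    site=str(g.attrs["site"]),
                    excluded_channels=excluded,
                )
        truth = None
        if "ground_truth" in f.attrs:
            truth = GroundTruth.from_dict(json.loads(f.attrs["ground_truth"]))
    return Dataset(recordings=recordings, ground_truth=truth)
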