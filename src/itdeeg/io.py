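"""Recording I/O.

Recordings round-trip through an ``.npz`` file (data in µV) with a JSON
sidecar for events and the embedded ground-truth configuration.  EDF import
is available through :mod:`mne` when installed (optional extra); EDF export
is not provided.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .stimuli import StimulusSpec
from .synth_eeg import (ArtifactModel, CaepTemplateParams, EEGRecording,
                        NoiseModel, SynthRecordingConfig)

__all__ = ["save_recording", "load_recording", "read_edf"]


def _config_to_dict(cfg: SynthRecordingConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["stimulus"] = cfg.stimulus.to_dict()
    return d


def _config_from_dict(d: dict) -> SynthRecordingConfig:
    d = dict(d)
    d["stimulus"] = StimulusSpec.from_dict(d["stimulus"])
    d["caep"] = CaepTemplateParams(**d["caep"])
    d["noise"] = NoiseModel(**d["noise"])
    d["artifact"] = ArtifactModel(**d["artifact"])
    d["channel_labels"] = tuple(d["channel_labels"])
    d["channel_gains"] = tuple(d["channel_gains"])
    return SynthRecordingConfig(**d)


def save_recording(path, rec: EEGRecording) -> None:
    path = Path(path)
    np.savez_compressed(path, data=rec.data,
                        clean=rec.clean_signal if rec.clean_signal is not None
                        else np.empty(0))
    meta = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "events": [[t, c] for t, c in rec.events],
        "artifact_trials": list(rec.artifact_trials),
        "ground_truth": _config_to_dict(rec.ground_truth)
        if rec.ground_truth is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(path) -> EEGRecording:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as z:
        data = z["data"]
        clean = z["clean"] if z["clean"].size else None
    meta = json.loads(path.with_suffix(".json").read_text())
    gt = meta.get("ground_truth")
    return EEGRecording(
        data=data, fs=float(meta["fs"]),
        channel_labels=tuple(meta["channel_labels"]),
        events=[(float(t), int(c)) for t, c in meta["events"]],
        ground_truth=_config_from_dict(gt) if gt else None,
        artifact_trials=tuple(meta.get("artifact_trials", [])),
        clean_signal=clean,
    )


def read_edf(path, channels: list[str] | None = None) -> EEGRecording:
    """Import a continuous EDF recording (requires mne); data scaled to µV.

    EDF annotations become events (condition id 0).
    """
    import mne  # optional dependency

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    data = raw.get_data() * 1e6
    events = [(float(a["onset"]), 0) for a in raw.annotations] or [(0.0, 0)]
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_labels=tuple(raw.ch_names), events=events)
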