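"""Serialization: array containers with JSON sidecars.

Epoch and parcel sets are written as a compressed ``.npz`` (the numeric
array) plus a ``.json`` sidecar holding channel/trial metadata, sampling
parameters and the generator's ground truth; melodies go to JSON and
behavioral tables to CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import ChannelInfo
from .synth import EpochSet, GroundTruth, ParcelSet


def _trials_records(trials: pd.DataFrame | None):
    if trials is None:
        return None
    recs = trials.to_dict(orient="records")
    for r in recs:
        r["correct"] = bool(r["correct"])
    return recs


def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write ``<path>.npz`` (data) and ``<path>.json`` (metadata)."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=epochs.data)
    meta = {
        "kind": "epochs",
        "sfreq": epochs.sfreq,
        "t0": epochs.t0,
        "channels": [dataclasses.asdict(ch) for ch in epochs.channels],
        "trials": _trials_records(epochs.trials),
        "ground_truth": (epochs.ground_truth.to_dict()
                         if epochs.ground_truth else None),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    channels = [
        ChannelInfo(c["name"], c["kind"], c["site"], c["pair_index"],
                    tuple(c["pos2d"]))
        for c in meta["channels"]
    ]
    gt = (GroundTruth.from_dict(meta["ground_truth"])
          if meta["ground_truth"] else None)
    return EpochSet(data, channels, meta["sfreq"], meta["t0"],
                    pd.DataFrame(meta["trials"]), gt)


def save_parcels(parcels: ParcelSet, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=parcels.data)
    meta = {
        "kind": "parcels",
        "sfreq": parcels.sfreq,
        "role": parcels.role,
        "parcel_names": list(parcels.parcel_names),
        "trials": _trials_records(parcels.trials),
        "ground_truth": (parcels.ground_truth.to_dict()
                         if parcels.ground_truth else None),
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_parcels(path: str | Path) -> ParcelSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))["data"]
    meta = json.loads(path.with_suffix(".json").read_text())
    gt = (GroundTruth.from_dict(meta["ground_truth"])
          if meta["ground_truth"] else None)
    trials = pd.DataFrame(meta["trials"]) if meta["trials"] else None
    return ParcelSet(data, meta["sfreq"], meta["role"],
                     tuple(meta["parcel_names"]), trials, gt)
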