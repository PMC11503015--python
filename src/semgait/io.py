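"""HDF5 / CSV serialization of recordings, feature stores and checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import ANGLE_CHANNELS, EMG_CHANNELS, PRESSURE_CHANNELS, GaitLabelSeries, Recording
from .errors import DataError
from .features import FeatureSet

__all__ = [
    "save_recording", "load_recording", "recording_to_csv",
    "save_features", "load_features", "save_checkpoint", "load_checkpoint",
]


def save_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording to HDF5: /semg, /pressure, /angles, /labels with
    sampling_rate, channel names and provenance attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("semg", data=rec.semg, compression="gzip")
        f.create_dataset("pressure", data=rec.pressure, compression="gzip")
        f.create_dataset("angles", data=rec.angles, compression="gzip")
        if rec.labels is not None:
            f.create_dataset("labels", data=rec.labels.codes, compression="gzip")
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["emg_channels"] = list(EMG_CHANNELS)
        f.attrs["pressure_channels"] = list(PRESSURE_CHANNELS)
        f.attrs["angle_channels"] = list(ANGLE_CHANNELS)
        f.attrs["meta"] = json.dumps(rec.meta, sort_keys=True)


def load_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        fs = float(f.attrs["sampling_rate"])
        labels = None
        if "labels" in f:
            labels = GaitLabelSeries(codes=f["labels"][...], sampling_rate=fs)
        return Recording(
            semg=f["semg"][...],
            pressure=f["pressure"][...],
            angles=f["angles"][...],
            labels=labels,
            sampling_rate=fs,
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def recording_to_csv(rec: Recording, path: str | Path) -> None:
    """Long-form CSV export for inspection (one row per sample)."""
    cols = ([f"semg_{c}" for c in EMG_CHANNELS]
            + [f"pressure_{c}" for c in PRESSURE_CHANNELS]
            + [f"angle_{c}" for c in ANGLE_CHANNELS])
    blocks = [rec.semg, rec.pressure, rec.angles]
    if rec.labels is not None:
        cols.append("gait")
        blocks.append(rec.labels.codes[:, None].astype(float))
    data = np.hstack(blocks)
    header = "sample," + ",".join(cols)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i, row in enumerate(data):
            fh.write(str(i) + "," + ",".join(f"{v:.6g}" for v in row) + "\n")


def save_features(fs_: FeatureSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for name in ("raw", "td", "spec", "gait", "angles", "window_start",
                     "cycle_index"):
            f.create_dataset(name, data=getattr(fs_, name), compression="gzip")
        f.attrs["sampling_rate"] = fs_.sampling_rate
        f.attrs["meta"] = json.dumps(fs_.meta, sort_keys=True)


def load_features(path: str | Path) -> FeatureSet:
    with h5py.File(path, "r") as f:
        return FeatureSet(
            raw=f["raw"][...], td=f["td"][...], spec=f["spec"][...],
            gait=f["gait"][...], angles=f["angles"][...],
            window_start=f["window_start"][...], cycle_index=f["cycle_index"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            meta=json.loads(f.attrs.get("meta", "{}")),
        )


def save_checkpoint(state: dict[str, np.ndarray], meta: dict, path: str | Path) -> None:
    """Model weights plus a JSON metadata blob (config hash, seed, history)."""
    np.savez_compressed(path, __meta__=json.dumps(meta, sort_keys=True), **state)


def load_checkpoint(path: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path, allow_pickle=False) as z:
        if "__meta__" not in z:
            raise DataError("not a semgait checkpoint (missing metadata)")
        meta = json.loads(str(z["__meta__"]))
        state = {k: z[k] for k in z.files if k != "__meta__"}
    return state, meta
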