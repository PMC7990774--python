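"""Epoch container format and continuous-EDF ingestion.

The on-disk epoch container is a small self-describing HDF5 file::

    /data            float32, trials x channels x samples
    /labels          int64 vector
    /channel_names   UTF-8 string vector
    attrs: fs (Hz), class_names, schema_version

Payloads are float32 (EEG dynamic range does not need float64 on disk);
labels are integers with a class-name lookup.  Continuous recordings come in
as EDF (read through MNE) plus a CSV marker table with columns
``sample_index, label``.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np

from .epochs import EpochSet
from .montage import Montage
from .preprocess import ContinuousRecording

__all__ = ["SchemaError", "SCHEMA_VERSION", "read_container", "write_container", "read_continuous_edf"]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """The container is missing a required dataset or attribute."""


def write_container(
    epochs: EpochSet,
    path: str | Path,
    class_names: tuple[str, ...] | None = None,
) -> None:
    """Write an :class:`EpochSet` to an HDF5 epoch container (atomically)."""
    path = Path(path)
    if class_names is None:
        class_names = tuple(f"class_{c}" for c in epochs.classes)
    tmp = path.with_name(path.name + ".tmp")
    try:
        with h5py.File(tmp, "w") as f:
            f.create_dataset("data", data=epochs.data.astype(np.float32))
            f.create_dataset("labels", data=epochs.labels.astype(np.int64))
            f.create_dataset(
                "channel_names",
                data=np.array(epochs.channel_names, dtype=h5py.string_dtype("utf-8")),
            )
            f.attrs["fs"] = float(epochs.fs)
            f.attrs["class_names"] = list(class_names)
            f.attrs["schema_version"] = SCHEMA_VERSION
        os.replace(tmp, path)
    finally:
        tmp.unlink(missing_ok=True)


def read_container(path: str | Path) -> EpochSet:
    """Read and validate an HDF5 epoch container."""
    with h5py.File(path, "r") as f:
        for name in ("data", "labels", "channel_names"):
            if name not in f:
                raise SchemaError(f"container is missing dataset '/{name}'")
        for attr in ("fs", "schema_version"):
            if attr not in f.attrs:
                raise SchemaError(f"container is missing attribute '{attr}'")
        data = np.asarray(f["data"])
        labels = np.asarray(f["labels"])
        names = tuple(
            c.decode("utf-8") if isinstance(c, bytes) else str(c) for c in f["channel_names"]
        )
        fs = float(f.attrs["fs"])
        class_names = [str(c) for c in f.attrs.get("class_names", [])]
    if data.ndim != 3:
        raise SchemaError(f"/data must be 3-D, got shape {data.shape}")
    if labels.shape != (data.shape[0],):
        raise SchemaError("/labels length does not match the trial count")
    if len(names) != data.shape[1]:
        raise SchemaError("/channel_names length does not match the channel count")
    if class_names and (labels.min() < 0 or labels.max() >= len(class_names)):
        raise SchemaError("labels fall outside the class_names range")
    return EpochSet(data=data, labels=labels, channel_names=names, fs=fs)


def read_continuous_edf(path: str | Path, marker_csv: str | Path) -> ContinuousRecording:
    """Load a continuous EDF recording and attach a CSV marker table.

    The marker CSV needs columns ``sample_index`` and ``label``.  Channel
    names and the (uniform) sampling rate come from the EDF header.
    """
    import mne
    import pandas as pd

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    values = raw.get_data()
    montage = Montage(tuple(raw.ch_names))

    table = pd.read_csv(marker_csv)
    for col in ("sample_index", "label"):
        if col not in table.columns:
            raise SchemaError(f"marker table is missing column '{col}'")
    markers = [(int(r.sample_index), int(r.label)) for r in table.itertuples()]
    return ContinuousRecording(values=values, fs=fs, montage=montage, markers=markers)
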