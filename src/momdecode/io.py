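"""Serialization: HDF5 epoch containers and MAT-format epoch import.

The HDF5 layout is documented and stable:

* ``data`` — float32 dataset, trials x sensors x samples
* ``time_ms`` — per-sample times
* attributes ``fs_hz``, ``subject_id``
* group ``labels`` — one dataset per label column (strings stored as UTF-8)

:func:`load_deposited_epochs` maps externally deposited MAT-format epoch
files (as produced by :func:`save_epochs_mat` or compatible layouts) into
an :class:`~momdecode.epochs.EpochSet`; it is schema-tolerant about key
names and raises an explicit error listing the keys it found otherwise.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .epochs import DistanceBinnedSet, EpochSet

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_binned",
    "load_binned",
    "save_epochs_mat",
    "load_deposited_epochs",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised when a deposited file's layout cannot be interpreted."""


def _write_labels(grp: h5py.Group, labels: pd.DataFrame) -> None:
    for col in labels.columns:
        vals = labels[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind in "U":
            grp.create_dataset(
                col, data=np.asarray(vals, dtype=object),
                dtype=h5py.string_dtype("utf-8"),
            )
        else:
            grp.create_dataset(col, data=vals)


def _read_labels(grp: h5py.Group) -> pd.DataFrame:
    cols = {}
    for col in grp:
        vals = grp[col][()]
        if vals.dtype.kind in ("S", "O"):
            vals = np.array([v.decode() if isinstance(v, bytes) else v for v in vals])
        cols[col] = vals
    return pd.DataFrame(cols)


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("time_ms", data=epochs.time_ms)
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["subject_id"] = epochs.subject_id
        _write_labels(f.create_group("labels"), epochs.labels)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            time_ms=f["time_ms"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            labels=_read_labels(f["labels"]),
            subject_id=str(f.attrs["subject_id"]),
        )


def save_binned(path: str | Path, binned: DistanceBinnedSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=binned.features.astype(np.float32))
        f.create_dataset("bin_edges_ms", data=binned.bin_edges_ms)
        f.attrs["subject_id"] = binned.subject_id
        f.attrs["pooled"] = binned.pooled
        _write_labels(f.create_group("labels"), binned.labels)


def load_binned(path: str | Path) -> DistanceBinnedSet:
    with h5py.File(path, "r") as f:
        return DistanceBinnedSet(
            features=f["features"][()],
            bin_edges_ms=f["bin_edges_ms"][()],
            labels=_read_labels(f["labels"]),
            subject_id=str(f.attrs["subject_id"]),
            pooled=bool(f.attrs["pooled"]),
        )


#: Key aliases accepted when importing deposited MAT-format epochs.
_DATA_KEYS = ("data", "X", "epochs", "meg_data")
_TIME_KEYS = ("time_ms", "time", "times")
_FS_KEYS = ("fs", "fs_hz", "srate", "sampling_rate")


def save_epochs_mat(path: str | Path, epochs: EpochSet) -> None:
    """Write an EpochSet to a MAT-compatible container (round-trip format)."""
    import scipy.io

    payload = {
        "data": epochs.data,
        "time_ms": epochs.time_ms,
        "fs": epochs.fs_hz,
        "subject_id": epochs.subject_id,
    }
    for col in epochs.labels.columns:
        payload[f"label_{col}"] = epochs.labels[col].to_numpy()
    scipy.io.savemat(path, payload)


def load_deposited_epochs(path: str | Path) -> EpochSet:
    """Load MAT-format epochs into an EpochSet (optional input path).

    Accepts v5/v7 MAT files via scipy and v7.3 (HDF5) files via h5py.
    Expects a trials x sensors x samples array under one of
    ``data/X/epochs/meg_data``, a time axis, a sampling rate, and
    ``label_*`` arrays; raises :class:`SchemaError` naming the keys found
    otherwise.
    """
    try:
        import scipy.io

        raw = scipy.io.loadmat(path, squeeze_me=True)
    except NotImplementedError:  # MAT v7.3 falls back to HDF5
        with h5py.File(path, "r") as f:
            raw = {k: f[k][()] for k in f}
    keys = [k for k in raw if not k.startswith("__")]

    def pick(cands):
        for k in cands:
            if k in raw:
                return raw[k]
        return None

    data = pick(_DATA_KEYS)
    time_ms = pick(_TIME_KEYS)
    fs = pick(_FS_KEYS)
    label_cols = {k[len("label_"):]: np.atleast_1d(raw[k]) for k in keys
                  if k.startswith("label_")}
    if data is None or time_ms is None or fs is None or not label_cols:
        raise SchemaError(
            "unrecognized epoch layout: expected a data array "
            f"({'/'.join(_DATA_KEYS)}), a time axis, a sampling rate and "
            f"label_* columns; found keys {sorted(keys)}"
        )
    labels = pd.DataFrame(
        {
            c: np.array([v.strip() if isinstance(v, str) else v for v in vals])
            for c, vals in label_cols.items()
        }
    )
    return EpochSet(
        data=np.asarray(data),
        time_ms=np.atleast_1d(np.asarray(time_ms, dtype=float).squeeze()),
        fs_hz=float(np.asarray(fs).squeeze()),
        labels=labels,
        subject_id=str(raw.get("subject_id", "deposited")).strip(),
    )
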