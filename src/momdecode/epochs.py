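"""Epoched sensor data containers and preprocessing.

The data model follows the common M/EEG convention of a ``trials x sensors x
samples`` array with a per-trial label table.  Preprocessing implemented here
covers the steps the decoding pipeline needs:

* anti-aliased downsampling (e.g. 1000 Hz acquisition -> 200 Hz analysis),
* per-trial division of the onset-to-deflection span into 15 ordinal
  "distance to object" bins (bin 15 = dot just appeared, bin 1 = nearest the
  central object), with uniform within-bin decimation to a fixed number of
  samples per bin,
* pooling of the two directions of approach under shared distance labels so
  that distance decoding is direction-invariant,
* seeded trial-count equalization across condition cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "EpochSet",
    "DistanceBinnedSet",
    "SensorGroups",
    "default_sensor_groups",
    "downsample",
    "bin_distances",
    "pool_directions",
    "equalize_trial_counts",
]


@dataclass
class EpochSet:
    """Epoched multi-sensor time series with a per-trial label table.

    ``data`` has shape ``(n_trials, n_sensors, n_samples)``; ``time_ms`` is
    the shared (strictly increasing, uniformly spaced) time axis in
    milliseconds relative to dot onset; ``labels`` carries one row per trial
    (direction, attended, condition, epoch_half, block, outcome,
    deflection_ms, ...).
    """

    data: np.ndarray
    time_ms: np.ndarray
    fs_hz: float
    labels: pd.DataFrame
    subject_id: str = "S01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis length does not match data")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label rows must equal trial count")
        steps = np.diff(self.time_ms)
        if self.time_ms.size > 1:
            expected = 1000.0 / self.fs_hz
            if not np.all(steps > 0):
                raise ValueError("time axis must be strictly increasing")
            if not np.allclose(steps, expected, atol=1e-6):
                raise ValueError("time axis must be uniform at 1000/fs_hz")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            time_ms=self.time_ms,
            fs_hz=self.fs_hz,
            labels=self.labels.iloc[mask].reset_index(drop=True),
            subject_id=self.subject_id,
        )


@dataclass
class DistanceBinnedSet:
    """Per-trial ordinal distance-bin features.

    ``features`` has shape ``(n_trials, n_bins, n_sensors,
    samples_per_bin)``; index ``d - 1`` along the bin axis holds distance
    ``d`` (1 = nearest the central object, ``n_bins`` = farthest / dot just
    appeared).  Feature vectors are flattened sensor-major, time-minor by
    :meth:`feature_matrix`.
    """

    features: np.ndarray
    bin_edges_ms: np.ndarray  # (n_trials, n_bins + 1), onset -> deflection
    labels: pd.DataFrame
    subject_id: str = "S01"
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.features.ndim != 4:
            raise ValueError("features must be trials x bins x sensors x samples")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("label rows must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_bins(self) -> int:
        return self.features.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.features.shape[2]

    def select(self, mask: np.ndarray) -> "DistanceBinnedSet":
        mask = np.asarray(mask)
        return replace(
            self,
            features=self.features[mask],
            bin_edges_ms=self.bin_edges_ms[mask],
            labels=self.labels.iloc[mask].reset_index(drop=True),
        )

    def feature_matrix(self, sensors: Sequence[int] | None = None) -> np.ndarray:
        """Flattened features ``(n_trials, n_bins, n_features)``.

        Flattening is sensor-major, time-minor: all within-bin samples of
        sensor 0 first, then sensor 1, and so on.  ``sensors`` restricts to a
        sensor subset (used for sensor-group analyses).
        """
        feats = self.features
        if sensors is not None:
            feats = feats[:, :, np.asarray(sensors, dtype=int), :]
        n_tr, n_b = feats.shape[:2]
        return feats.reshape(n_tr, n_b, -1)


class SensorGroups:
    """Named map from group name to sensor index array."""

    def __init__(self, groups: Mapping[str, Sequence[int]], n_sensors: int):
        self.n_sensors = int(n_sensors)
        self.groups: dict[str, np.ndarray] = {}
        for name, idx in groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError(f"sensor group {name!r} is empty")
            if idx.min() < 0 or idx.max() >= self.n_sensors:
                raise ValueError(f"sensor group {name!r} has out-of-range indices")
            self.groups[name] = idx

    def __getitem__(self, name: str) -> np.ndarray:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def names(self) -> list[str]:
        return list(self.groups)


def default_sensor_groups(n_sensors: int) -> SensorGroups:
    """Default peri-frontal / peri-occipital groups.

    The first quartile of the sensor index range stands in for peri-frontal
    sensors and the last quartile for peri-occipital ones (real helmet
    layouts would supply explicit index sets).
    """
    q = max(1, n_sensors // 4)
    return SensorGroups(
        {
            "frontal": np.arange(q),
            "occipital": np.arange(n_sensors - q, n_sensors),
            "all": np.arange(n_sensors),
        },
        n_sensors=n_sensors,
    )


def downsample(epochs: EpochSet, target_fs: float) -> EpochSet:
    """Anti-alias low-pass filter and decimate to ``target_fs``.

    ``target_fs`` must divide the current sampling rate.  The sample at the
    first time point is always retained, so a -100..3000 ms epoch at 1000 Hz
    (3101 samples) yields 621 samples at 200 Hz.
    """
    q = epochs.fs_hz / float(target_fs)
    if abs(q - round(q)) > 1e-9:
        raise ValueError(
            f"target_fs={target_fs} does not divide fs_hz={epochs.fs_hz}"
        )
    q = int(round(q))
    if q == 1:
        return replace(epochs, data=epochs.data.copy())
    out = scipy.signal.decimate(
        epochs.data.astype(np.float64, copy=False), q, axis=-1,
        ftype="fir", zero_phase=True,
    )
    return EpochSet(
        data=out.astype(np.float32),
        time_ms=epochs.time_ms[::q].copy(),
        fs_hz=float(target_fs),
        labels=epochs.labels.copy(),
        subject_id=epochs.subject_id,
    )


def bin_distances(
    epochs: EpochSet, n_bins: int = 15, samples_per_bin: int = 5
) -> DistanceBinnedSet:
    """Divide each trial's onset-to-deflection span into ordinal distance bins.

    The dot moves at constant speed, so equal time windows are equal distance
    steps.  Each retained sample is assigned to the temporally closest bin
    centre; because the windows are equal width this is the containing
    window, and a sample exactly on a boundary goes to the later
    (nearer-object, lower-distance) bin.  Within each bin the samples are
    decimated uniformly to ``samples_per_bin`` so feature vectors have equal
    length across trials.
    """
    defl = epochs.labels["deflection_ms"].to_numpy(dtype=float)
    if np.any(~np.isfinite(defl)) or np.any(defl <= 0):
        raise ValueError("every trial needs a positive deflection_ms")
    t = epochs.time_ms
    n_tr, n_sens = epochs.n_trials, epochs.n_sensors
    feats = np.empty((n_tr, n_bins, n_sens, samples_per_bin), dtype=np.float32)
    edges = np.empty((n_tr, n_bins + 1))
    for i in range(n_tr):
        d = defl[i]
        edges[i] = np.linspace(0.0, d, n_bins + 1)
        in_span = (t >= 0.0) & (t < d)
        ts = t[in_span]
        window = np.minimum((ts * n_bins / d).astype(int), n_bins - 1)
        base = np.flatnonzero(in_span)
        for w in range(n_bins):
            idx = base[window == w]
            if idx.size < samples_per_bin:
                raise ValueError(
                    f"trial {i}: bin {w} has {idx.size} samples, "
                    f"fewer than samples_per_bin={samples_per_bin}"
                )
            keep = idx[np.round(np.linspace(0, idx.size - 1, samples_per_bin)).astype(int)]
            # window 0 is the far end of the trajectory: distance index n_bins-1
            feats[i, n_bins - 1 - w] = epochs.data[i][:, keep]
    return DistanceBinnedSet(
        features=feats,
        bin_edges_ms=edges,
        labels=epochs.labels.copy(),
        subject_id=epochs.subject_id,
        pooled=False,
    )


def pool_directions(binned: DistanceBinnedSet) -> DistanceBinnedSet:
    """Pool left/right approaches under shared distance-class labels.

    After pooling, distance decoding treats a trial's bin-``d`` feature
    vector as a sample of class ``d`` regardless of the direction of
    approach, so the direction signal cannot drive distance classification.
    The direction label is retained for bookkeeping.  Idempotent.
    """
    dirs = set(binned.labels["direction"].unique())
    if dirs != {"left", "right"}:
        raise ValueError(f"both directions required for pooling, found {sorted(dirs)}")
    return replace(binned, pooled=True)


def equalize_trial_counts(
    sets: Mapping[str, np.ndarray], seed: int
) -> dict[str, np.ndarray]:
    """Subsample every labelled trial-index set to the global minimum count.

    Sampling is without replacement with a seeded generator; raises if any
    set is empty, naming the offending condition.
    """
    for name, idx in sets.items():
        if np.asarray(idx).size == 0:
            raise ValueError(f"condition {name!r} has no trials")
    n_min = min(np.asarray(idx).size for idx in sets.values())
    rng = np.random.default_rng(seed)
    out = {}
    for name, idx in sets.items():
        idx = np.asarray(idx)
        if idx.size == n_min:
            out[name] = idx.copy()
        else:
            out[name] = np.sort(rng.choice(idx, size=n_min, replace=False))
    return out
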