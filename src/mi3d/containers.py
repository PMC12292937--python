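"""Core in-memory containers for continuous and epoched EEG.

A :class:`Recording` holds a continuous multichannel signal (channels x
samples, microvolts) together with its sampling rate and the event markers
extracted from the acquisition software.  A :class:`TrialSet` holds the
epoched counterpart: a ``(n_trials, n_channels, n_samples)`` array with one
integer class label per trial.

Both containers round-trip losslessly through a small HDF5 layout with fixed
dataset names (``/data``, ``/labels``, ``/fs``, ``/channel_names``,
``/events``) so that fixtures are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = ["Recording", "TrialSet", "save_hdf5", "load_hdf5"]


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    channel_names : list of str
        Ordered electrode labels (10-20 style); must be unique.
    fs : float
        Sampling rate in Hz, > 0.
    events : list of (int, int)
        ``(sample_index, label_code)`` pairs; every index must fall inside
        the recording.
    """

    data: np.ndarray
    channel_names: list[str]
    fs: float
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n = self.data.shape[1]
        for s, _code in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside recording of length {n}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Same metadata, new signal matrix (must keep the channel count)."""
        if data.shape[0] != self.n_channels:
            raise ValueError("channel count must be preserved")
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class TrialSet:
    """Epoched EEG trials with class labels.

    ``trials`` has shape ``(n_trials, n_channels, n_samples)``; ``labels``
    holds one integer class code per trial (1..4 for the four motor-imagery
    tasks).
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.trials.shape[1]:
            raise ValueError("channel_names length must match channel axis")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def select(self, idx) -> "TrialSet":
        """Subset of trials (by boolean mask or index array)."""
        idx = np.asarray(idx)
        return TrialSet(self.trials[idx], self.labels[idx], self.fs,
                        list(self.channel_names))

    def copy_with(self, trials: np.ndarray) -> "TrialSet":
        trials = np.asarray(trials, dtype=float)
        if trials.shape[0] != self.n_trials or trials.shape[1] != self.n_channels:
            raise ValueError("trial and channel counts must be preserved")
        return TrialSet(trials, self.labels.copy(), self.fs,
                        list(self.channel_names))


def save_hdf5(obj: Recording | TrialSet, path: str | Path) -> None:
    """Write a container to the fixed internal HDF5 layout.

    Layout: ``/data`` (2-D for recordings, 3-D for trial sets), ``/fs``,
    ``/channel_names`` (UTF-8), plus ``/events`` (n x 2) for recordings or
    ``/labels`` for trial sets.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=obj.data if isinstance(obj, Recording)
                         else obj.trials)
        f.create_dataset("fs", data=float(obj.fs))
        names = np.array(obj.channel_names, dtype=h5py.string_dtype("utf-8"))
        f.create_dataset("channel_names", data=names)
        if isinstance(obj, Recording):
            ev = np.array(obj.events, dtype=np.int64).reshape(-1, 2)
            f.create_dataset("events", data=ev)
        else:
            f.create_dataset("labels", data=obj.labels.astype(np.int64))


def load_hdf5(path: str | Path) -> Recording | TrialSet:
    """Read a container written by :func:`save_hdf5` (shape decides the type)."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("data", "fs", "channel_names"):
            if key not in f:
                raise ValueError(f"{path}: missing required dataset '/{key}'")
        data = f["data"][()]
        fs = float(f["fs"][()])
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["channel_names"][()]]
        if data.ndim == 2:
            events = [tuple(int(v) for v in row) for row in f["events"][()]] \
                if "events" in f else []
            return Recording(data, names, fs, events)
        if data.ndim == 3:
            if "labels" not in f:
                raise ValueError(f"{path}: 3-D data without '/labels'")
            return TrialSet(data, f["labels"][()], fs, names)
    raise ValueError(f"{path}: '/data' must be 2-D or 3-D")
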