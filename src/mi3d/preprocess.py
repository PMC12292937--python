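"""Reading, filtering, epoching and normalisation of EEG recordings.

The preprocessing chain mirrors a standard offline motor-imagery pipeline:
a 0.5-40 Hz zero-phase band-pass, a narrow 49.9-50.1 Hz band-stop against
mains interference, epoching into 3 s cue-locked trials (750 samples at
250 Hz) and per-trial per-channel z-scoring.

All IIR filters are 4th-order Butterworth designs applied forward-backward
(``scipy.signal.filtfilt``), so filtering is zero-phase and event latencies
are untouched.  File reading for the standard containers (BrainVision
triplets and GDF) is delegated to MNE; the internal HDF5 container is the
package's own fixture format.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from scipy import signal

from .containers import Recording, TrialSet, load_hdf5

__all__ = [
    "load_recording",
    "bandpass",
    "notch",
    "epoch",
    "normalize",
    "common_average",
    "bandpass_trials",
]

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-12


def _events_from_mne(raw) -> list[tuple[int, int]]:
    """Extract (sample, code) events from an MNE Raw's annotations.

    Marker descriptions of the form ``S1``/``S 1``/``Stimulus/S  1`` map to
    integer codes 1..n; anything non-numeric is skipped.
    """
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        token = str(desc).split("/")[-1].strip()
        if token.upper().startswith("S"):
            token = token[1:].strip()
        try:
            code = int(token)
        except ValueError:
            continue
        sample = int(round((onset - raw.first_time) * raw.info["sfreq"]))
        events.append((sample, code))
    return events


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load a continuous EEG recording.

    Parameters
    ----------
    path : path
        ``.vhdr`` (BrainVision header), ``.gdf`` or ``.h5``/``.hdf5`` file.
    format : {"brainvision", "gdf", "hdf5"}, optional
        Explicit container name; inferred from the suffix when omitted.

    Returns
    -------
    Recording
        Data in microvolts, channel order as stored in the file, events
        taken from the marker/annotation stream.
    """
    path = Path(path)
    if format is None:
        format = {".vhdr": "brainvision", ".gdf": "gdf",
                  ".h5": "hdf5", ".hdf5": "hdf5"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}; "
                             "pass format explicitly")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "hdf5":
        obj = load_hdf5(path)
        if not isinstance(obj, Recording):
            raise ValueError(f"{path}: HDF5 file holds epoched trials, "
                             "not a continuous recording")
        return obj

    import mne  # deferred: slow import

    if format == "brainvision":
        marker = path.with_suffix(".vmrk")
        if not marker.exists():
            raise FileNotFoundError(
                f"BrainVision marker file {marker} is missing "
                f"(required alongside {path.name})")
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif format == "gdf":
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {format!r}; "
                         "expected brainvision, gdf or hdf5")

    data = raw.get_data() * 1e6  # MNE stores volts; containers use microvolts
    return Recording(data, list(raw.ch_names), float(raw.info["sfreq"]),
                     _events_from_mne(raw))


def _butter_sos(kind: str, edges, fs: float, order: int = 4):
    return signal.butter(order, edges, btype=kind, fs=fs, output="sos")


def _filtfilt(data: np.ndarray, sos) -> np.ndarray:
    return signal.sosfiltfilt(sos, data, axis=-1)


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; ``low=0`` degenerates to a low-pass."""
    if not (0 <= low < high < rec.fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 <= low < high < fs/2; "
            f"got ({low}, {high}) at fs={rec.fs}")
    if low == 0:
        sos = _butter_sos("lowpass", high, rec.fs, order)
    else:
        sos = _butter_sos("bandpass", (low, high), rec.fs, order)
    return rec.copy_with(_filtfilt(rec.data, sos))


def notch(rec: Recording, low: float = 49.9, high: float = 50.1,
          order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop over [low, high] Hz (mains rejection)."""
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(
            f"stop-band edges must satisfy 0 < low < high < fs/2; "
            f"got ({low}, {high}) at fs={rec.fs}")
    sos = _butter_sos("bandstop", (low, high), rec.fs, order)
    return rec.copy_with(_filtfilt(rec.data, sos))


def common_average(rec: Recording) -> Recording:
    """Re-reference to the common average (optional, not part of defaults)."""
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def epoch(rec: Recording, tmin: float = 0.0, tmax: float = 3.0) -> TrialSet:
    """Cut one trial per event over the half-open window [event+tmin, event+tmax).

    Events whose window exceeds the recording bounds are rejected with a
    logged warning; an empty result raises.
    """
    if tmax <= tmin:
        raise ValueError("tmax must exceed tmin")
    n_samp = int(round((tmax - tmin) * rec.fs))
    trials, labels = [], []
    for sample, code in rec.events:
        start = sample + int(round(tmin * rec.fs))
        stop = start + n_samp
        if start < 0 or stop > rec.n_samples:
            logger.warning("event at sample %d: window [%d, %d) outside "
                           "recording of length %d; trial rejected",
                           sample, start, stop, rec.n_samples)
            continue
        trials.append(rec.data[:, start:stop])
        labels.append(code)
    if not trials:
        raise ValueError("no trial window fits inside the recording")
    return TrialSet(np.stack(trials), np.asarray(labels), rec.fs,
                    list(rec.channel_names))


def normalize(ts: TrialSet) -> TrialSet:
    """Per-trial, per-channel z-scoring (zero mean, unit variance).

    Constant channels are floored at sigma=1e-12 instead of raising, with a
    warning, so degenerate fixtures stay finite.
    """
    mean = ts.trials.mean(axis=2, keepdims=True)
    std = ts.trials.std(axis=2, keepdims=True)
    if np.any(std < VARIANCE_FLOOR):
        warnings.warn("constant channel encountered; variance floor applied",
                      RuntimeWarning, stacklevel=2)
    return ts.copy_with((ts.trials - mean) / np.maximum(std, VARIANCE_FLOOR))


def bandpass_trials(ts: TrialSet, low: float, high: float,
                    order: int = 4, detrend: bool = True) -> TrialSet:
    """Band-pass every trial; a 0 Hz lower edge becomes a low-pass.

    Trials are mean-detrended first when ``detrend`` is set, so the 0 Hz
    band family carries no DC offset.
    """
    if not (0 <= low < high < ts.fs / 2):
        raise ValueError(
            f"band edges must satisfy 0 <= low < high < fs/2; "
            f"got ({low}, {high}) at fs={ts.fs}")
    x = ts.trials
    if detrend:
        x = x - x.mean(axis=2, keepdims=True)
    if low == 0:
        sos = _butter_sos("lowpass", high, ts.fs, order)
    else:
        sos = _butter_sos("bandpass", (low, high), ts.fs, order)
    return ts.copy_with(signal.sosfiltfilt(sos, x, axis=2))
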