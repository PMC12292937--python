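"""Seeded synthetic four-class motor-imagery EEG.

Each trial is pink (1/f) background noise per channel — plus a shared
common-mode term standing in for volume conduction — with a class-specific
band-limited (8-13 Hz by default) oscillation added on top.  The rhythm's
per-channel amplitude follows the class's spatial pattern: a smooth Gaussian
bump over the scalp grid, one distinct centre per class (left/right central
and anterior/posterior midline), so spatial filters and spatial CNN kernels
have recoverable structure.

The ``snr`` parameter is the ratio of channel-averaged rhythm power to
channel-averaged background power; ``snr=0`` makes the classes statistically
indistinguishable.  Geometry defaults to the acquisition protocol being
emulated: 64 channels, 250 Hz, 3 s epochs, 4 balanced classes.

Optional artifact injection adds frontal blink transients (<3 Hz), 50 Hz
line noise with a fixed spatial gain profile (rank-one, so ICA can isolate
it) and broadband (>30 Hz) EMG bursts on random channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .containers import Recording, TrialSet
from .rep3d import standard_mapping

__all__ = ["SynthParams", "generate", "generate_recording",
           "inject_artifacts", "concatenate_trials"]

BACKGROUND_STD_UV = 10.0  # resting EEG amplitude scale
COMMON_MODE_GAIN = 0.5

# class -> Gaussian bump centre (row, col) on the 9x9 grid
CLASS_CENTERS = {1: (4, 2), 2: (4, 6), 3: (2, 4), 4: (6, 4)}
PATTERN_SIGMA = 1.5  # grid cells


@dataclass
class SynthParams:
    """Generator settings; defaults are the emulated study conditions."""

    n_channels: int = 64
    fs: float = 250.0
    epoch_s: float = 3.0
    trials_per_class: int = 100
    classes: int = 4
    rhythm_band: tuple[float, float] = (8.0, 13.0)
    snr: float = 1.0
    blink: bool = False
    line: bool = False
    emg: bool = False
    blink_rate: float = 0.5   # events per second
    emg_rate: float = 0.3
    line_amp_uv: float = 15.0
    seed: int = 0
    class_patterns: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.snr < 0:
            raise ValueError("snr must be non-negative")
        if self.trials_per_class < 2:
            raise ValueError("need at least 2 trials per class")
        if not 1 < self.classes <= 4:
            raise ValueError("classes must be 2..4")
        if self.n_channels > 64:
            raise ValueError("at most 64 channels (the packaged montage)")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_s))


def _montage_names(n: int) -> list[str]:
    return standard_mapping("64ch-1020").channels[:n]


def _default_patterns(params: SynthParams) -> np.ndarray:
    """(classes, channels) Gaussian bumps over the packaged grid."""
    mapping = standard_mapping("64ch-1020")
    names = _montage_names(params.n_channels)
    pats = np.zeros((params.classes, params.n_channels))
    for k in range(params.classes):
        r0, c0 = CLASS_CENTERS[k + 1]
        for i, name in enumerate(names):
            r, c = mapping.placements[name]
            d2 = (r - r0) ** 2 + (c - c0) ** 2
            pats[k, i] = np.exp(-d2 / (2 * PATTERN_SIGMA ** 2))
    return pats


def _pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                fs: float) -> np.ndarray:
    """Rows of unit-variance 1/f-amplitude noise (spectrally shaped white)."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _narrowband(rng: np.random.Generator, n_samples: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    s = signal.sosfiltfilt(sos, rng.standard_normal(n_samples + 2 * int(fs)))
    s = s[int(fs):int(fs) + n_samples]  # drop filter warm-up
    return s / max(s.std(), 1e-12)


def _background(rng, n_channels, n_samples, fs) -> np.ndarray:
    bg = _pink_noise(rng, n_channels, n_samples, fs)
    common = _pink_noise(rng, 1, n_samples, fs)
    bg = bg + COMMON_MODE_GAIN * common
    return BACKGROUND_STD_UV * bg / bg.std(axis=1, keepdims=True)


def _rhythm_gains(params: SynthParams, patterns: np.ndarray) -> np.ndarray:
    """Per-class channel amplitudes delivering the requested SNR."""
    if params.snr == 0:
        return np.zeros_like(patterns)
    gains = np.empty_like(patterns)
    for k in range(patterns.shape[0]):
        scale = np.sqrt(params.snr * BACKGROUND_STD_UV ** 2
                        / np.mean(patterns[k] ** 2))
        gains[k] = scale * patterns[k]
    return gains


def generate(params: SynthParams | None = None) -> tuple[TrialSet, dict]:
    """Balanced, seeded four-class trial set plus its ground-truth record."""
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed)
    patterns = (params.class_patterns if params.class_patterns is not None
                else _default_patterns(params))
    gains = _rhythm_gains(params, patterns)
    names = _montage_names(params.n_channels)
    n_samp = params.n_samples

    trials, labels = [], []
    for k in range(params.classes):
        for _ in range(params.trials_per_class):
            x = _background(rng, params.n_channels, n_samp, params.fs)
            s = _narrowband(rng, n_samp, params.fs, params.rhythm_band)
            x = x + gains[k][:, None] * s
            trials.append(x)
            labels.append(k + 1)
    ts = TrialSet(np.stack(trials), np.asarray(labels), params.fs, names)
    truth = {"patterns": patterns, "gains": gains,
             "rhythm_band": params.rhythm_band, "snr": params.snr,
             "seed": params.seed}
    if params.blink or params.line or params.emg:
        ts = inject_artifacts(ts, params)
    return ts, truth


def generate_recording(params: SynthParams | None = None,
                       gap_s: float = 1.0) -> Recording:
    """Continuous recording: trials separated by background-only gaps.

    Event markers sit at each trial onset with the class code, so
    ``epoch(rec, 0, epoch_s)`` recovers the trial set.
    """
    params = params or SynthParams()
    # mains interference is continuous in a real recording, so the line
    # component is added over the full length below, not per trial
    trial_params = replace(params, line=False)
    ts, _ = generate(trial_params)
    rng = np.random.default_rng(params.seed + 1)
    order = rng.permutation(ts.n_trials)
    gap = int(round(gap_s * params.fs))
    chunks, events = [], []
    cursor = 0
    for t in order:
        pad = _background(rng, params.n_channels, gap, params.fs)
        chunks += [pad, ts.trials[t]]
        cursor += gap
        events.append((cursor, int(ts.labels[t])))
        cursor += ts.n_samples
    chunks.append(_background(rng, params.n_channels, gap, params.fs))
    data = np.concatenate(chunks, axis=1)
    if params.line:
        gain = params.line_amp_uv * rng.uniform(0.8, 1.2,
                                                size=params.n_channels)
        t_axis = np.arange(data.shape[1]) / params.fs
        data = data + gain[:, None] * np.sin(
            2 * np.pi * 50.0 * t_axis + rng.uniform(0, 2 * np.pi))
    return Recording(data, list(ts.channel_names), params.fs, events)


def concatenate_trials(ts: TrialSet) -> Recording:
    """Back-to-back trial concatenation with onset events (ICA convenience)."""
    data = np.concatenate(list(ts.trials), axis=1)
    events = [(i * ts.n_samples, int(l)) for i, l in enumerate(ts.labels)]
    return Recording(data, list(ts.channel_names), ts.fs, events)


def _frontal_weights(names: list[str]) -> np.ndarray:
    w = np.full(len(names), 0.05)
    for i, n in enumerate(names):
        up = n.upper()
        if up.startswith(("FP", "AF")):
            w[i] = 1.0
        elif up.startswith("F") and not up.startswith("FC") \
                and not up.startswith("FT"):
            w[i] = 0.4
    return w


def inject_artifacts(ts: TrialSet, params: SynthParams) -> TrialSet:
    """Add the enabled artifact types; all flags off returns the input as-is."""
    if not (params.blink or params.line or params.emg):
        return ts
    rng = np.random.default_rng(params.seed + 7)
    fs, n_samp = ts.fs, ts.n_samples
    t = np.arange(n_samp) / fs
    out = ts.trials.copy()

    frontal = _frontal_weights(list(ts.channel_names))
    # fixed per-channel line-noise gains: a rank-one spatial profile
    line_gain = params.line_amp_uv * rng.uniform(0.8, 1.2, size=ts.n_channels)

    for i in range(ts.n_trials):
        if params.blink:
            for _ in range(rng.poisson(params.blink_rate * n_samp / fs)):
                onset = rng.uniform(0, max(n_samp / fs - 0.4, 0.01))
                dur = 0.4
                mask = (t >= onset) & (t < onset + dur)
                pulse = np.zeros(n_samp)
                pulse[mask] = 0.5 * (1 - np.cos(2 * np.pi * (t[mask] - onset) / dur))
                out[i] += 80.0 * frontal[:, None] * pulse[None, :]
        if params.line:
            phase = rng.uniform(0, 2 * np.pi)
            out[i] += line_gain[:, None] * np.sin(2 * np.pi * 50.0 * t + phase)
        if params.emg:
            for _ in range(rng.poisson(params.emg_rate * n_samp / fs)):
                onset = rng.uniform(0, max(n_samp / fs - 0.2, 0.01))
                mask = (t >= onset) & (t < onset + 0.2)
                chans = rng.choice(ts.n_channels, size=min(5, ts.n_channels),
                                   replace=False)
                sos = signal.butter(4, 30.0, btype="highpass", fs=fs,
                                    output="sos")
                burst = signal.sosfiltfilt(sos, rng.standard_normal(n_samp))
                burst = burst / max(burst.std(), 1e-12)
                for c in chans:
                    out[i, c, mask] += 25.0 * burst[mask]
    return ts.copy_with(out)
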