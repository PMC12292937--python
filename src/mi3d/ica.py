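"""Automated ICA artifact rejection.

A recording is decomposed into a fixed number of independent components
(FastICA, deflation, seeded), each component is scored by a rule-based
labeller into one of seven classes (neural, emg, eog, ecg, line, impedance,
other), and every non-neural component whose probability exceeds a global
threshold (0.9 by default) is subtracted from the signal.

The labeller is deliberately pluggable: :func:`remove_artifacts` accepts any
list of :class:`ComponentLabel`, so a pretrained classifier can replace the
built-in heuristics.  The built-in rules score, per component:

* ``line``      - fraction of source power inside 49-51 Hz;
* ``eog``       - correlation with a <3 Hz frontal-channel proxy, gated on a
  frontally dominant mixing topography;
* ``emg``       - fraction of source power above 30 Hz;
* ``ecg``       - periodic autocorrelation peak at 0.8-1.5 s lag combined
  with spiky (high-kurtosis) sources;
* ``impedance`` - a mixing column concentrated (>0.8 of its l2 mass) on a
  single channel.

Raw scores are squashed to [0, 1] probabilities by fixed logistic maps;
a component is neural when no artifact rule fires above 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import FastICA

from .containers import Recording

__all__ = [
    "ICADecomposition",
    "ComponentLabel",
    "decompose",
    "label_components",
    "remove_artifacts",
    "clean_recording",
]

ARTIFACT_CLASSES = ("emg", "eog", "ecg", "line", "impedance")
FRONTAL_PREFIXES = ("FP", "AF")


@dataclass
class ICADecomposition:
    """Result of a seeded FastICA fit.

    ``sources = unmixing @ (data - mean)``; ``mixing @ sources + mean``
    reconstructs the data up to the subspace truncation when
    ``n_components < n_channels``.  Artifact removal subtracts component
    contributions, so the untruncated residual is always preserved.
    """

    unmixing: np.ndarray   # (n_components, n_channels)
    mixing: np.ndarray     # (n_channels, n_components)
    sources: np.ndarray    # (n_components, n_samples)
    mean: np.ndarray       # (n_channels,) channel means removed before fitting
    n_components: int


@dataclass
class ComponentLabel:
    component_index: int
    klass: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def decompose(rec: Recording, n_components: int = 15,
              seed: int = 0) -> ICADecomposition:
    """Fit seeded FastICA (deflation, tol 1e-4, <=500 iterations).

    Rank-deficient data triggers a component-count reduction with a warning
    rather than an error.
    """
    if n_components > rec.n_channels:
        raise ValueError(f"n_components={n_components} exceeds "
                         f"{rec.n_channels} channels")
    rank = np.linalg.matrix_rank(rec.data - rec.data.mean(axis=1, keepdims=True))
    if rank < n_components:
        warnings.warn(f"data rank {rank} < n_components {n_components}; "
                      "reducing", RuntimeWarning, stacklevel=2)
        n_components = int(rank)

    ica = FastICA(n_components=n_components, algorithm="deflation",
                  fun="logcosh", tol=1e-4, max_iter=500, whiten="unit-variance",
                  random_state=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on short fixtures
        sources = ica.fit_transform(rec.data.T).T
    return ICADecomposition(
        unmixing=np.asarray(ica.components_),
        mixing=np.asarray(ica.mixing_),
        sources=sources,
        mean=np.asarray(ica.mean_),
        n_components=n_components,
    )


def _logistic(x: float, center: float, gain: float) -> float:
    return float(1.0 / (1.0 + np.exp(-gain * (x - center))))


def _band_power_fraction(psd: np.ndarray, freqs: np.ndarray,
                         low: float, high: float) -> float:
    total = psd.sum()
    if total <= 0:
        return 0.0
    return float(psd[(freqs >= low) & (freqs <= high)].sum() / total)


def _frontal_mask(channel_names: list[str]) -> np.ndarray:
    up = [c.upper() for c in channel_names]
    return np.array([c.startswith(FRONTAL_PREFIXES) for c in up])


def label_components(ica: ICADecomposition, rec: Recording) -> list[ComponentLabel]:
    """Score every component with the built-in heuristics.

    Pure function of ``(ica, rec)``: repeated calls return identical labels.
    """
    fs = rec.fs
    frontal = _frontal_mask(rec.channel_names)
    # frontal low-pass proxy for ocular activity
    eog_proxy = None
    if frontal.any() and fs > 8:
        sos = signal.butter(4, 3.0, btype="lowpass", fs=fs, output="sos")
        eog_proxy = signal.sosfiltfilt(sos, rec.data[frontal].mean(axis=0))

    labels: list[ComponentLabel] = []
    for k in range(ica.n_components):
        src = ica.sources[k]
        col = ica.mixing[:, k]
        if src.std() < 1e-15 or np.linalg.norm(col) < 1e-15:
            labels.append(ComponentLabel(k, "other", 0.0))
            continue

        nper = min(len(src), int(fs) * 2)
        freqs, psd = signal.welch(src, fs=fs, nperseg=nper)
        col_l2 = col ** 2 / np.sum(col ** 2)

        probs: dict[str, float] = {}
        probs["line"] = _logistic(
            _band_power_fraction(psd, freqs, 49.0, 51.0), 0.6, 12.0)
        # EMG fraction excludes the mains band so a pure 50 Hz source
        # cannot masquerade as muscle activity
        emg_frac = (_band_power_fraction(psd, freqs, 30.0, fs / 2)
                    - _band_power_fraction(psd, freqs, 49.0, 51.0))
        probs["emg"] = _logistic(max(emg_frac, 0.0), 0.5, 12.0)
        probs["impedance"] = _logistic(col_l2.max(), 0.8, 25.0)

        eog_score = 0.0
        if eog_proxy is not None:
            frontal_mass = float(col_l2[frontal].sum())
            if frontal_mass > 0.4:  # topography gate
                c = np.corrcoef(src, eog_proxy)[0, 1]
                eog_score = abs(float(c)) if np.isfinite(c) else 0.0
        probs["eog"] = _logistic(eog_score, 0.7, 12.0)

        # ECG: periodic autocorrelation in the 0.8-1.5 s lag range plus
        # spiky amplitude distribution (QRS-like kurtosis)
        lag_lo, lag_hi = int(0.8 * fs), int(1.5 * fs)
        ecg_score = 0.0
        if lag_hi < len(src):
            s = src - src.mean()
            ac = signal.correlate(s, s, mode="full")[len(s) - 1:]
            ac = ac / ac[0]
            peak = float(ac[lag_lo:lag_hi + 1].max())
            from scipy.stats import kurtosis
            kurt = float(kurtosis(src))
            ecg_score = peak if kurt > 2.0 else 0.0
        probs["ecg"] = _logistic(ecg_score, 0.5, 10.0)

        best = max(ARTIFACT_CLASSES, key=lambda c: probs[c])
        if probs[best] > 0.5:
            labels.append(ComponentLabel(k, best, probs[best]))
        else:
            labels.append(ComponentLabel(k, "neural", 1.0 - probs[best]))
    return labels


def remove_artifacts(rec: Recording, ica: ICADecomposition,
                     labels: list[ComponentLabel],
                     threshold: float = 0.9) -> Recording:
    """Subtract non-neural components whose probability exceeds ``threshold``.

    Removal is a subtraction of ``mixing[:, k] @ sources[k]`` per flagged
    component, so the recording's non-ICA residual is untouched and a
    threshold of 1.0 is the exact identity.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    flagged = [l.component_index for l in labels
               if l.klass not in ("neural",) and l.probability > threshold]
    if len(flagged) == ica.n_components and ica.n_components > 0:
        raise ValueError("every component is flagged; refusing to delete "
                         "the entire recording")
    if not flagged:
        return rec.copy_with(rec.data.copy())
    artifact = ica.mixing[:, flagged] @ ica.sources[flagged]
    return rec.copy_with(rec.data - artifact)


def clean_recording(rec: Recording, n_components: int = 15, seed: int = 0,
                    threshold: float = 0.9):
    """decompose -> label -> remove in one call.

    Returns ``(cleaned recording, labels)`` so callers can report the
    per-component classification.
    """
    ica = decompose(rec, n_components=n_components, seed=seed)
    labels = label_components(ica, rec)
    return remove_artifacts(rec, ica, labels, threshold=threshold), labels
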