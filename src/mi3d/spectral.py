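"""Welch power-spectral-density features.

The Welch estimator splits a signal into length-``L`` segments whose starts
are ``D`` samples apart (overlap ``L - D``), windows each segment, corrects
each periodogram by the window power ``sum(w(n)^2)``, and averages.  The
one-sided density convention (power per Hz, divide by ``fs * sum(w^2)``) is
used throughout, under which Parseval holds: the integral of the PSD equals
the signal variance for broadband signals.

Defaults: ``L = fs`` (1 s segments, 1 Hz resolution), 50% overlap, Hamming
window, per-segment constant detrend, bins retained up to 40 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import TrialSet

__all__ = ["WelchParams", "PSDFeatures", "welch_psd", "psd_features",
           "psd_tensor"]


@dataclass
class WelchParams:
    """Segmentation and windowing parameters for the Welch estimator.

    ``D`` is the offset between segment starts (overlap = L - D); ``None``
    means 50% overlap.  ``fmax`` caps the retained frequency bins.
    """

    fs: float
    L: int | None = None
    D: int | None = None
    window: str = "hamming"
    fmax: float = 40.0
    detrend: str | bool = "constant"

    def resolved(self, n_samples: int) -> tuple[int, int]:
        L = int(self.fs) if self.L is None else int(self.L)
        D = L // 2 if self.D is None else int(self.D)
        if not 0 < D <= L:
            raise ValueError(f"need 0 < D <= L, got D={D}, L={L}")
        if L > n_samples:
            raise ValueError(f"signal of {n_samples} samples is shorter than "
                             f"the segment length L={L}")
        if self.fmax > self.fs / 2:
            raise ValueError("fmax cannot exceed the Nyquist rate")
        return L, D


@dataclass
class PSDFeatures:
    """Per-channel PSD matrix (channels x bins, power/Hz) and bin centers."""

    psd: np.ndarray
    freqs: np.ndarray


def welch_psd(x: np.ndarray, p: WelchParams) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD of a single-channel signal.

    Returns ``(freqs, psd)`` truncated at ``p.fmax``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("welch_psd expects a single-channel 1-D signal")
    L, D = p.resolved(len(x))
    freqs, psd = signal.welch(x, fs=p.fs, window=p.window, nperseg=L,
                              noverlap=L - D, detrend=p.detrend,
                              scaling="density")
    keep = freqs <= p.fmax
    return freqs[keep], psd[keep]


def psd_features(ts: TrialSet, p: WelchParams | None = None) -> list[PSDFeatures]:
    """Per-trial, per-channel Welch PSD features.

    All trials share the same bin grid, so the feature length is identical
    across trials.
    """
    p = p or WelchParams(fs=ts.fs)
    L, D = p.resolved(ts.n_samples)
    freqs, psd = signal.welch(ts.trials, fs=ts.fs, window=p.window,
                              nperseg=L, noverlap=L - D, detrend=p.detrend,
                              scaling="density", axis=-1)
    keep = freqs <= p.fmax
    return [PSDFeatures(psd=psd[t][:, keep], freqs=freqs[keep])
            for t in range(ts.n_trials)]


def psd_tensor(ts: TrialSet, p: WelchParams | None = None):
    """(freqs, array of shape (n_trials, n_channels, n_bins)) in one call."""
    feats = psd_features(ts, p)
    return feats[0].freqs, np.stack([f.psd for f in feats])
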