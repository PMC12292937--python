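"""Filter banks and the superimposed filter-bank CSP (SFB-CSP).

Three bank schemes cover the sub-40 Hz EEG rhythms:

* ``fixed_start`` — nine expanding bands sharing a 0 Hz lower cutoff with
  the upper edge growing in 4 Hz steps: (0,4), (0,8), ..., (0,36);
* ``sliding``     — eight overlapping 8 Hz bands stepping by 4 Hz:
  (0,8), (4,12), ..., (28,36);
* ``merged``      — the union of the two, 16 unique bands (the single
  shared band (0,8) is de-duplicated);
* ``fbcsp``       — the uniform-4 Hz baseline bank, eleven bands stepping
  from 4 Hz upward.

SFB-CSP trains one multi-class CSP+SVM per band on band-filtered trials and
predicts by majority vote across bands (ties: summed decision margins, then
lowest class index).  A 0 Hz lower edge is realised as a low-pass after
per-trial mean detrending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import MulticlassCSP, break_ties
from .containers import TrialSet
from .csp import GAParams
from .preprocess import bandpass_trials

__all__ = ["BandFilterSpec", "SFBModel", "build_filter_banks",
           "fit_sfbcsp", "predict_sfbcsp"]

SCHEMES = ("fixed_start", "sliding", "fbcsp", "merged")


@dataclass
class BandFilterSpec:
    """Ordered list of (low, high) band edges in Hz plus the scheme name."""

    bands: list[tuple[float, float]]
    scheme: str

    def __post_init__(self) -> None:
        for low, high in self.bands:
            if not low < high:
                raise ValueError(f"band ({low}, {high}) has low >= high")
        if self.scheme == "merged" and len(set(self.bands)) != len(self.bands):
            raise ValueError("merged scheme must not contain duplicate bands")

    def __len__(self) -> int:
        return len(self.bands)


def build_filter_banks(scheme: str) -> BandFilterSpec:
    """Construct one of the packaged band schemes."""
    if scheme == "fixed_start":
        bands = [(0.0, 4.0 * (i + 1)) for i in range(9)]
    elif scheme == "sliding":
        bands = [(4.0 * j, 4.0 * j + 8.0) for j in range(8)]
    elif scheme == "fbcsp":
        bands = [(4.0 + 4.0 * i, 8.0 + 4.0 * i) for i in range(11)]
    elif scheme == "merged":
        seen: list[tuple[float, float]] = []
        for b in (build_filter_banks("fixed_start").bands
                  + build_filter_banks("sliding").bands):
            if b not in seen:
                seen.append(b)
        bands = seen
    else:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return BandFilterSpec(bands=bands, scheme=scheme)


@dataclass
class SFBModel:
    """Per-band CSP+SVM ensemble with a cross-band voting rule."""

    banks: BandFilterSpec
    fitted_bands: list[tuple[float, float]] = field(default_factory=list)
    classifiers: list[MulticlassCSP] = field(default_factory=list)
    fs: float = 250.0
    classes_: np.ndarray | None = None

    @property
    def n_bands(self) -> int:
        return len(self.classifiers)


def fit_sfbcsp(ts: TrialSet, banks: BandFilterSpec, n_pairs: int = 4,
               strategy: str = "ovo", use_gene: bool = False,
               ga: GAParams | None = None, train_index=None) -> SFBModel:
    """Train one multi-class CSP+SVM per band.

    Bands whose upper edge reaches the Nyquist rate are dropped with a
    warning instead of failing the whole bank.
    """
    model = SFBModel(banks=banks, fs=ts.fs, classes_=np.unique(ts.labels))
    for low, high in banks.bands:
        if high >= ts.fs / 2:
            warnings.warn(f"band ({low}, {high}) reaches Nyquist at "
                          f"fs={ts.fs}; dropped", RuntimeWarning, stacklevel=2)
            continue
        filtered = bandpass_trials(ts, low, high)
        clf = MulticlassCSP(strategy=strategy, n_pairs=n_pairs,
                            use_gene=use_gene, ga=ga)
        clf.fit(filtered, train_index)
        model.fitted_bands.append((low, high))
        model.classifiers.append(clf)
    if not model.classifiers:
        raise ValueError("no band survived the Nyquist check")
    return model


def predict_sfbcsp(model: SFBModel, ts_or_trials) -> np.ndarray:
    """Majority vote across band classifiers (Eq.-style argmax over votes)."""
    if isinstance(ts_or_trials, TrialSet):
        ts = ts_or_trials
    else:
        trials = np.asarray(ts_or_trials, dtype=float)
        if trials.ndim == 2:
            trials = trials[None]
        names = [f"CH{i}" for i in range(trials.shape[1])]
        ts = TrialSet(trials, np.zeros(trials.shape[0], dtype=int),
                      model.fs, names)

    classes = model.classes_
    idx = {int(c): i for i, c in enumerate(classes)}
    n = ts.n_trials
    votes = np.zeros((n, len(classes)), dtype=int)
    margins = np.zeros((n, len(classes)))
    for (low, high), clf in zip(model.fitted_bands, model.classifiers):
        filtered = bandpass_trials(ts, low, high)
        pred = clf.predict(filtered)
        margins += clf.class_margins(filtered.trials)
        for t in range(n):
            votes[t, idx[int(pred[t])]] += 1
    return np.array([break_ties(votes[t], margins[t], classes)
                     for t in range(n)])
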