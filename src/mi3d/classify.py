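"""Multi-class CSP+SVM classification (one-vs-one / one-vs-rest).

CSP is inherently two-class, so four-class decoding decomposes into binary
subproblems: OVO fits one CSP+SVM per class pair (6 for four classes) and
predicts by majority vote; OVR fits one CSP+SVM per class-vs-rest (4) and
predicts by the largest decision value.  Ties in any vote are broken by the
highest summed decision-function margin, then by the lowest class index —
deterministic and documented.

The binary building block optionally replaces the fixed top-n/bottom-n row
selection with a GA-selected gene (the weighted-criterion variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TrialSet
from .csp import (CSPModel, GAParams, WeightGene, csp_features, fit_csp,
                  fit_wccsp, make_svm)

__all__ = ["BinaryCSPSVM", "MulticlassCSP", "fit_multiclass",
           "break_ties", "accuracy"]


def break_ties(votes: np.ndarray, margins: np.ndarray,
               classes: np.ndarray) -> int:
    """Deterministic vote resolution.

    Most votes wins; tied classes are compared on summed decision margins;
    a residual tie goes to the lowest class index.
    """
    top = votes == votes.max()
    if top.sum() == 1:
        return int(classes[int(np.argmax(votes))])
    cand = np.where(top)[0]
    m = margins[cand]
    best = cand[m == m.max()]
    return int(classes[best.min()])


@dataclass
class BinaryCSPSVM:
    """CSP features + RBF SVM for one class pair.

    ``n_pairs`` rows from each end of the eigenvalue-sorted filter matrix
    feed the SVM; when ``gene`` mode is active the rows come from a GA
    search instead.
    """

    class_a: int
    class_b: int
    n_pairs: int = 4
    use_gene: bool = False
    ga: GAParams | None = None
    model: CSPModel | None = None
    gene: WeightGene | None = None
    svm: object = None

    def _features(self, trials: np.ndarray) -> np.ndarray:
        if self.use_gene:
            # same routine as the plain path so an all-ones gene is bit-equal
            # to the untrimmed filter matrix
            from .csp import _log_var_features
            rows = self.gene.w.astype(bool)
            P_rows = self.model.P[rows]
            return np.stack([_log_var_features(P_rows, X) for X in trials])
        n = self.n_pairs
        return np.stack([csp_features(self.model, X, n_pairs=n)
                         for X in trials])

    def fit(self, ts: TrialSet) -> "BinaryCSPSVM":
        mask = np.isin(ts.labels, (self.class_a, self.class_b))
        sub = ts.select(mask)
        n = min(self.n_pairs, sub.n_channels // 2)
        self.n_pairs = n
        if self.use_gene:
            if self.gene is None:   # a preset gene skips the GA search
                self.gene, self.model, _ = fit_wccsp(
                    sub, self.class_a, self.class_b, self.ga)
            else:
                self.model = fit_csp(sub, self.class_a, self.class_b)
        else:
            self.model = fit_csp(sub, self.class_a, self.class_b)
        X = self._features(sub.trials)
        y = (sub.labels == self.class_a).astype(int)
        self.svm = make_svm()
        self.svm.fit(X, y)
        return self

    def decision(self, trials: np.ndarray) -> np.ndarray:
        """Signed margin per trial; positive favours ``class_a``."""
        X = self._features(trials)
        d = self.svm.decision_function(X)
        # sklearn orders binary classes as [0, 1]; d > 0 favours label 1 == class_a
        return np.asarray(d, dtype=float)


@dataclass
class MulticlassCSP:
    """OVO or OVR ensemble of :class:`BinaryCSPSVM` models."""

    strategy: str = "ovo"
    n_pairs: int = 4
    use_gene: bool = False
    ga: GAParams | None = None
    classes_: np.ndarray | None = None
    models_: list = field(default_factory=list)
    train_index: np.ndarray | None = None   # leakage bookkeeping

    def fit(self, ts: TrialSet, train_index=None) -> "MulticlassCSP":
        if self.strategy not in ("ovo", "ovr"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        self.classes_ = np.unique(ts.labels)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        for c in self.classes_:
            if (ts.labels == c).sum() < 2:
                raise ValueError(f"class {c} has fewer than 2 trials")
        self.train_index = (np.asarray(train_index)
                            if train_index is not None else None)
        self.models_ = []
        if self.strategy == "ovo":
            for i, a in enumerate(self.classes_):
                for b in self.classes_[i + 1:]:
                    m = BinaryCSPSVM(int(a), int(b), self.n_pairs,
                                     self.use_gene, self.ga)
                    self.models_.append(m.fit(ts))
        else:
            # OVR: relabel as class vs rest; rest carries code 0
            for a in self.classes_:
                rest = TrialSet(ts.trials,
                                np.where(ts.labels == a, int(a), 0),
                                ts.fs, list(ts.channel_names))
                m = BinaryCSPSVM(int(a), 0, self.n_pairs,
                                 self.use_gene, self.ga)
                self.models_.append(m.fit(rest))
        return self

    def class_margins(self, trials: np.ndarray) -> np.ndarray:
        """(n_trials, n_classes) summed decision margins."""
        n = trials.shape[0]
        margins = np.zeros((n, len(self.classes_)))
        idx = {int(c): i for i, c in enumerate(self.classes_)}
        for m in self.models_:
            d = m.decision(trials)
            margins[:, idx[m.class_a]] += d
            if self.strategy == "ovo":
                margins[:, idx[m.class_b]] -= d
        return margins

    def predict(self, ts_or_trials) -> np.ndarray:
        trials = (ts_or_trials.trials if isinstance(ts_or_trials, TrialSet)
                  else np.asarray(ts_or_trials, dtype=float))
        if trials.ndim == 2:
            trials = trials[None]
        n = trials.shape[0]
        idx = {int(c): i for i, c in enumerate(self.classes_)}
        margins = self.class_margins(trials)
        if self.strategy == "ovr":
            return self.classes_[np.argmax(margins, axis=1)]
        votes = np.zeros((n, len(self.classes_)), dtype=int)
        for m in self.models_:
            d = m.decision(trials)
            winner = np.where(d >= 0, idx[m.class_a], idx[m.class_b])
            for t in range(n):
                votes[t, winner[t]] += 1
        return np.array([break_ties(votes[t], margins[t], self.classes_)
                         for t in range(n)])

    def score(self, ts: TrialSet) -> float:
        return accuracy(self.predict(ts), ts.labels)


def fit_multiclass(ts: TrialSet, strategy: str = "ovo", n_pairs: int = 4,
                   use_gene: bool = False, ga: GAParams | None = None,
                   train_index=None) -> MulticlassCSP:
    """Fit a four-class (or k-class) CSP+SVM ensemble."""
    return MulticlassCSP(strategy=strategy, n_pairs=n_pairs,
                         use_gene=use_gene, ga=ga).fit(ts, train_index)


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    return float((pred == truth).mean())
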