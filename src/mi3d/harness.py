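"""Stratified cross-validation harness over the CSP-family decoders.

``run_benchmark`` ties the stages together: per method and per fold it fits
strictly on the training trials (trial-index bookkeeping asserts the split
is leak-free), predicts the held-out fold, and reports accuracy, Cohen's
kappa and the confusion counts.  Failures are recorded per cell and the run
continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import accuracy, fit_multiclass
from .containers import TrialSet
from .csp import GAParams
from .filterbank import build_filter_banks, fit_sfbcsp, predict_sfbcsp
from .nn import cohen_kappa

__all__ = ["SplitPlan", "stratified_folds", "run_benchmark", "METHODS"]


@dataclass
class SplitPlan:
    """Fold partition of trial indices (stratified, seeded)."""

    folds: list[tuple[np.ndarray, np.ndarray]]   # (train_idx, test_idx)
    n_folds: int
    stratified: bool
    seed: int
    assignment: np.ndarray = field(default=None, repr=False)


def stratified_folds(labels, n_folds: int = 10, seed: int = 0) -> SplitPlan:
    """Balanced fold assignment; every class must have >= n_folds trials."""
    labels = np.asarray(labels)
    for c in np.unique(labels):
        if (labels == c).sum() < n_folds:
            raise ValueError(f"class {c} has fewer than {n_folds} trials")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr.copy(), te.copy())
             for tr, te in skf.split(np.zeros(len(labels)), labels)]
    assignment = np.empty(len(labels), dtype=int)
    for k, (_, te) in enumerate(folds):
        assignment[te] = k
    return SplitPlan(folds=folds, n_folds=n_folds, stratified=True,
                     seed=seed, assignment=assignment)


def _confusion(truth: np.ndarray, pred: np.ndarray, classes: np.ndarray):
    lookup = {int(c): i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, pred):
        cm[lookup[int(t)], lookup[int(p)]] += 1
    return cm


def _fit_predict(method: str, train: TrialSet, test: TrialSet,
                 strategy: str, n_pairs: int, ga: GAParams | None,
                 train_index: np.ndarray):
    if method == "csp":
        clf = fit_multiclass(train, strategy=strategy, n_pairs=n_pairs,
                             train_index=train_index)
        return clf.predict(test)
    if method == "wccsp":
        clf = fit_multiclass(train, strategy=strategy, n_pairs=n_pairs,
                             use_gene=True, ga=ga or GAParams(
                                 population_size=20, generations=15),
                             train_index=train_index)
        return clf.predict(test)
    if method in ("fbcsp", "sfbcsp"):
        banks = build_filter_banks("fbcsp" if method == "fbcsp" else "merged")
        model = fit_sfbcsp(train, banks, n_pairs=n_pairs, strategy=strategy,
                           train_index=train_index)
        return predict_sfbcsp(model, test)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(ts: TrialSet, methods: list[str], plan: SplitPlan,
                  strategy: str = "ovo", n_pairs: int = 4,
                  ga: GAParams | None = None, out_dir=None):
    """Per-method, per-fold accuracy/kappa table.

    Returns ``(DataFrame, report dict)``; the report keeps the confusion
    counts so kappa stays recomputable.  With ``out_dir`` set, writes
    ``benchmark.csv`` and ``benchmark.json``.
    """
    classes = np.unique(ts.labels)
    rows, report = [], {"folds": plan.n_folds, "seed": plan.seed, "cells": []}
    for method in methods:
        for k, (tr_idx, te_idx) in enumerate(plan.folds):
            assert not set(tr_idx) & set(te_idx), "train/test folds overlap"
            cell = {"method": method, "fold": k}
            try:
                pred = _fit_predict(method, ts.select(tr_idx), ts.select(te_idx),
                                    strategy, n_pairs, ga, tr_idx)
                cm = _confusion(ts.labels[te_idx], pred, classes)
                cell.update(accuracy=accuracy(pred, ts.labels[te_idx]),
                            kappa=cohen_kappa(cm),
                            confusion=cm.tolist())
            except Exception as exc:   # recorded, run continues
                cell.update(accuracy=np.nan, kappa=np.nan, error=repr(exc))
            report["cells"].append(cell)
            rows.append({k2: cell.get(k2) for k2 in
                         ("method", "fold", "accuracy", "kappa", "error")})
    df = pd.DataFrame(rows)
    summary = (df.groupby("method")[["accuracy", "kappa"]]
               .agg(["mean", "std"]))
    report["summary"] = {m: {"accuracy_mean": float(df[df.method == m].accuracy.mean()),
                             "kappa_mean": float(df[df.method == m].kappa.mean())}
                         for m in methods}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "benchmark.csv", index=False)
        (out_dir / "benchmark.json").write_text(json.dumps(report, indent=2))
    df.attrs["summary"] = summary
    return df, report
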