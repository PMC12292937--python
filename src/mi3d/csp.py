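"""Common spatial patterns and the weighted-gene (GA-selected) variant.

CSP finds spatial filters that maximise the variance ratio between two
classes.  With trial-normalised class covariances ``R_a`` and ``R_b``, the
filters solve the generalised eigenproblem

    R_a p = lambda (R_a + R_b) p ,

so each whitened eigenvalue ``lambda`` lies in [0, 1] and the eigenvalues of
the two classes pair up to 1.  Rows of the filter matrix ``P`` (shape C x C)
are sorted by descending eigenvalue; the most discriminative filters sit at
the top and bottom, which motivates both the classic top-n/bottom-n row
reduction and the genetic-algorithm row selection implemented here.

Features are the Ramoser log-variance convention: for retained filters
``p_i``, ``f_i = log( var(p_i X) / sum_j var(p_j X) )`` — invariant to a
global gain on the trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .containers import TrialSet

__all__ = [
    "CSPModel",
    "WeightGene",
    "GAParams",
    "class_covariance",
    "fit_csp",
    "csp_from_covariances",
    "csp_features",
    "reduce_rows",
    "apply_weight",
    "make_svm",
    "wccsp_fitness",
    "fit_wccsp",
    "save_csp_hdf5",
    "load_csp_hdf5",
]

# RBF-SVM defaults; kernel scale 0.783 maps to gamma = 1/0.783^2, C = 0.922
SVM_KERNEL_SCALE = 0.783
SVM_REGULARIZATION = 0.922


def make_svm(kernel_scale: float = SVM_KERNEL_SCALE,
             regularization: float = SVM_REGULARIZATION) -> SVC:
    """RBF SVM with the package's default kernel scale / regularisation."""
    return SVC(kernel="rbf", gamma=1.0 / kernel_scale ** 2, C=regularization)


@dataclass
class CSPModel:
    """Spatial filter matrix for one class pair.

    ``P`` holds one filter per row, sorted by descending whitened eigenvalue
    (class-A variance fraction).  ``n_pairs`` records the retained
    top-n/bottom-n selection used for feature extraction; ``None`` keeps all
    rows.
    """

    P: np.ndarray
    eigenvalues: np.ndarray
    class_a: int
    class_b: int
    n_pairs: int | None = None

    @property
    def n_filters(self) -> int:
        return self.P.shape[0]

    def selected_rows(self) -> np.ndarray:
        """Row indices used for features (top n + bottom n, or all)."""
        if self.n_pairs is None:
            return np.arange(self.n_filters)
        n = self.n_pairs
        return np.r_[np.arange(n), np.arange(self.n_filters - n, self.n_filters)]


@dataclass
class WeightGene:
    """Binary row-selection gene for the GA-weighted CSP."""

    w: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=int)
        if not np.isin(self.w, (0, 1)).all():
            raise ValueError("gene entries must be binary")


@dataclass
class GAParams:
    """Genetic-algorithm budget and rates (defaults: 50/200/0.5/0.06)."""

    population_size: int = 50
    generations: int = 200
    crossover_rate: float = 0.5
    mutation_rate: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.generations <= 0:
            raise ValueError("population size and generations must be positive")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def class_covariance(ts: TrialSet, klass: int) -> np.ndarray:
    """Trial-averaged trace-normalised covariance of one class.

    Per trial ``X`` (channels x samples): ``X X^T / trace(X X^T)``, averaged
    over all trials of ``klass``.
    """
    mask = ts.labels == klass
    if mask.sum() < 1:
        raise ValueError(f"no trials of class {klass}")
    covs = []
    for X in ts.trials[mask]:
        S = X @ X.T
        tr = np.trace(S)
        if tr <= 0:
            raise ValueError("zero-power trial cannot be normalised")
        covs.append(S / tr)
    C = np.mean(covs, axis=0)
    return 0.5 * (C + C.T)  # enforce exact symmetry


def csp_from_covariances(cov_a: np.ndarray,
                         cov_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whitened eigenvalues and filter rows for a covariance pair.

    Solves ``R_a p = lambda (R_a + R_b) p``; returns ``(eigenvalues, P)``
    with rows of ``P`` sorted by descending eigenvalue.  A singular
    composite covariance is ridge-regularised with ``eps = 1e-8 * trace``
    and a warning.
    """
    composite = cov_a + cov_b
    # guard: the generalised eigensolver needs composite > 0
    min_eig = linalg.eigvalsh(composite)[0]
    if min_eig < 1e-10 * np.trace(composite):
        eps = 1e-8 * np.trace(composite)
        warnings.warn(f"singular composite covariance; ridge eps={eps:.3e} "
                      "applied", RuntimeWarning, stacklevel=2)
        composite = composite + eps * np.eye(composite.shape[0])
    evals, evecs = linalg.eigh(cov_a, composite)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = np.clip(evals[order], 0.0, 1.0)
    return evals, evecs[:, order].T  # rows are filters


def fit_csp(ts: TrialSet, class_a: int, class_b: int,
            n_pairs: int | None = None) -> CSPModel:
    """Fit the C x C spatial filter matrix for one class pair."""
    evals, P = csp_from_covariances(class_covariance(ts, class_a),
                                    class_covariance(ts, class_b))
    return CSPModel(P=P, eigenvalues=evals, class_a=int(class_a),
                    class_b=int(class_b), n_pairs=n_pairs)


def _log_var_features(P_rows: np.ndarray, trial: np.ndarray) -> np.ndarray:
    Z = P_rows @ trial
    v = Z.var(axis=1)
    v = np.maximum(v, 1e-12)
    return np.log(v / v.sum())


def csp_features(model: CSPModel, trial: np.ndarray,
                 n_pairs: int | None = None) -> np.ndarray:
    """Log normalised-variance features of the retained filters.

    ``n_pairs`` overrides the model's stored selection; the feature vector
    has length ``2 * n_pairs`` (or ``n_filters`` when no selection applies).
    """
    if n_pairs is not None:
        if 2 * n_pairs > model.n_filters:
            raise ValueError(f"2*n_pairs={2 * n_pairs} exceeds "
                             f"{model.n_filters} filters")
        rows = np.r_[np.arange(n_pairs),
                     np.arange(model.n_filters - n_pairs, model.n_filters)]
    else:
        rows = model.selected_rows()
    return _log_var_features(model.P[rows], np.asarray(trial, dtype=float))


def reduce_rows(model: CSPModel, n: int) -> CSPModel:
    """Keep the top n and bottom n eigenvalue-sorted rows of ``P``."""
    if 2 * n > model.n_filters:
        raise ValueError(f"2n={2 * n} exceeds the {model.n_filters} filters")
    rows = np.r_[np.arange(n), np.arange(model.n_filters - n, model.n_filters)]
    return CSPModel(P=model.P[rows].copy(),
                    eigenvalues=model.eigenvalues[rows].copy(),
                    class_a=model.class_a, class_b=model.class_b, n_pairs=None)


def apply_weight(P: np.ndarray, gene: WeightGene, drop: bool = True) -> np.ndarray:
    """Apply the binary gene to the filter matrix.

    ``drop=True`` (the feature-extraction convention) returns only the
    selected rows; ``drop=False`` returns ``diag(w) @ P`` with unselected
    rows zeroed.  An all-zero gene is flagged as degenerate.
    """
    w = gene.w
    if len(w) != P.shape[0]:
        raise ValueError(f"gene length {len(w)} != {P.shape[0]} filters")
    if w.sum() == 0:
        raise ValueError("degenerate all-zero gene")
    if drop:
        return P[w.astype(bool)]
    return (w[:, None] * P)


# ---------------------------------------------------------------------------
# GA row selection (weighted-criterion CSP)
# ---------------------------------------------------------------------------

def _binary_feature_table(ts: TrialSet, class_a: int, class_b: int):
    """Per-trial filtered-row variances for the binary subset.

    The filter matrix is fitted once on the full binary training set; gene
    evaluation then only re-normalises a subset of the precomputed
    variances, which makes the GA (and the exhaustive oracle) cheap.
    """
    mask = np.isin(ts.labels, (class_a, class_b))
    sub = ts.select(mask)
    model = fit_csp(sub, class_a, class_b)
    Z = np.einsum("fc,tcs->tfs", model.P, sub.trials)
    variances = np.maximum(Z.var(axis=2), 1e-12)  # (trials, filters)
    y = (sub.labels == class_a).astype(int)
    return model, variances, y


def wccsp_fitness(gene: WeightGene, variances: np.ndarray, y: np.ndarray,
                  n_folds: int = 5, seed: int = 0,
                  svm_factory=make_svm) -> float:
    """Mean stratified k-fold SVM accuracy of a gene's feature subset.

    All-zero genes score chance level (0.5 for the binary task) instead of
    being evaluated.
    """
    sel = gene.w.astype(bool)
    if not sel.any():
        return 0.5
    v = variances[:, sel]
    X = np.log(v / v.sum(axis=1, keepdims=True))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        clf = svm_factory()
        clf.fit(X[tr], y[tr])
        accs.append(float((clf.predict(X[te]) == y[te]).mean()))
    return float(np.mean(accs))


def fit_wccsp(ts: TrialSet, class_a: int, class_b: int,
              ga: GAParams | None = None):
    """GA search for the most discriminative CSP-row subset.

    Tournament selection (size 2), single-point crossover, per-bit flip
    mutation, elitism of one; fitness is mean 5-fold SVM accuracy.  Returns
    ``(best WeightGene, CSPModel, trace)`` where ``trace`` is a dict of
    per-generation mean and best fitness.
    """
    ga = ga or GAParams()
    rng = np.random.default_rng(ga.seed)
    model, variances, y = _binary_feature_table(ts, class_a, class_b)
    C = model.n_filters

    cache: dict[bytes, float] = {}

    def fitness(w: np.ndarray) -> float:
        key = w.tobytes()
        if key not in cache:
            cache[key] = wccsp_fitness(WeightGene(w), variances, y,
                                       seed=ga.seed)
        return cache[key]

    pop = rng.integers(0, 2, size=(ga.population_size, C))
    trace = {"mean": [], "best": []}
    best_w, best_f = None, -np.inf

    for _gen in range(ga.generations):
        fits = np.array([fitness(w) for w in pop])
        trace["mean"].append(float(fits.mean()))
        trace["best"].append(float(fits.max()))
        gen_best = int(fits.argmax())
        if fits[gen_best] > best_f:
            best_f = float(fits[gen_best])
            best_w = pop[gen_best].copy()

        # next generation: elitism of 1, then tournament + crossover + mutation
        nxt = [best_w.copy()]
        while len(nxt) < ga.population_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(0, ga.population_size, size=2)
                parents.append(pop[i] if fits[i] >= fits[j] else pop[j])
            a, b = parents[0].copy(), parents[1].copy()
            if rng.random() < ga.crossover_rate and C > 1:
                cut = int(rng.integers(1, C))
                a = np.r_[parents[0][:cut], parents[1][cut:]]
            flips = rng.random(C) < ga.mutation_rate
            a = np.where(flips, 1 - a, a)
            nxt.append(a)
        pop = np.array(nxt[:ga.population_size])

    gene = WeightGene(best_w, fitness=best_f)
    return gene, model, trace


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_csp_hdf5(model: CSPModel, path: str | Path) -> None:
    """Persist a CSPModel (datasets /P, /eigenvalues; attrs for the rest)."""
    with h5py.File(Path(path), "w") as f:
        f.create_dataset("P", data=model.P)
        f.create_dataset("eigenvalues", data=model.eigenvalues)
        f.attrs["class_a"] = model.class_a
        f.attrs["class_b"] = model.class_b
        f.attrs["n_pairs"] = -1 if model.n_pairs is None else model.n_pairs


def load_csp_hdf5(path: str | Path) -> CSPModel:
    with h5py.File(Path(path), "r") as f:
        n_pairs = int(f.attrs["n_pairs"])
        return CSPModel(P=f["P"][()], eigenvalues=f["eigenvalues"][()],
                        class_a=int(f.attrs["class_a"]),
                        class_b=int(f.attrs["class_b"]),
                        n_pairs=None if n_pairs < 0 else n_pairs)
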