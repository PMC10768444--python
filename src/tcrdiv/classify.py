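"""Potential Support Vector Machine (P-SVM) classification on distance data.

Repertoire samples are represented purely relationally: the feature matrix K
has one row per sample and one column per reference sample, holding pairwise
diversity-profile distances.  Such a matrix is not a Mercer kernel (it is not
positive semi-definite, not even square in general), which is exactly the
setting the P-SVM was designed for: it treats the columns of K as features and
fits a sparse weight vector over them.

The dual problem solved here is the box-constrained l1-penalised least-squares
program

    minimise_alpha  1/(2n) ||K alpha - y||^2 + epsilon ||alpha||_1
    subject to      |alpha_j| <= C,

with labels y in {-1, +1}, prediction sign(K_x . alpha + b) and bias
b = mean(y - K alpha) over the training rows.  Columns of K are standardised
before solving so that C and epsilon are comparable across problems.  The QP
is solved by cyclic coordinate descent with soft-thresholding and clipping
(each one-dimensional subproblem is exact), compiled with numba because the
permutation test below re-solves it thousands of times.

Significance of a group separation is assessed by label permutation: the full
leave-one-out cross-validation (holding out each sample as both row and
reference column) is re-run under shuffled labels and

    p = (1 + #{permuted score >= observed score}) / (1 + n_perm)

with balanced accuracy as the score.  Families of such tests are corrected by
Bonferroni (alpha / m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import balanced_accuracy_score
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PSVMClassifier",
    "ClassificationResult",
    "HypothesisFamily",
    "Comparison",
    "train_psvm",
    "loocv",
    "permutation_test",
    "bonferroni_threshold",
    "hypothesis_family",
    "run_comparison_grid",
    "GROUP_LABELS",
]

GROUP_LABELS = ("MEsa", "MEmm", "MS", "HC")
CELL_TYPES = ("CD8", "CD4")
CHAINS = ("alpha", "beta", "gamma")


# --------------------------------------------------------------------------
# QP solver


@njit(cache=True)
def _cd_solve(G, q, C, eps, max_sweeps, tol):
    """Cyclic coordinate descent for min 1/2 a'Ga - q'a + eps|a|_1, |a_j|<=C.

    Each coordinate update is the exact minimiser of the one-dimensional
    restriction (soft-threshold then clip to the box).
    """
    m = q.shape[0]
    alpha = np.zeros(m)
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(m):
            r = q[j] - np.dot(G[j], alpha) + G[j, j] * alpha[j]
            gjj = G[j, j]
            if gjj <= 1e-14:
                if r > eps:
                    new = C
                elif r < -eps:
                    new = -C
                else:
                    new = 0.0
            else:
                if r > eps:
                    new = (r - eps) / gjj
                elif r < -eps:
                    new = (r + eps) / gjj
                else:
                    new = 0.0
                if new > C:
                    new = C
                elif new < -C:
                    new = -C
            d = new - alpha[j]
            if d != 0.0:
                alpha[j] = new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            break
    return alpha


def psvm_objective(K, y, alpha, epsilon):
    """1/(2n)||K alpha - y||^2 + epsilon ||alpha||_1 (for oracle comparisons)."""
    n = K.shape[0]
    resid = K @ alpha - y
    return float(resid @ resid / (2 * n) + epsilon * np.abs(alpha).sum())


# --------------------------------------------------------------------------
# Estimator


class PSVMClassifier(ClassifierMixin, BaseEstimator):
    """P-SVM binary classifier over a relational (dyadic) data matrix.

    Parameters
    ----------
    C : float
        Box constraint on each dual coefficient.
    epsilon : float
        l1 sparsity penalty (on the 1/n-scaled least-squares objective).
    scale : bool
        Standardise the columns of K using training rows before solving.
    max_sweeps, tol : int, float
        Coordinate-descent iteration controls.

    Attributes
    ----------
    coef_ : ndarray of shape (n_ref,)
        Sparse weight per reference column.
    intercept_ : float
    classes_ : ndarray of shape (2,)
        ``classes_[1]`` is the positive class.
    """

    def __init__(self, C: float = 10.0, epsilon: float = 0.05, scale: bool = True,
                 max_sweeps: int = 2000, tol: float = 1e-10):
        self.C = C
        self.epsilon = epsilon
        self.scale = scale
        self.max_sweeps = max_sweeps
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D relational matrix")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        if np.all(X == 0):
            raise ValueError("degenerate relational matrix: all entries zero")
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("P-SVM is a binary classifier: need exactly 2 classes")
        ysigned = np.where(y == self.classes_[1], 1.0, -1.0)
        n, m = X.shape
        if self.scale:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
        else:
            mu = np.zeros(m)
            sd = np.ones(m)
        Z = (X - mu) / sd
        G = Z.T @ Z / n
        q = Z.T @ ysigned / n
        alpha = _cd_solve(G, q, float(self.C), float(self.epsilon),
                          int(self.max_sweeps), float(self.tol))
        self.column_mean_ = mu
        self.column_scale_ = sd
        self.coef_ = alpha
        self.intercept_ = float(np.mean(ysigned - Z @ alpha))
        self.n_features_in_ = m
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.column_mean_) / self.column_scale_
        return Z @ self.coef_ + self.intercept_

    def predict(self, X):
        dec = self.decision_function(X)
        return np.where(dec >= 0, self.classes_[1], self.classes_[0])


def train_psvm(K, y, C: float = 10.0, epsilon: float = 0.05) -> PSVMClassifier:
    """Fit a :class:`PSVMClassifier` on a relational matrix (thin wrapper)."""
    return PSVMClassifier(C=C, epsilon=epsilon).fit(K, y)


# --------------------------------------------------------------------------
# LOOCV and permutation testing (fast path)


def _prepare_folds(K: np.ndarray):
    """Per-fold standardised training matrices, Gram matrices and held-out rows.

    Fold i drops sample i both as a row and as a reference column; these
    quantities do not depend on the labels, so they are shared across all
    label permutations.
    """
    n = K.shape[0]
    Zf = np.empty((n, n - 1, n - 1))
    Gf = np.empty((n, n - 1, n - 1))
    zh = np.empty((n, n - 1))
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Ktr = K[np.ix_(idx, idx)]
        mu = Ktr.mean(axis=0)
        sd = Ktr.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        Z = (Ktr - mu) / sd
        Zf[i] = Z
        Gf[i] = Z.T @ Z / (n - 1)
        zh[i] = (K[i, idx] - mu) / sd
    return Zf, Gf, zh


@njit(cache=True)
def _loocv_decisions(Zf, Gf, zh, y, C, eps, max_sweeps, tol):
    n = y.shape[0]
    m = n - 1
    dec = np.empty(n)
    ytr = np.empty(m)
    for i in range(n):
        k = 0
        for j in range(n):
            if j != i:
                ytr[k] = y[j]
                k += 1
        q = Zf[i].T @ ytr / m
        alpha = _cd_solve(Gf[i], q, C, eps, max_sweeps, tol)
        b = np.mean(ytr - Zf[i] @ alpha)
        dec[i] = np.dot(zh[i], alpha) + b
    return dec


@njit(cache=True)
def _balanced_accuracy(dec, y):
    tp = 0.0
    tn = 0.0
    npos = 0.0
    nneg = 0.0
    for i in range(y.shape[0]):
        if y[i] > 0:
            npos += 1.0
            if dec[i] >= 0:
                tp += 1.0
        else:
            nneg += 1.0
            if dec[i] < 0:
                tn += 1.0
    return 0.5 * (tp / npos + tn / nneg)


@njit(cache=True)
def _perm_scores(Zf, Gf, zh, perms, C, eps, max_sweeps, tol):
    n_perm = perms.shape[0]
    out = np.empty(n_perm)
    for p in range(n_perm):
        yp = perms[p]
        dec = _loocv_decisions(Zf, Gf, zh, yp, C, eps, max_sweeps, tol)
        out[p] = _balanced_accuracy(dec, yp)
    return out


def _check_square(K) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("LOOCV needs a square sample-by-sample relational matrix")
    if not np.all(np.isfinite(K)):
        raise ValueError("relational matrix must be finite")
    return K


def _signed_labels(y) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    return np.where(y == classes[1], 1.0, -1.0), classes


def loocv(K, y, C: float = 10.0, epsilon: float = 0.05,
          param_grid: Sequence[tuple[float, float]] | None = None):
    """Leave-one-out cross-validation of the P-SVM on a square distance matrix.

    The held-out sample is removed both as a row and as a reference column.
    Returns ``(predictions, balanced_accuracy)`` where predictions are in the
    original label alphabet.  If ``param_grid`` (a list of ``(C, epsilon)``
    pairs) is given, hyperparameters are selected per outer fold by an inner
    LOOCV restricted to the training samples (leakage-free), otherwise the
    fixed ``C``/``epsilon`` are used.
    """
    K = _check_square(K)
    ysigned, classes = _signed_labels(y)
    if min((ysigned > 0).sum(), (ysigned < 0).sum()) < 1:
        raise ValueError("both classes must be non-empty")
    n = K.shape[0]
    if n < 4:
        raise ValueError("need at least 2 samples per class for LOOCV")
    if param_grid is None:
        Zf, Gf, zh = _prepare_folds(K)
        dec = _loocv_decisions(Zf, Gf, zh, ysigned, float(C), float(epsilon), 2000, 1e-10)
    else:
        dec = np.empty(n)
        for i in range(n):
            idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            Ktr = K[np.ix_(idx, idx)]
            ytr = ysigned[idx]
            best, best_score = (C, epsilon), -np.inf
            Zf, Gf, zh = _prepare_folds(Ktr)
            for cc, ee in param_grid:
                inner = _loocv_decisions(Zf, Gf, zh, ytr, float(cc), float(ee), 2000, 1e-10)
                sc = _balanced_accuracy(inner, ytr)
                if sc > best_score:
                    best, best_score = (cc, ee), sc
            model = PSVMClassifier(C=best[0], epsilon=best[1]).fit(Ktr, ytr)
            dec[i] = model.decision_function(K[i, idx][None, :])[0]
    preds = np.where(dec >= 0, classes[1], classes[0])
    score = float(balanced_accuracy_score(np.asarray(y), preds))
    return preds, score


@dataclass
class ClassificationResult:
    comparison: str
    predictions: np.ndarray
    observed_score: float
    perm_scores: np.ndarray
    n_permutations: int
    p_value: float
    truncated: bool = False
    labels: np.ndarray | None = None
    n_greater: int = 0  # permutation scores strictly above the observed score
    n_equal: int = 0    # permutation scores tied with the observed score

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p-value must lie in (0, 1]")


def permutation_test(K, y, C: float = 10.0, epsilon: float = 0.05,
                     n_perm: int = 1000, seed: int = 0,
                     comparison: str = "", max_completed: int | None = None) -> ClassificationResult:
    """Label-permutation significance test of the P-SVM LOOCV score.

    Labels are shuffled (class sizes preserved), the full LOOCV is re-run for
    each shuffle, and the p-value uses the add-one rule
    ``p = (1 + #{perm >= obs}) / (1 + n_completed)`` so that p is never zero.
    ``max_completed`` caps the number of shuffles actually run (the truncated
    flag is set when fewer than ``n_perm`` were completed).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    K = _check_square(K)
    ysigned, classes = _signed_labels(y)
    n = K.shape[0]
    Zf, Gf, zh = _prepare_folds(K)
    dec = _loocv_decisions(Zf, Gf, zh, ysigned, float(C), float(epsilon), 2000, 1e-10)
    observed = _balanced_accuracy(dec, ysigned)

    n_run = n_perm if max_completed is None else min(n_perm, max_completed)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_run, n))
    for p in range(n_run):
        perms[p] = rng.permutation(ysigned)
    scores = _perm_scores(Zf, Gf, zh, perms, float(C), float(epsilon), 2000, 1e-10)

    n_greater = int(np.sum(scores > observed + 1e-12))
    n_equal = int(np.sum(np.abs(scores - observed) <= 1e-12))
    pval = (1.0 + n_greater + n_equal) / (1.0 + n_run)
    preds = np.where(dec >= 0, classes[1], classes[0])
    return ClassificationResult(
        comparison=comparison,
        predictions=preds,
        observed_score=float(observed),
        perm_scores=scores,
        n_permutations=n_run,
        p_value=pval,
        truncated=n_run < n_perm,
        labels=np.asarray(y),
        n_greater=n_greater,
        n_equal=n_equal,
    )


# --------------------------------------------------------------------------
# Hypothesis families and Bonferroni correction


@dataclass(frozen=True)
class Comparison:
    name: str
    set_a: frozenset
    set_b: frozenset
    cell_type: str
    chain: str


@dataclass
class HypothesisFamily:
    name: str
    comparisons: list[Comparison]
    alpha_family: float = 0.05

    @property
    def m(self) -> int:
        return len(self.comparisons)


def _members(label: str, cases_definition: str = "ME") -> frozenset:
    sets = {
        "ME": frozenset({"MEsa", "MEmm"}),
        "Cases": frozenset({"MEsa", "MEmm"}) if cases_definition == "ME"
        else frozenset({"MEsa", "MEmm", "MS"}),
    }
    if label in sets:
        return sets[label]
    if label in GROUP_LABELS:
        return frozenset({label})
    raise ValueError(f"unknown group label {label!r}")


_PRIMARY_PAIRS = [("ME", "HC"), ("ME", "MS"), ("MEsa", "MEmm")]
_SECONDARY_PAIRS = [("Cases", "HC"), ("MS", "HC"), ("MEmm", "HC"),
                    ("MEsa", "HC"), ("MEmm", "MS"), ("MEsa", "MS")]


def hypothesis_family(name: str, alpha_family: float = 0.05,
                      cases_definition: str = "ME") -> HypothesisFamily:
    """Enumerate the primary (18), secondary (36) or combined (54) test family.

    Each group-pair hypothesis is tested once per cell type (CD8, CD4) and
    chain (alpha, beta, gamma).  ``cases_definition`` controls whether the
    secondary "Cases" pool means ME only (default) or ME plus MS.
    """
    if name == "primary":
        pairs = _PRIMARY_PAIRS
    elif name == "secondary":
        pairs = _SECONDARY_PAIRS
    elif name == "combined":
        pairs = _PRIMARY_PAIRS + _SECONDARY_PAIRS
    else:
        raise ValueError("family must be primary, secondary or combined")
    comparisons = [
        Comparison(f"{a} vs. {b}", _members(a, cases_definition),
                   _members(b, cases_definition), ct, ch)
        for (a, b), ct, ch in product(pairs, CELL_TYPES, CHAINS)
    ]
    return HypothesisFamily(name=name, comparisons=comparisons, alpha_family=alpha_family)


def bonferroni_threshold(family, alpha_family: float | None = None) -> float:
    """Per-test alpha = family alpha / number of tests."""
    if isinstance(family, HypothesisFamily):
        m = family.m
        a = family.alpha_family if alpha_family is None else alpha_family
    else:
        m = int(family)
        a = 0.05 if alpha_family is None else alpha_family
    if m < 1:
        raise ValueError("family must contain at least one test")
    return a / m


def run_comparison_grid(
    matrices: Mapping[tuple[str, str], "object"],
    metadata: pd.DataFrame,
    family: HypothesisFamily,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 10.0,
    epsilon: float = 0.05,
) -> pd.DataFrame:
    """Run every comparison of a family over its (cell type, chain) matrices.

    ``matrices`` maps ``(cell_type, chain)`` to a
    :class:`~tcrdiv.diversity.DistanceMatrix`; ``metadata`` needs columns
    ``sample_id`` and ``group``.  Returns a tidy report with one row per
    comparison: raw p, permutation count, truncation flag and whether the raw
    p survives the Bonferroni family threshold.
    """
    import warnings

    group_of = dict(zip(metadata["sample_id"].astype(str), metadata["group"]))
    thresh = bonferroni_threshold(family)
    rows = []
    for k, comp in enumerate(family.comparisons):
        key = (comp.cell_type, comp.chain)
        if key not in matrices:
            raise KeyError(f"no distance matrix for cell type/chain {key}")
        dm = matrices[key]
        wanted = comp.set_a | comp.set_b
        ids = [s for s in dm.sample_ids if group_of.get(s) in wanted]
        labels = np.array([1 if group_of[s] in comp.set_a else -1 for s in ids])
        if len(set(labels)) < 2:
            warnings.warn(f"skipping {comp.name} ({key}): a group is missing")
            continue
        sub = dm.submatrix(ids)
        res = permutation_test(
            sub.values, labels, C=C, epsilon=epsilon, n_perm=n_perm,
            seed=int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31)),
            comparison=comp.name,
        )
        rows.append({
            "comparison": comp.name,
            "cell_type": comp.cell_type,
            "chain": comp.chain,
            "observed_score": res.observed_score,
            "n_permutations": res.n_permutations,
            "p_value": res.p_value,
            "truncated": res.truncated,
            "significant_raw": res.p_value < 0.05,
            "significant_family": res.p_value < thresh,
        })
    report = pd.DataFrame(rows)
    report.attrs["family"] = family.name
    report.attrs["bonferroni_threshold"] = thresh
    return report
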