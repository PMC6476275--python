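"""Mapping geometric features to graded judgements and metaphoric class.

The evaluation protocol: features are z-scored once over the whole
dataset, then every dyad is predicted by a model fit on the remaining
n-1 dyads (leave-one-out). Graded ratings use ordinary least squares
and are summarised by the Pearson correlation between held-out
predictions and the true ratings; the three-way class label uses
one-vs-rest logistic regression (one binary model per class, predicted
class = highest score) summarised by accuracy.

Feature analysis proceeds from single-feature Pearson correlations
(ranked by absolute value) to a collinearity-constrained subset: walk
down the ranking and append a candidate feature only while its variance
inflation factor against the already-selected set,

    VIF = 1 / (1 - R^2)  <  fac            (default fac = 2),

stays under the threshold, keeping at most ``max_features`` features.

Significance machinery: Fisher r-to-z tests for differences between
correlations, and permutation tests for differences between
classifiers (or against a label-shuffling null).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .errors import InsufficientDataError

__all__ = [
    "FeatureMatrix",
    "CVResult",
    "VIFSelection",
    "load_dyads",
    "standardize_features",
    "loo_linear_cv",
    "loo_logistic_ovr_cv",
    "rank_single_features",
    "vif_select",
    "fisher_r_to_z_test",
    "permutation_test",
]

CLASS_LABELS = ("literal", "conventional", "novel")
RATING_COLUMNS = ("metaphoricity", "meaningfulness", "familiarity")

# Effectively-unregularised maximum-likelihood fit; on non-convergence
# (e.g. complete separation) we fall back to this fixed L2 strength.
_ML_C = 1e6
_FALLBACK_C = 1.0


@dataclass
class FeatureMatrix:
    """An n x p feature table with canonical column names."""

    data: pd.DataFrame
    standardized: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CVResult:
    """Held-out predictions plus their summary statistic."""

    predictions: np.ndarray
    summary: float
    kind: str  # "r" or "accuracy"
    target: str = ""
    technique: str = ""


@dataclass
class VIFSelection:
    selected: list[str]
    r_squared: dict[str, float]  # candidate -> R^2 at decision time
    fac: float
    rejected: list[str] = field(default_factory=list)


def load_dyads(path) -> pd.DataFrame:
    """Read a rated-dyad CSV (verb,noun,class,metaphoricity,meaningfulness,familiarity)."""
    df = pd.read_csv(path)
    required = ["verb", "noun", "class", *RATING_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"dyad table is missing columns: {missing}")
    bad = set(df["class"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return df


def _as_fm(F) -> FeatureMatrix:
    if isinstance(F, FeatureMatrix):
        return F
    return FeatureMatrix(pd.DataFrame(F))


def standardize_features(F) -> FeatureMatrix:
    """Column-wise z-scores (sample SD, ddof=1).

    Constant columns become all-zeros with a warning; fewer than two
    rows raise :class:`InsufficientDataError`.
    """
    F = _as_fm(F)
    if len(F) < 2:
        raise InsufficientDataError("standardization needs at least 2 rows")
    X = F.values
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    const = sd == 0.0
    if const.any():
        names = [n for n, c in zip(F.feature_names, const) if c]
        warnings.warn(f"constant feature columns zeroed: {names}", stacklevel=2)
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    return FeatureMatrix(
        pd.DataFrame(Z, columns=F.feature_names, index=F.data.index),
        standardized=True,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r; 0 (with a warning upstream where relevant) when either
    argument has zero variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _ols_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    """OLS with intercept; rank-deficient designs take the minimum-norm
    solution (pseudoinverse) with a warning."""
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    beta, _, rank, _ = np.linalg.lstsq(A, ytr, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            "singular OLS design; using minimum-norm solution", stacklevel=3
        )
    return np.column_stack([np.ones(len(Xte)), Xte]) @ beta


def ols_coefficients(F, y) -> pd.Series:
    """All-in OLS coefficients (no intercept term reported)."""
    F = _as_fm(F)
    A = np.column_stack([np.ones(len(F)), F.values])
    beta, *_ = np.linalg.lstsq(A, np.asarray(y, dtype=np.float64), rcond=None)
    return pd.Series(beta[1:], index=F.feature_names)


def _fold_standardize(Xtr: np.ndarray, Xte: np.ndarray):
    """Z-score a training fold and map the held-out rows through the
    fold's own moments (leakage-free alternative to whole-dataset
    standardization)."""
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0, ddof=1)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (Xtr - mu) / sd, (Xte - mu) / sd


def loo_linear_cv(
    F,
    target,
    target_name: str = "",
    technique: str = "",
    fold_standardize: bool = False,
) -> CVResult:
    """Leave-one-out OLS; summary is Pearson r of held-out predictions
    against the true ratings.

    The protocol standardizes once over the whole dataset before
    cross-validation (accepting the mild leakage that implies);
    ``fold_standardize=True`` instead re-standardizes inside each
    training fold and maps the held-out row through the fold moments.
    """
    F = _as_fm(F)
    if not F.standardized and not fold_standardize:
        warnings.warn("feature matrix is not standardized", stacklevel=2)
    X = F.values
    y = np.asarray(target, dtype=np.float64)
    n, p = X.shape
    if n <= p + 1:
        warnings.warn(
            f"n={n} rows for p={p} features: LOO fits are under-determined",
            stacklevel=2,
        )
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        Xtr, Xte = X[mask], X[i : i + 1]
        if fold_standardize:
            Xtr, Xte = _fold_standardize(Xtr, Xte)
        preds[i] = _ols_predict(Xtr, y[mask], Xte)[0]
    return CVResult(preds, _pearson(preds, y), "r", target_name, technique)


def _fit_binary_logistic(X: np.ndarray, y01: np.ndarray, coef_init=None):
    """Maximum-likelihood binary logistic fit with an L2 fallback on
    non-convergence (e.g. complete separation)."""
    for C in (_ML_C, _FALLBACK_C):
        clf = LogisticRegression(C=C, max_iter=500, tol=1e-6, solver="lbfgs")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y01)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return clf
        if C == _ML_C:
            warnings.warn(
                "logistic fit did not converge; refitting with a fixed "
                f"L2 penalty (C={_FALLBACK_C})",
                stacklevel=3,
            )
    return clf


def loo_logistic_ovr_cv(
    F, labels, technique: str = "", fold_standardize: bool = False
) -> CVResult:
    """Leave-one-out one-vs-rest logistic classification.

    For each held-out dyad, one binary model per class is fit on the
    remaining rows; the predicted class is the one whose model assigns
    the highest probability (ties broken lexicographically by class
    name). Summary is accuracy.
    """
    F = _as_fm(F)
    if not F.standardized and not fold_standardize:
        warnings.warn("feature matrix is not standardized", stacklevel=2)
    X = F.values
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = len(labels)
    scores = np.empty((n, len(classes)))
    idx = np.arange(n)
    # One warm-started model per class: successive LOO folds differ by a
    # single row, so lbfgs restarts from the previous optimum and
    # converges in a handful of iterations.
    warm = {
        cls: LogisticRegression(
            C=_ML_C, max_iter=500, tol=1e-6, solver="lbfgs", warm_start=True
        )
        for cls in classes
    }
    for i in range(n):
        mask = idx != i
        Xtr, Xte = X[mask], X[i : i + 1]
        if fold_standardize:
            Xtr, Xte = _fold_standardize(Xtr, Xte)
        for ci, cls in enumerate(classes):
            y01 = (labels[mask] == cls).astype(int)
            if y01.min() == y01.max():  # fold degenerates to one class
                scores[i, ci] = float(y01[0])
                continue
            clf = warm[cls]
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                clf.fit(Xtr, y01)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                clf = _fit_binary_logistic(Xtr, y01)
            # column for the positive class (may be absent if training
            # labels were all-negative; then probability of positive = 0)
            if 1 in clf.classes_:
                pos = list(clf.classes_).index(1)
                scores[i, ci] = clf.predict_proba(Xte)[0, pos]
            else:
                scores[i, ci] = 0.0
    pred_idx = np.argmax(scores, axis=1)  # ties -> lowest index = lexicographic
    preds = np.array([classes[j] for j in pred_idx])
    acc = float(np.mean(preds == labels))
    return CVResult(preds, acc, "accuracy", "class", technique)


def rank_single_features(F, target) -> list[tuple[str, float]]:
    """Per-feature Pearson correlation with the target, sorted by |r|
    descending (ties broken lexicographically by feature name).
    Zero-variance features get r = 0 with a warning."""
    F = _as_fm(F)
    y = np.asarray(target, dtype=np.float64)
    out = []
    for name in F.feature_names:
        x = F.data[name].to_numpy(dtype=np.float64)
        if np.std(x) == 0.0:
            warnings.warn(f"zero-variance feature {name!r}: r set to 0", stacklevel=2)
            r = 0.0
        else:
            r = _pearson(x, y)
        out.append((name, r))
    return sorted(out, key=lambda t: (-abs(t[1]), t[0]))


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of OLS(y ~ X + intercept)."""
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 1.0  # constant candidate carries no new information
    pred = _ols_predict(X, y, X)
    ssr = float(np.sum((y - pred) ** 2))
    return 1.0 - ssr / sst


def vif_select(
    ranked: list[tuple[str, float]],
    F,
    fac: float = 2.0,
    max_features: int = 5,
) -> VIFSelection:
    """Walk the |r| ranking, admitting features while 1/(1-R^2) < fac.

    The top-ranked feature seeds the set; each later candidate is
    regressed (OLS with intercept) on the current selection and is
    appended only if its variance inflation factor stays below ``fac``.
    Selection stops at ``max_features`` or the end of the ranking.
    """
    if not ranked:
        raise ValueError("ranked feature list must be non-empty")
    F = _as_fm(F)
    selected: list[str] = []
    rejected: list[str] = []
    r2_log: dict[str, float] = {}
    for name, _ in ranked:
        if len(selected) >= max_features:
            break
        if not selected:
            selected.append(name)
            r2_log[name] = 0.0
            continue
        Xsel = F.data[selected].to_numpy(dtype=np.float64)
        y = F.data[name].to_numpy(dtype=np.float64)
        r2 = _r_squared(Xsel, y)
        r2_log[name] = r2
        if r2 < 1.0 and 1.0 / (1.0 - r2) < fac:
            selected.append(name)
        else:
            rejected.append(name)
    return VIFSelection(selected, r2_log, fac, rejected)


def fisher_r_to_z_test(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-sided z-test for the difference of two independent Pearson
    correlations via the Fisher transform atanh(r)."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise ValueError("|r| must be < 1 for the Fisher transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return z, float(p)


def permutation_test(
    metric,
    predictions_a,
    labels,
    predictions_b=None,
    n_perm: int = 10_000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> float:
    """Permutation p-value for a prediction metric.

    With one prediction set, the null shuffles the labels:
    p = (1 + #{metric(a, shuffled) >= metric(a, labels)}) / (n_perm + 1).
    With two sets, a paired sign-flip null swaps a/b per item and the
    statistic is the metric difference. ``exhaustive=True`` enumerates
    every permutation / flip pattern (small n only) and returns the
    exact tail proportion.
    """
    a = np.asarray(predictions_a)
    labels = np.asarray(labels)
    if len(a) != len(labels):
        raise ValueError("predictions and labels differ in length")
    n = len(labels)
    if predictions_b is None:
        observed = metric(a, labels)
        if exhaustive:
            perms = list(itertools.permutations(range(n)))
            count = sum(metric(a, labels[list(p)]) >= observed for p in perms)
            return count / len(perms)
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += metric(a, labels[rng.permutation(n)]) >= observed
        return (1 + count) / (n_perm + 1)

    b = np.asarray(predictions_b)
    if len(b) != n:
        raise ValueError("prediction sets differ in length")
    observed = metric(a, labels) - metric(b, labels)
    if exhaustive:
        count = 0
        total = 2**n
        for bits in range(total):
            flip = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
            pa, pb = np.where(flip, b, a), np.where(flip, a, b)
            count += (metric(pa, labels) - metric(pb, labels)) >= observed
        return count / total
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        flip = rng.integers(0, 2, size=n).astype(bool)
        pa, pb = np.where(flip, b, a), np.where(flip, a, b)
        count += (metric(pa, labels) - metric(pb, labels)) >= observed
    return (1 + count) / (n_perm + 1)


def accuracy_metric(pred: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(np.asarray(pred) == np.asarray(labels)))
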