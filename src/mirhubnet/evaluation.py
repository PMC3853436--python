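"""Validation battery for a candidate miRNA set.

Four independent checks of whether a feature set carries subtype signal:

* stratified cross-validated classification accuracy with four standard
  classifiers (Gaussian naive Bayes, kNN with k=3, RBF-kernel SVM, random
  forest with 5,000 trees), 5-fold by default;
* a random-set correlation test — is the candidate set's mean pairwise
  Pearson correlation higher than that of equally sized random draws from
  a reference pool;
* a permutation global test of joint association between the set's
  expression pattern and the class labels (score statistic
  Q = sum_j (x_j' y)^2 / m with standardized features and centred labels);
* a survival comparison — K-means (k=2) on the candidate features, clusters
  labelled by their majority subtype, two-group log-rank test and
  Kaplan-Meier curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .exceptions import InputError, ParameterError
from .io import ExpressionMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationReport",
    "RandomSetResult",
    "GlobalTestResult",
    "SurvivalComparison",
    "CLASSIFIERS",
    "crossval_accuracy",
    "random_set_correlation_test",
    "global_test",
    "two_group_logrank",
    "survival_compare",
]

CLASSIFIERS = ("naive_bayes", "knn", "svm_rbf", "random_forest")


@dataclass
class ClassificationReport:
    classifier: str
    accuracy: float
    fold_assignments: np.ndarray
    n_folds: int
    seed: int
    settings: dict = field(default_factory=dict)


@dataclass
class RandomSetResult:
    candidate_mean_r: float
    null_means: np.ndarray
    empirical_p: float


@dataclass
class GlobalTestResult:
    Q: float
    p_value: float
    per_feature: pd.DataFrame  # feature, contribution, p_value
    n_perm: int
    seed: int


@dataclass
class SurvivalComparison:
    groups: dict[str, str]
    statistic: float
    p_value: float
    km_curves: pd.DataFrame  # time, survival, group
    degenerate: bool = False


def _make_classifier(name: str, seed: int):
    if name == "naive_bayes":
        return GaussianNB(), {}
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=3), {"n_neighbors": 3}
    if name == "svm_rbf":
        return SVC(kernel="rbf", C=1.0, gamma="scale"), {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
    if name == "random_forest":
        return (
            RandomForestClassifier(n_estimators=5000, random_state=seed, n_jobs=1),
            {"n_estimators": 5000},
        )
    raise ParameterError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _feature_submatrix(matrix: ExpressionMatrix, feature_ids) -> np.ndarray:
    missing = sorted(set(feature_ids) - set(matrix.feature_ids))
    if missing:
        raise InputError(f"features not in matrix: {missing}")
    idx = [matrix.feature_ids.index(f) for f in feature_ids]
    return matrix.values[idx]


def crossval_accuracy(
    matrix: ExpressionMatrix,
    feature_ids,
    classifier: str,
    folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold cross-validated overall accuracy (pooled over folds)."""
    X = _feature_submatrix(matrix, feature_ids).T  # samples x features
    y = np.array([matrix.labels[s] for s in matrix.sample_ids])
    counts = pd.Series(y).value_counts()
    if counts.min() < folds:
        raise InputError(f"each class needs >= {folds} samples for {folds}-fold CV")
    clf, settings = _make_classifier(classifier, seed)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        fold_of[test] = fold
        clf_fold, _ = _make_classifier(classifier, seed)
        clf_fold.fit(X[train], y[train])
        correct += int((clf_fold.predict(X[test]) == y[test]).sum())
    return ClassificationReport(
        classifier=classifier,
        accuracy=correct / len(y),
        fold_assignments=fold_of,
        n_folds=folds,
        seed=seed,
        settings=settings,
    )


def _mean_pairwise_r(block: np.ndarray, absolute: bool) -> float:
    r = np.corrcoef(block)
    iu = np.triu_indices(r.shape[0], k=1)
    vals = r[iu]
    return float(np.mean(np.abs(vals) if absolute else vals))


def random_set_correlation_test(
    matrix: ExpressionMatrix,
    candidate_ids,
    pool_ids,
    set_size: int | None = None,
    n_iter: int = 1000,
    seed: int = 0,
    absolute: bool = False,
) -> RandomSetResult:
    """Mean pairwise Pearson r of the candidate set vs random pool draws.

    ``absolute=True`` averages |r| instead of signed r (the signed mean is
    the default reading of "average correlation coefficient").
    """
    candidate_ids = list(candidate_ids)
    pool_ids = list(pool_ids)
    if set_size is None:
        set_size = len(candidate_ids)
    if set_size < 2 or len(candidate_ids) < 2:
        raise ParameterError("set_size must be >= 2")
    if set_size > len(pool_ids):
        raise ParameterError("set_size exceeds the pool")
    cand = _feature_submatrix(matrix, candidate_ids)
    pool = _feature_submatrix(matrix, pool_ids)
    candidate_mean = _mean_pairwise_r(cand, absolute)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    for b in range(n_iter):
        # sorted draw => identical subsets give bit-identical means
        pick = np.sort(rng.choice(len(pool_ids), size=set_size, replace=False))
        null[b] = _mean_pairwise_r(pool[pick], absolute)
    p = (1.0 + int((null >= candidate_mean).sum())) / (1.0 + n_iter)
    return RandomSetResult(candidate_mean_r=candidate_mean, null_means=null, empirical_p=p)


def global_test(
    matrix: ExpressionMatrix,
    feature_ids,
    n_perm: int = 10000,
    seed: int = 0,
) -> GlobalTestResult:
    """Permutation global test of set-level association with the class labels."""
    if n_perm < 1000:
        raise ParameterError("n_perm must be >= 1000")
    if matrix.labels is None or len(set(matrix.labels.values())) < 2:
        raise InputError("two-class sample labels are required")
    X = _feature_submatrix(matrix, feature_ids).astype(float)
    m = X.shape[0]
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d constant feature(s) contribute 0 to the global test", int(zero.sum()))
        sd = np.where(zero, 1.0, sd)
    Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    Xs[zero] = 0.0
    mask_a, _ = matrix.class_columns()
    y = mask_a.astype(float)
    y = y - y.mean()
    scores = Xs @ y
    contrib = scores**2
    Q = float(contrib.sum() / m)
    rng = np.random.default_rng(seed)
    count_q = 0
    count_f = np.zeros(m, dtype=int)
    for _ in range(n_perm):
        yp = rng.permutation(y)
        sp = (Xs @ yp) ** 2
        count_q += sp.sum() / m >= Q
        count_f += sp >= contrib
    p = (1.0 + count_q) / (1.0 + n_perm)
    per_feature = pd.DataFrame(
        {
            "feature": list(feature_ids),
            "contribution": contrib,
            "p_value": (1.0 + count_f) / (1.0 + n_perm),
        }
    )
    return GlobalTestResult(Q=Q, p_value=p, per_feature=per_feature, n_perm=n_perm, seed=seed)


def two_group_logrank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic and p-value.

    The standard observed-minus-expected formulation over the pooled event
    times: chi2 = (sum(O_a - E_a))^2 / sum(V), V the hypergeometric variance
    at each event time.
    """
    res = logrank_test(time_a, time_b, event_observed_A=event_a, event_observed_B=event_b)
    return float(res.test_statistic), float(res.p_value)


def survival_compare(
    matrix: ExpressionMatrix,
    feature_ids,
    survival: SurvivalTable,
    seed: int = 0,
) -> SurvivalComparison:
    """K-means (k=2) grouping on candidate features + two-group log-rank test.

    Each cluster is named after its majority true subtype; with both
    clusters dominated by the same subtype the minority cluster gets the
    other name suffixed, keeping exactly two groups. A degenerate single
    cluster yields statistic 0, p = 1 and a warning.
    """
    if matrix.labels is None:
        raise InputError("sample labels are required to name the survival groups")
    X = _feature_submatrix(matrix, feature_ids).T  # samples x features
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    cluster = km.fit_predict(X)
    time, event = survival.lookup(matrix.sample_ids)
    labels = np.array([matrix.labels[s] for s in matrix.sample_ids])
    class_a, class_b = matrix.classes

    if len(np.unique(cluster)) < 2:
        logger.warning("K-means produced a single cluster; log-rank undefined")
        groups = {s: f"{class_a}_trend" for s in matrix.sample_ids}
        km_df = _km_curves(time, event, np.zeros(len(time), dtype=int), [f"{class_a}_trend"])
        return SurvivalComparison(groups=groups, statistic=0.0, p_value=1.0,
                                  km_curves=km_df, degenerate=True)

    # majority-subtype naming, deterministic on ties (class_a first)
    names = []
    for c in (0, 1):
        in_c = labels[cluster == c]
        names.append(class_a if (in_c == class_a).sum() >= (in_c == class_b).sum() else class_b)
    if names[0] == names[1]:
        # both clusters lean the same way: the smaller one takes the other name
        minority = 0 if (cluster == 0).sum() <= (cluster == 1).sum() else 1
        names[minority] = class_b if names[minority] == class_a else class_a
    group_names = [f"{nm}_trend" for nm in names]

    stat, p = two_group_logrank(
        time[cluster == 0], event[cluster == 0], time[cluster == 1], event[cluster == 1]
    )
    groups = {s: group_names[c] for s, c in zip(matrix.sample_ids, cluster)}
    km_df = _km_curves(time, event, cluster, group_names)
    return SurvivalComparison(groups=groups, statistic=stat, p_value=p, km_curves=km_df)


def _km_curves(time, event, cluster, group_names) -> pd.DataFrame:
    frames = []
    for c, name in enumerate(group_names):
        sel = cluster == c
        if not sel.any():
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event_observed=event[sel])
        sf = kmf.survival_function_
        frames.append(
            pd.DataFrame(
                {"time": sf.index.to_numpy(dtype=float),
                 "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                 "group": name}
            )
        )
    return pd.concat(frames, ignore_index=True)
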