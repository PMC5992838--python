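"""Endpoint classification: training, evaluation, and model integration.

Three algorithm families are supported — linear discriminant analysis (LDA),
random forests (RF) and support vector machines (SVM, linear or radial
kernel with a grid search over cost and kernel width).  Performance is
summarized by accuracy (ACC), balanced accuracy (bACC = mean of sensitivity
and specificity) and the Matthews correlation coefficient (MCC), estimated
on a held-out stratified split; a ten-times five-fold cross-validation on
the training patients yields the leakage-free performance estimate used to
weight models in the voting ensemble.

Leakage discipline: every fit-time statistic (feature scaling, grid-search
scores, CV estimates) is computed on training patients only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datatypes import TopoFeatureSet, ValidationError

logger = logging.getLogger(__name__)

SVM_GRID_POWERS = (-4, -2, -1, 0, 1, 2, 4)


@dataclass
class SplitSpec:
    """A stratified train/test split over patient ids."""

    train: list[str]
    test: list[str]
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.test)
        if overlap == set(self.train) == set(self.test):
            # resubstitution evaluation: legal for sanity checks, but leaky
            logger.warning("train and test sets are identical: "
                           "resubstitution estimate, leakage by design")
        elif overlap:
            raise ValidationError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass
class ModelConfig:
    algorithm: str = "RF"            # LDA | RF | SVM
    svm_kernel: str = "radial"       # linear | radial
    svm_grid_powers: tuple[int, ...] = SVM_GRID_POWERS
    optimize: bool = True
    n_trees: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("LDA", "RF", "SVM"):
            raise ValidationError(f"unknown algorithm {self.algorithm!r}")
        if self.svm_kernel not in ("linear", "radial"):
            raise ValidationError(f"unknown SVM kernel {self.svm_kernel!r}")
        if self.optimize and not self.svm_grid_powers:
            raise ValidationError("empty SVM grid with optimize=True")


@dataclass
class PerformanceReport:
    acc: float
    bacc: float
    mcc: float
    tp: int
    fp: int
    fn: int
    tn: int
    cv_mean_bacc: float | None = None
    cv_sd_bacc: float | None = None


@dataclass
class ComparisonReport:
    groups: list[str]
    delta_bacc: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    significant: dict[tuple[str, str], bool]
    anova_p: float | None = None
    alpha: float = 0.01


def stratified_split(patient_ids: list[str], labels: np.ndarray,
                     fraction: float = 0.5, rng_seed: int = 0) -> SplitSpec:
    """Per-class random split; the train side gets ceil(fraction * n_class)."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(patient_ids),):
        raise ValidationError("labels must align with patient_ids")
    rng = np.random.default_rng(rng_seed)
    train: list[str] = []
    test: list[str] = []
    for cls in (0, 1):
        members = [p for p, y in zip(patient_ids, labels) if y == cls]
        if len(members) < 2:
            raise ValidationError(f"class {cls} has fewer than 2 members")
        order = rng.permutation(len(members))
        n_train = math.ceil(fraction * len(members))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    index = {p: i for i, p in enumerate(patient_ids)}
    train.sort(key=index.__getitem__)
    test.sort(key=index.__getitem__)
    return SplitSpec(train=train, test=test, stratified=True, rng_seed=rng_seed)


def _make_estimator(config: ModelConfig, C: float | None = None,
                    gamma: float | None = None):
    if config.algorithm == "LDA":
        return LinearDiscriminantAnalysis()
    if config.algorithm == "RF":
        return RandomForestClassifier(n_estimators=config.n_trees,
                                      random_state=config.rng_seed)
    kernel = "rbf" if config.svm_kernel == "radial" else "linear"
    kwargs = {"kernel": kernel, "C": 1.0 if C is None else C,
              "random_state": config.rng_seed}
    if kernel == "rbf":
        kwargs["gamma"] = "scale" if gamma is None else gamma
    return SVC(**kwargs)


def _fit(est, X: np.ndarray, y: np.ndarray):
    if isinstance(est, LinearDiscriminantAnalysis):
        try:
            est.fit(X, y)
        except np.linalg.LinAlgError:
            logger.warning("singular within-class covariance: LDA refitted "
                           "with lsqr solver and automatic shrinkage")
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            est.fit(X, y)
        return est
    est.fit(X, y)
    return est


def _scores(est, X: np.ndarray) -> np.ndarray:
    """Continuous class-probability-like score in [0, 1]."""
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    decision = est.decision_function(X)
    return 1.0 / (1.0 + np.exp(-np.clip(decision, -30, 30)))


def svm_grid_search(X: np.ndarray, y: np.ndarray, config: ModelConfig,
                    folds: int = 5) -> tuple[float, float | None]:
    """Exhaustive scan of the (cost, width) grid by stratified-CV bACC.

    Grid values are 2^(2p) for the configured powers; the linear kernel
    scans cost only.  Ties resolve to the first grid point in scan order.
    """
    costs = [float(2.0 ** (2 * p)) for p in config.svm_grid_powers]
    if config.svm_kernel == "radial":
        grid = list(itertools.product(costs, costs))
    else:
        grid = [(c, None) for c in costs]
    cv = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=config.rng_seed)
    splits = list(cv.split(X, y))
    best, best_score = grid[0], -np.inf
    for C, gamma in grid:
        baccs = []
        for tr, va in splits:
            scaler = StandardScaler().fit(X[tr])
            est = _fit(_make_estimator(config, C, gamma),
                       scaler.transform(X[tr]), y[tr])
            pred = (_scores(est, scaler.transform(X[va])) >= 0.5).astype(int)
            baccs.append(compute_metrics(y[va], pred).bacc)
        score = float(np.mean(baccs))
        if score > best_score + 1e-12:
            best, best_score = (C, gamma), score
    return best


def _resolve(config: ModelConfig, X: np.ndarray, y: np.ndarray):
    """Freeze grid-searched hyper-parameters (SVM only) on training data."""
    if config.algorithm == "SVM" and config.optimize:
        C, gamma = svm_grid_search(X, y, config)
        logger.info("SVM grid search: C=%g gamma=%s", C, gamma)
        return lambda: _make_estimator(config, C, gamma)
    return lambda: _make_estimator(config)


def crossvalidate(features: TopoFeatureSet, labels: np.ndarray,
                  config: ModelConfig, repeats: int = 10, folds: int = 5,
                  train_ids: list[str] | None = None) -> tuple[float, float, list[float]]:
    """Repeated stratified cross-validation on (a subset of) the cohort.

    Returns (mean bACC, SD, the per-fold bACC list) over repeats x folds
    fits.  SVM hyper-parameters, when optimized, are resolved once on the
    full set being cross-validated before the folds run.
    """
    X, y = _matrix(features, labels, train_ids)
    if min(np.bincount(y, minlength=2)) < folds:
        raise ValidationError(f"need at least {folds} members per class")
    factory = _resolve(config, X, y)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=config.rng_seed)
    baccs: list[float] = []
    for tr, va in cv.split(X, y):
        scaler = StandardScaler().fit(X[tr])
        est = _fit(factory(), scaler.transform(X[tr]), y[tr])
        pred = (_scores(est, scaler.transform(X[va])) >= 0.5).astype(int)
        baccs.append(compute_metrics(y[va], pred).bacc)
    return float(np.mean(baccs)), float(np.std(baccs)), baccs


def _matrix(features: TopoFeatureSet, labels: np.ndarray,
            ids: list[str] | None) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(features.patient_ids),):
        raise ValidationError("labels must align with feature rows")
    if ids is None:
        return features.values, labels
    index = {p: i for i, p in enumerate(features.patient_ids)}
    rows = [index[p] for p in ids]
    return features.values[rows], labels[rows]


def train_predict(features: TopoFeatureSet, labels: np.ndarray,
                  split: SplitSpec, config: ModelConfig,
                  cv_estimate: bool = True) -> tuple[dict[str, float], PerformanceReport]:
    """Fit on the train side, score the test side.

    Returns the per-test-patient continuous scores in [0, 1] and a
    :class:`PerformanceReport` on the test labels (binary predictions use a
    0.5 threshold, ties counting as positive).  ``cv_estimate`` additionally
    runs the 10x5 cross-validation on the training patients to populate
    ``cv_mean_bacc`` (the voting weight).
    """
    X_tr, y_tr = _matrix(features, labels, split.train)
    X_te, y_te = _matrix(features, labels, split.test)
    if len(np.unique(y_tr)) < 2:
        raise ValidationError("training labels are single-class")
    if set(split.train) == set(split.test):
        logger.warning("train and test sets are identical: leakage by design")
    factory = _resolve(config, X_tr, y_tr)
    scaler = StandardScaler().fit(X_tr)
    est = _fit(factory(), scaler.transform(X_tr), y_tr)
    test_scores = _scores(est, scaler.transform(X_te))
    pred = (test_scores >= 0.5).astype(int)
    report = compute_metrics(y_te, pred)
    if cv_estimate:
        cv_mean, cv_sd, _ = crossvalidate(features, labels, config,
                                          train_ids=split.train)
        report.cv_mean_bacc, report.cv_sd_bacc = cv_mean, cv_sd
    return dict(zip(split.test, test_scores)), report


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> PerformanceReport:
    """ACC, bACC and MCC from the 2x2 confusion table.

    MCC is defined as 0 when any marginal of the table is empty (the
    conventional continuity choice).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValidationError("predictions and labels must be equal-length, "
                              "non-empty")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    n = tp + fp + fn + tn
    acc = (tp + tn) / n
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    bacc = (tpr + tnr) / 2.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / denom) if denom else 0.0
    return PerformanceReport(acc=acc, bacc=bacc, mcc=mcc,
                             tp=tp, fp=fp, fn=fn, tn=tn)


def weighted_vote(score_sets: list[dict[str, float]],
                  performances: list[float],
                  threshold: float = 0.5) -> tuple[dict[str, float], dict[str, int]]:
    """Performance-weighted consensus of per-patient scores.

    Weights are the performances normalized to sum to one; the consensus
    score is the weighted mean, thresholded at 0.5 (ties positive) for the
    binary prediction.
    """
    if not score_sets:
        raise ValidationError("need at least one model to vote")
    if len(score_sets) != len(performances):
        raise ValidationError("one performance value per score set required")
    perf = np.asarray(performances, dtype=float)
    if (perf < 0).any():
        raise ValidationError("performances must be non-negative")
    if perf.sum() == 0:
        raise ValidationError("all model performances are zero")
    weights = perf / perf.sum()
    ids = list(score_sets[0])
    for other in score_sets[1:]:
        if set(other) != set(ids):
            raise ValidationError("score sets cover different patients")
    consensus = {p: float(sum(w * s[p] for w, s in zip(weights, score_sets)))
                 for p in ids}
    predictions = {p: int(consensus[p] >= threshold) for p in ids}
    return consensus, predictions


def compare_models(bacc_groups: dict[str, list[float]],
                   alpha: float = 0.01) -> ComparisonReport:
    """Pairwise Welch t-test (2 groups) or ANOVA + Tukey HSD (more).

    Reports the accuracy gain Delta_bACC = mean(A) - mean(B) per ordered
    pair and flags significance at ``alpha``.
    """
    names = list(bacc_groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups to compare")
    arrays = {g: np.asarray(v, dtype=float) for g, v in bacc_groups.items()}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValidationError(f"group {g!r} needs at least 2 values")
    pairs = list(itertools.combinations(names, 2))
    delta = {(a, b): float(arrays[a].mean() - arrays[b].mean())
             for a, b in pairs}
    all_const = all(np.ptp(arr) == 0 for arr in arrays.values())
    p_values: dict[tuple[str, str], float] = {}
    anova_p = None
    if len(names) == 2:
        a, b = names
        if all_const and delta[(a, b)] == 0:
            p_values[(a, b)] = float("nan")
        else:
            p_values[(a, b)] = float(stats.ttest_ind(
                arrays[a], arrays[b], equal_var=False).pvalue)
    else:
        if all_const:
            p_values = {pair: float("nan") for pair in pairs}
        else:
            anova_p = float(stats.f_oneway(*arrays.values()).pvalue)
            tukey = stats.tukey_hsd(*[arrays[g] for g in names])
            for i, a in enumerate(names):
                for j, b in enumerate(names):
                    if i < j:
                        p_values[(a, b)] = float(tukey.pvalue[i, j])
    significant = {pair: (not math.isnan(p)) and p < alpha
                   for pair, p in p_values.items()}
    return ComparisonReport(groups=names, delta_bacc=delta, p_values=p_values,
                            significant=significant, anova_p=anova_p,
                            alpha=alpha)
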