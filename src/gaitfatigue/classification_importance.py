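"""Low- vs high-fatigue classification and feature-importance ranking.

Two cross-validation designs:

* intersubject — five-fold leave-subjects-out: subjects are shuffled and
  partitioned, so every window of a subject sits on one side of a fold;
  labels are binarised with the fixed rule low = {0, 1, 2},
  high = {3, 4, 5, 6};
* intrasubject — five-fold CV within each subject's own windows; the
  binarisation threshold is the mean of the training scores (score >
  mean counts as high), so it reflects the subject's baseline.  Folds
  whose training or test split lacks a class are skipped.

Per fold: missing features are imputed with training medians, the
training minority class is oversampled to parity with SMOTE (synthetic
minority interpolation between nearest neighbours), features are
standardised with statistics of the (resampled) training set, and rows
are shuffled.  The test split only ever receives training-derived
imputation and scaling — never resampling.  Four classifier families are
tuned by exhaustive grid search with inner 10-fold stratified CV scored
by balanced accuracy: RBF-kernel SVM (C, gamma), kNN (k), random forest
(trees, max features; prediction averages the trees' probabilities) and
Gaussian naive Bayes.  High fatigue is the positive class for precision,
recall and balanced accuracy.

Importance rankers: LightGBM split-gain (Gini-style node importance
normalised per fold to sum to one) and permutation importance (score drop
under K=5 seeded shuffles of one column, averaged over the four
classifier families).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

N_FOLDS = 5
INNER_CV_FOLDS = 10
FIXED_THRESHOLD = 2  # intersubject: score <= 2 is low fatigue
PERMUTATION_REPEATS = 5

SVM_GRID = [0.001, 0.01, 0.1, 1, 10, 100, 1000]
KNN_GRID = [1, 2, 3, 4, 5, 6, 8, 10, 15]
RF_TREES_GRID = [5, 10, 50, 100, 200, 500]
RF_FEATURES_GRID = ["sqrt", "log2", None]

CLASSIFIER_FAMILIES = ("svm_rbf", "knn", "rf", "gnb")


@dataclass
class CVScheme:
    mode: str  # "intersubject" | "intrasubject"
    n_folds: int = N_FOLDS

    def __post_init__(self):
        if self.mode not in ("intersubject", "intrasubject"):
            raise ValueError(f"unknown CV mode {self.mode!r}")


@dataclass
class FoldResult:
    scheme: str
    classifier: str
    fold: int
    subject_id: str | None
    balanced_accuracy: float
    precision: float
    recall: float
    params: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0


def binarise_fixed(scores) -> np.ndarray:
    """Fixed-threshold rule: 0-2 low (0), 3-6 high (1)."""
    return (np.asarray(scores) > FIXED_THRESHOLD).astype(int)


def binarise_by_training_mean(train_scores, test_scores
                              ) -> tuple[np.ndarray, np.ndarray] | None:
    """Subject-baseline rule: score > mean(training scores) is high.

    Returns None when either split ends up single-class (insufficient
    range in the scores), in which case the fold is skipped.
    """
    thr = float(np.mean(train_scores))
    y_tr = (np.asarray(train_scores) > thr).astype(int)
    y_te = (np.asarray(test_scores) > thr).astype(int)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        return None
    return y_tr, y_te


def make_intersubject_folds(subject_ids, n_folds: int, rng: np.random.Generator):
    """Partition subjects into folds; yields (train_idx, test_idx)."""
    subjects = np.unique(subject_ids)
    order = rng.permutation(subjects)
    groups = np.array_split(order, n_folds)
    sid = np.asarray(subject_ids)
    for test_subjects in groups:
        test = np.isin(sid, test_subjects)
        yield np.flatnonzero(~test), np.flatnonzero(test)


def make_intrasubject_folds(n_windows: int, n_folds: int, rng: np.random.Generator):
    """KFold over one subject's windows, shuffled; sizes differ by <= 1."""
    k = min(n_folds, n_windows)
    if k < 2:
        return
    kf = KFold(n_splits=k, shuffle=True,
               random_state=int(rng.integers(2 ** 31 - 1)))
    yield from kf.split(np.arange(n_windows))


def smote_oversample(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                     k_neighbors: int = 5) -> tuple[np.ndarray, np.ndarray] | None:
    """Oversample the minority class to parity by SMOTE interpolation.

    New samples are x_i + u (x_j - x_i) for a random minority point x_i, a
    random one of its k nearest minority neighbours x_j and u ~ U(0, 1).
    k is reduced to minority-1 when the class is small; a minority class
    of fewer than two members makes SMOTE impossible (None).
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        return None
    minority = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    if n_new == 0:
        return X, y
    Xm = X[y == minority]
    if len(Xm) < 2:
        return None
    k = min(k_neighbors, len(Xm) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)
    base = rng.integers(len(Xm), size=n_new)
    pick = neigh[base, rng.integers(1, k + 1, size=n_new)]
    u = rng.uniform(size=(n_new, 1))
    synthetic = Xm[base] + u * (Xm[pick] - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


def preprocess_fold(X_train, y_train, X_test, rng: np.random.Generator,
                    smote: bool = True):
    """Impute, SMOTE (training only), scale and shuffle one fold.

    Imputation medians and scaling statistics derive from the training
    split alone; the test split is imputed and scaled with them, never
    resampled.  Returns (X_train, y_train, X_test, medians, mu, sd) or
    None when SMOTE is impossible.
    """
    X_train = np.asarray(X_train, dtype=float).copy()
    X_test = np.asarray(X_test, dtype=float).copy()
    y_train = np.asarray(y_train)
    medians = np.nanmedian(X_train, axis=0)
    medians = np.where(np.isfinite(medians), medians, 0.0)
    for X in (X_train, X_test):
        mask = ~np.isfinite(X)
        X[mask] = np.take(medians, np.nonzero(mask)[1])
    if smote:
        resampled = smote_oversample(X_train, y_train, rng)
        if resampled is None:
            logger.info("fold skipped: minority class too small for SMOTE")
            return None
        X_train, y_train = resampled
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    X_train = (X_train - mu) / sd
    X_test = (X_test - mu) / sd
    order = rng.permutation(len(y_train))
    return X_train[order], y_train[order], X_test, medians, mu, sd


def classifier_grid(family: str, seed: int, grids: dict | None = None):
    """Estimator and hyperparameter grid for one classifier family."""
    grids = grids or {}
    if family == "svm_rbf":
        est = SVC(kernel="rbf", random_state=seed)
        grid = {"C": grids.get("svm", SVM_GRID),
                "gamma": grids.get("svm", SVM_GRID)}
    elif family == "knn":
        est = KNeighborsClassifier()
        grid = {"n_neighbors": grids.get("knn", KNN_GRID)}
    elif family == "rf":
        est = RandomForestClassifier(random_state=seed)
        grid = {"n_estimators": grids.get("rf_trees", RF_TREES_GRID),
                "max_features": grids.get("rf_features", RF_FEATURES_GRID)}
    elif family == "gnb":
        est = GaussianNB()
        grid = {}
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    return est, grid


def grid_search_fit(X_train, y_train, family: str, seed: int,
                    inner_folds: int = INNER_CV_FOLDS, grids: dict | None = None):
    """Exhaustive grid search with stratified inner CV on balanced accuracy."""
    est, grid = classifier_grid(family, seed, grids)
    if not grid:
        return est.fit(X_train, y_train), {}
    folds = min(inner_folds, int(np.bincount(y_train).min()))
    if folds < 2:
        return clone(est).fit(X_train, y_train), {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="balanced_accuracy", cv=cv,
                          error_score=0.0, n_jobs=1)
    search.fit(X_train, y_train)
    return search.best_estimator_, dict(search.best_params_)


def evaluate(y_true, y_pred) -> dict[str, float]:
    """Precision, recall and balanced accuracy from the confusion counts.

    High fatigue (1) is the positive class.  Precision is missing when no
    positive predictions exist; an empty test split yields no metrics.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        return {"balanced_accuracy": np.nan, "precision": np.nan, "recall": np.nan}
    tp = float(np.sum((y_true == 1) & (y_pred == 1)))
    tn = float(np.sum((y_true == 0) & (y_pred == 0)))
    fp = float(np.sum((y_true == 0) & (y_pred == 1)))
    fn = float(np.sum((y_true == 1) & (y_pred == 0)))
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    sens = tp / (tp + fn) if tp + fn > 0 else np.nan
    spec = tn / (tn + fp) if tn + fp > 0 else np.nan
    return {
        "balanced_accuracy": 0.5 * (sens + spec),
        "precision": precision,
        "recall": recall,
    }


def _predict(model, X):
    if isinstance(model, RandomForestClassifier):
        # average of the trees' probabilistic predictions
        proba = model.predict_proba(X)
        return model.classes_[np.argmax(proba, axis=1)]
    return model.predict(X)


def run_classification(
    dataset: pd.DataFrame,
    feature_cols: list[str],
    label: str,
    scheme: CVScheme,
    seed: int = 0,
    families: tuple[str, ...] = CLASSIFIER_FAMILIES,
    inner_folds: int = INNER_CV_FOLDS,
    grids: dict | None = None,
) -> pd.DataFrame:
    """Run one CV design over the dataset; one row per (fold, classifier)."""
    rng = np.random.default_rng(seed)
    data = dataset.dropna(subset=[label]).reset_index(drop=True)
    X_all = data[feature_cols].to_numpy(float)
    scores = data[label].to_numpy(float)
    sid = data["subject_id"].to_numpy()
    results: list[FoldResult] = []

    def run_fold(tr, te, fold_no, subject, y_tr, y_te):
        prep = preprocess_fold(X_all[tr], y_tr, X_all[te], rng)
        if prep is None:
            return
        X_tr, y_tr2, X_te, *_ = prep
        for family in families:
            fam_seed = int(rng.integers(2 ** 31 - 1))
            model, params = grid_search_fit(X_tr, y_tr2, family, fam_seed,
                                            inner_folds=inner_folds, grids=grids)
            metrics = evaluate(y_te, _predict(model, X_te))
            results.append(FoldResult(scheme.mode, family, fold_no, subject,
                                      metrics["balanced_accuracy"],
                                      metrics["precision"], metrics["recall"],
                                      params, len(y_tr2), len(y_te)))

    if scheme.mode == "intersubject":
        y_bin = binarise_fixed(scores)
        for fold_no, (tr, te) in enumerate(
                make_intersubject_folds(sid, scheme.n_folds, rng)):
            if len(np.unique(y_bin[tr])) < 2 or len(te) == 0:
                logger.info("intersubject fold %d skipped: single class", fold_no)
                continue
            run_fold(tr, te, fold_no, None, y_bin[tr], y_bin[te])
    else:
        for subject in np.unique(sid):
            s_idx = np.flatnonzero(sid == subject)
            if len(s_idx) < 2:
                logger.info("subject %s skipped: fewer than 2 windows", subject)
                continue
            for fold_no, (tr_loc, te_loc) in enumerate(
                    make_intrasubject_folds(len(s_idx), scheme.n_folds, rng)):
                tr, te = s_idx[tr_loc], s_idx[te_loc]
                split = binarise_by_training_mean(scores[tr], scores[te])
                if split is None:
                    logger.info("subject %s fold %d skipped: not enough score "
                                "range to form two classes", subject, fold_no)
                    continue
                run_fold(tr, te, fold_no, subject, *split)
    return pd.DataFrame([r.__dict__ for r in results])


def lgbm_gini_importance(
    dataset: pd.DataFrame,
    feature_cols: list[str],
    labels: np.ndarray,
    n_folds: int = N_FOLDS,
    seed: int = 0,
    lgbm_params: dict | None = None,
) -> pd.Series:
    """Split-gain feature importance from a boosted-tree ensemble.

    Per fold, an LGBM classifier is trained and each feature's summed gain
    over the nodes splitting on it is normalised by the total gain
    (importances sum to one when any split occurred); fold values are
    averaged.  A feature never split on scores zero.
    """
    rng = np.random.default_rng(seed)
    X = dataset[feature_cols].to_numpy(float)
    y = np.asarray(labels)
    params = {"n_estimators": 100, "verbosity": -1, "min_child_samples": 5}
    params.update(lgbm_params or {})
    kf = StratifiedKFold(n_splits=min(n_folds, int(np.bincount(y).min()), len(y)),
                         shuffle=True, random_state=int(rng.integers(2 ** 31 - 1)))
    imp = np.zeros(len(feature_cols))
    n_used = 0
    for tr, _ in kf.split(X, y):
        model = LGBMClassifier(random_state=int(rng.integers(2 ** 31 - 1)),
                               importance_type="gain", **params)
        model.fit(X[tr], y[tr])
        gains = model.booster_.feature_importance(importance_type="gain")
        total = gains.sum()
        if total > 0:
            imp += gains / total
            n_used += 1
    if n_used:
        imp /= n_used
    return pd.Series(imp, index=feature_cols, name="lgbm_gain")


def permutation_importance_scores(
    model,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_repeats: int = PERMUTATION_REPEATS,
) -> np.ndarray:
    """Balanced-accuracy drop under K seeded shuffles of each column.

    importance_j = s - mean_k s_{k,j}, with s the reference balanced
    accuracy on (X, y).  A feature the model ignores scores exactly zero
    only in expectation; a constant column scores exactly zero since its
    permutation leaves X unchanged.
    """
    base = evaluate(y, _predict(model, X))["balanced_accuracy"]
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            drops.append(evaluate(y, _predict(model, Xp))["balanced_accuracy"])
        out[j] = base - np.mean(drops)
    return out


def mean_permutation_importance(
    dataset: pd.DataFrame,
    feature_cols: list[str],
    labels: np.ndarray,
    seed: int = 0,
    families: tuple[str, ...] = CLASSIFIER_FAMILIES,
    inner_folds: int = 3,
    grids: dict | None = None,
    n_repeats: int = PERMUTATION_REPEATS,
) -> pd.Series:
    """Permutation importance averaged over the four classifier families.

    Models are tuned and fitted on a training split (stratified 80%), and
    importances are measured on the held-out split.
    """
    rng = np.random.default_rng(seed)
    X = dataset[feature_cols].to_numpy(float)
    y = np.asarray(labels)
    kf = StratifiedKFold(n_splits=5, shuffle=True,
                         random_state=int(rng.integers(2 ** 31 - 1)))
    tr, te = next(kf.split(X, y))
    prep = preprocess_fold(X[tr], y[tr], X[te], rng)
    if prep is None:
        return pd.Series(np.nan, index=feature_cols, name="permutation")
    X_tr, y_tr, X_te, *_ = prep
    total = np.zeros(len(feature_cols))
    for family in families:
        model, _ = grid_search_fit(X_tr, y_tr, family,
                                   int(rng.integers(2 ** 31 - 1)),
                                   inner_folds=inner_folds, grids=grids)
        total += permutation_importance_scores(model, X_te, y[te], rng,
                                               n_repeats=n_repeats)
    return pd.Series(total / len(families), index=feature_cols, name="permutation")
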