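"""Diagnostic classification from FNC features.

Four feature strategies vectorise the unique off-diagonal FNC elements:
``OriginalFNC`` (unsplit networks, 28 features for 8 networks), ``ActFNC``
and ``InertFNC`` (one side each, 28), and ``AllFNC`` (both sides, 120).
Features are ranked by gradient-boosted-tree importance on the training
split only, the top-k feed a linear SVM whose regularisation strength is
chosen by 10-fold cross-validation, and performance is measured on a held-
out stratified 30% test set.  Repeated random splits give the performance
distribution; label permutation gives the chance distribution; McNemar's
test compares two strategies' predictions on a common test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .fnc import FncMatrix

STRATEGIES = ("OriginalFNC", "ActFNC", "InertFNC", "AllFNC")

_MODE_FOR_STRATEGY = {"OriginalFNC": "original", "ActFNC": "act",
                      "InertFNC": "inert", "AllFNC": "all"}


@dataclass
class FeatureTable:
    """Subjects x FNC-edge feature matrix with edge names and class labels."""

    X: np.ndarray
    feature_labels: list[str]
    strategy: str
    labels: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_labels):
            raise ValueError("feature matrix / label mismatch")
        if self.X.shape[0] != self.labels.size:
            raise ValueError("row count does not match subject labels")
        if np.isnan(self.X).any():
            raise ValueError("feature table contains missing entries")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, rows=None, cols=None) -> "FeatureTable":
        rows = (np.arange(self.X.shape[0]) if rows is None
                else np.asarray(rows, dtype=int))
        cols = (np.arange(self.n_features) if cols is None
                else np.asarray(cols, dtype=int))
        return FeatureTable(self.X[np.ix_(rows, cols)],
                            [self.feature_labels[c] for c in cols],
                            self.strategy, self.labels[rows])


def build_features(fncs: list[FncMatrix], strategy: str,
                   labels: np.ndarray) -> FeatureTable:
    """Vectorise each subject's unique off-diagonal FNC elements.

    Edge order is the fixed upper-triangle order of the labelled matrix;
    edges touching any subject's missing network are dropped cohort-wide so
    the table has no missing entries.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    mat_labels = fncs[0].labels
    n = len(mat_labels)
    iu, ju = np.triu_indices(n, k=1)
    edge_names = [f"{mat_labels[i]}-{mat_labels[j]}" for i, j in zip(iu, ju)]
    stack = np.stack([m.values[iu, ju] for m in fncs])
    keep = ~np.isnan(stack).any(axis=0)
    return FeatureTable(stack[:, keep],
                        [e for e, k in zip(edge_names, keep) if k],
                        strategy, labels)


def features_from_splits(all_splits, labels, strategy: str,
                         original_tcs=None) -> FeatureTable:
    """Build a FeatureTable straight from per-subject NetworkSplit lists."""
    from .fnc import compute_fnc

    mode = _MODE_FOR_STRATEGY[strategy]
    fncs = [compute_fnc(s, mode,
                        original_tcs[i] if original_tcs is not None else None)
            for i, s in enumerate(all_splits)]
    return build_features(fncs, strategy, labels)


def select_features(train: FeatureTable, k: int, seed: int = 0) -> np.ndarray:
    """Top-k feature indices by gradient-boosted-tree total-gain importance.

    The booster is fit on the training rows only; ties are broken by stable
    feature order.
    """
    if k > train.n_features:
        raise ValueError("k exceeds the feature count")
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise ValueError("training set holds a single class")
    model = XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.3,
                          tree_method="hist", random_state=seed,
                          verbosity=0, n_jobs=1)
    model.fit(train.X, train.labels)
    booster = model.get_booster()
    gains = booster.get_score(importance_type="total_gain")
    imp = np.zeros(train.n_features)
    for name, gain in gains.items():
        imp[int(name[1:])] = gain
    # stable sort: descending importance, then ascending feature index
    order = np.lexsort((np.arange(train.n_features), -imp))
    return np.sort(order[:k])


@dataclass
class SvmConfig:
    kernel: str = "linear"
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    cv_folds: int = 10
    n_selected: int = 20


@dataclass
class EvalResult:
    """Held-out test metrics for one split; metrics recompute from counts."""

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    predictions: np.ndarray
    truth: np.ndarray
    seed: int
    confusion: tuple[int, int, int, int] = (0, 0, 0, 0)  # tp, fn, tn, fp


def _metrics(truth: np.ndarray, pred: np.ndarray, seed: int) -> EvalResult:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    tp = int(((truth == 1) & (pred == 1)).sum())
    fn = int(((truth == 1) & (pred == 0)).sum())
    tn = int(((truth == 0) & (pred == 0)).sum())
    fp = int(((truth == 0) & (pred == 1)).sum())
    acc = (tp + tn) / truth.size
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return EvalResult(acc, sens, spec, f1, pred, truth, seed, (tp, fn, tn, fp))


def train_eval_svm(train: FeatureTable, test: FeatureTable,
                   config: SvmConfig | None = None, seed: int = 0) -> EvalResult:
    """Fit an SVM on the training split and score the held-out test split.

    Standardisation statistics, feature selection, and the 10-fold CV grid
    search over the regularisation strength all use the training rows only.
    Sensitivity is the true-positive rate of the patient class (label 1),
    specificity the true-negative rate of the control class (label 0).
    """
    config = config or SvmConfig()
    if test.X.shape[0] == 0:
        raise ValueError("empty test set")
    k = min(config.n_selected, train.n_features)
    cols = select_features(train, k, seed=seed)
    scaler = StandardScaler().fit(train.X[:, cols])
    Xtr = scaler.transform(train.X[:, cols])
    Xte = scaler.transform(test.X[:, cols])
    folds = min(config.cv_folds, np.bincount(train.labels.astype(int)).min())
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        search = GridSearchCV(SVC(kernel=config.kernel),
                              {"C": list(config.c_grid)}, cv=cv, n_jobs=1)
        search.fit(Xtr, train.labels)
        clf = search.best_estimator_
    else:
        clf = SVC(kernel=config.kernel, C=1.0).fit(Xtr, train.labels)
    return _metrics(test.labels, clf.predict(Xte), seed)


def split_table(table: FeatureTable, test_size: float = 0.3, seed: int = 0):
    """Stratified train/test split of a feature table."""
    idx = np.arange(table.X.shape[0])
    tr, te = train_test_split(idx, test_size=test_size, random_state=seed,
                              stratify=table.labels)
    return table.subset(rows=tr), table.subset(rows=te)


def evaluate_strategy(table: FeatureTable, n_repeats: int = 100,
                      config: SvmConfig | None = None,
                      test_size: float = 0.3,
                      permute: bool = False) -> list[EvalResult]:
    """Repeated stratified-split evaluation (seeds 0..n_repeats-1).

    With ``permute=True`` the subject labels are randomly shuffled before
    each split — the permutation null whose accuracy distribution should
    centre on chance.
    """
    results = []
    for seed in range(n_repeats):
        t = table
        if permute:
            rng = np.random.default_rng(seed)
            t = FeatureTable(table.X, table.feature_labels, table.strategy,
                             rng.permutation(table.labels))
        train, test = split_table(t, test_size=test_size, seed=seed)
        results.append(train_eval_svm(train, test, config, seed=seed))
    return results


def mcnemar_test(predA: np.ndarray, predB: np.ndarray,
                 truth: np.ndarray) -> tuple[float, float]:
    """McNemar's test on the discordant correct/incorrect pairs.

    Returns the continuity-corrected chi-square statistic
    ``(|b - c| - 1)^2 / (b + c)`` and a p-value — exact binomial when the
    discordant count ``b + c < 25``, chi-square otherwise.  ``b + c = 0``
    yields ``(0, 1)`` by convention.
    """
    predA, predB, truth = map(np.asarray, (predA, predB, truth))
    if not predA.shape == predB.shape == truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    okA = predA == truth
    okB = predB == truth
    b = int((okA & ~okB).sum())   # A right, B wrong
    c = int((~okA & okB).sum())   # A wrong, B right
    n = b + c
    if n == 0:
        return 0.0, 1.0
    statistic = (abs(b - c) - 1) ** 2 / n
    if n < 25:
        p = float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
    else:
        p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def single_feature_screen(table: FeatureTable, repeats: int = 20,
                          f1_threshold: float = 0.65,
                          test_size: float = 0.3) -> pd.DataFrame:
    """Classify with each single edge alone and rank by mean F1.

    Each feature is evaluated over ``repeats`` random stratified splits with
    a one-feature linear SVM; the returned table is ranked by mean F1 and
    flags features exceeding ``f1_threshold``.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rows = []
    for j, name in enumerate(table.feature_labels):
        scores = []
        for seed in range(repeats):
            sub = table.subset(cols=[j])
            train, test = split_table(sub, test_size=test_size, seed=seed)
            scaler = StandardScaler().fit(train.X)
            clf = SVC(kernel="linear", C=1.0).fit(
                scaler.transform(train.X), train.labels)
            pred = clf.predict(scaler.transform(test.X))
            scores.append(f1_score(test.labels, pred, zero_division=0))
        rows.append({"feature": name, "mean_f1": float(np.mean(scores))})
    df = pd.DataFrame(rows).sort_values("mean_f1", ascending=False,
                                        kind="stable").reset_index(drop=True)
    df["selected"] = df["mean_f1"] > f1_threshold
    return df


class StrategyComparison:
    """Model front-end: evaluate several feature strategies side by side."""

    def __init__(self, tables: dict[str, FeatureTable], n_repeats: int = 100,
                 config: SvmConfig | None = None, test_size: float = 0.3):
        self.tables = tables
        self.n_repeats = n_repeats
        self.config = config or SvmConfig()
        self.test_size = test_size

    def fit(self) -> "StrategyComparisonResults":
        results = {name: evaluate_strategy(t, self.n_repeats, self.config,
                                           self.test_size)
                   for name, t in self.tables.items()}
        return StrategyComparisonResults(self, results)


class StrategyComparisonResults:
    def __init__(self, model: StrategyComparison,
                 results: dict[str, list[EvalResult]]):
        self.model = model
        self.results = results

    def metric(self, name: str, metric: str = "accuracy") -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.results[name]])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.results:
            rows.append({
                "strategy": name,
                "mean_accuracy": self.metric(name).mean(),
                "mean_sensitivity": self.metric(name, "sensitivity").mean(),
                "mean_specificity": self.metric(name, "specificity").mean(),
                "mean_f1": self.metric(name, "f1").mean(),
            })
        return pd.DataFrame(rows)

    def compare(self, a: str, b: str, metric: str = "accuracy"):
        """Two-sample t-test on the repeat distributions of two strategies."""
        t, p = stats.ttest_ind(self.metric(a, metric), self.metric(b, metric))
        return float(t), float(p)

    def long_format(self) -> pd.DataFrame:
        rows = []
        for name, results in self.results.items():
            for r in results:
                for metric in ("accuracy", "sensitivity", "specificity", "f1"):
                    rows.append({"strategy": name, "seed": r.seed,
                                 "metric": metric, "value": getattr(r, metric)})
        return pd.DataFrame(rows)
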