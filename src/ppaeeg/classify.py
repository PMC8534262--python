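"""Classifier benchmark: split, scale, select, tune, evaluate.

The modelling pipeline is: stratified 80/20 split by subject; min-max
scaling fitted on the training split; univariate ANOVA-F selection of the
best k = 50 features (optional); per model, Bayesian hyperparameter search
maximizing mean 10-fold cross-validated F1; final refit on the full
training split and held-out evaluation.  Seven classifiers are compared:
Decision Tree, Elastic Net (logistic regression with elastic-net
penalty), SVM, Random Forest, kNN, Gaussian NB, and Multinomial NB.

Binary mode pools the three PPA variants against controls, with PPA as
the positive class; multiclass mode keeps the four groups and reports
macro-averaged metrics.  Nothing fitted (scaler, selector, search) ever
sees a test subject; the report carries an audit log of what saw what.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, f1_score, make_scorer, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB, MultinomialNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import FunctionTransformer, MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .bayesopt import Categorical, Integer, Real, bayes_search

LABEL_COLUMN = "label"
POSITIVE_CLASS = "PPA"
MODEL_KINDS = (
    "decision_tree",
    "elastic_net",
    "svm",
    "random_forest",
    "knn",
    "gaussian_nb",
    "multinomial_nb",
)
MODEL_NAMES = {
    "decision_tree": "Decision Tree",
    "elastic_net": "Elastic Net",
    "svm": "SVM",
    "random_forest": "Random Forest",
    "knn": "kNN",
    "gaussian_nb": "Gaussian NB",
    "multinomial_nb": "Multinomial NB",
}


def make_table(
    feature_rows: dict[str, dict[str, float]], labels: dict[str, str]
) -> pd.DataFrame:
    """Subjects x features table with a ``label`` column."""
    df = pd.DataFrame.from_dict(feature_rows, orient="index").sort_index()
    if df.isna().any().any():
        raise ValueError("feature table contains missing values")
    if df.columns.duplicated().any():
        raise ValueError("duplicate feature names")
    df[LABEL_COLUMN] = [labels[s] for s in df.index]
    return df


def binarize_labels(labels: pd.Series | list[str]) -> pd.Series:
    """Pool the PPA variants: any non-CG label becomes 'PPA'."""
    s = pd.Series(labels)
    return s.where(s == "CG", POSITIVE_CLASS)


def split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    X = table.drop(columns=[LABEL_COLUMN])
    return X, table[LABEL_COLUMN]


def stratified_split(
    table: pd.DataFrame, train_frac: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Per class, round-half-up of train_frac*n subjects go to train.

    Returns (train_ids, test_ids); every class must keep at least one test
    subject and have at least two members.
    """
    y = table[LABEL_COLUMN]
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for cls in sorted(y.unique()):
        members = list(table.index[y == cls])
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = math.floor(train_frac * len(members) + 0.5)
        if n_train >= len(members):
            raise ValueError(
                f"train_frac {train_frac} leaves no test subjects for {cls!r}"
            )
        order = rng.permutation(len(members))
        train_ids += [members[i] for i in order[:n_train]]
        test_ids += [members[i] for i in order[n_train:]]
    return sorted(train_ids), sorted(test_ids)


def minmax_scale(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, MinMaxScaler]:
    """Fit a [0, 1] scaler on train only; test may exceed the range."""
    constant = train.columns[(train.max() - train.min()) == 0]
    if len(constant):
        warnings.warn(
            f"{len(constant)} constant feature column(s) map to 0", stacklevel=2
        )
    scaler = MinMaxScaler().fit(train.values)
    train_s = pd.DataFrame(
        scaler.transform(train.values), index=train.index, columns=train.columns
    )
    test_s = pd.DataFrame(
        scaler.transform(test.values), index=test.index, columns=test.columns
    )
    return train_s, test_s, scaler


def select_features_anova(
    train: pd.DataFrame, labels: pd.Series, k: int = 50
) -> tuple[list[str], dict[str, float]]:
    """The k columns with the largest one-way ANOVA F statistic.

    Ties are broken by column-name order.  Returns (selected names in rank
    order, F-score per column).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > train.shape[1]:
        raise ValueError(f"k = {k} exceeds {train.shape[1]} columns")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns yield 0/0
        F, _ = f_classif(train.values, labels.loc[train.index].values)
    F = np.nan_to_num(F, nan=0.0, posinf=np.finfo(float).max)
    scores = dict(zip(train.columns, F.astype(float)))
    ranked = sorted(train.columns, key=lambda c: (-scores[c], c))
    return ranked[:k], scores


@dataclass
class ClassificationMetrics:
    """Confusion-count metrics; undefined ratios are reported as NaN."""

    f1: float
    precision: float
    sensitivity: float
    specificity: float
    youden: float
    accuracy: float
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None
    tn: int | None = None


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_confusion(
    tp: int, fp: int, fn: int, tn: int
) -> ClassificationMetrics:
    """Precision, sensitivity, specificity, F1, Youden index and accuracy
    from binary confusion counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("negative confusion counts")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(tp, tp + fp)
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    f1 = _ratio(2 * precision * sensitivity, precision + sensitivity)
    return ClassificationMetrics(
        f1=f1,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        youden=sensitivity + specificity - 1,
        accuracy=(tp + tn) / total,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )


def multiclass_metrics(cm: np.ndarray) -> ClassificationMetrics:
    """Macro average of the one-vs-rest metrics over the classes."""
    cm = np.asarray(cm)
    per: list[ClassificationMetrics] = []
    for i in range(cm.shape[0]):
        tp = int(cm[i, i])
        fn = int(cm[i].sum() - tp)
        fp = int(cm[:, i].sum() - tp)
        tn = int(cm.sum() - tp - fn - fp)
        per.append(metrics_from_confusion(tp, fp, fn, tn))
    mean = lambda vals: float(np.nanmean(vals))  # noqa: E731
    return ClassificationMetrics(
        f1=mean([m.f1 for m in per]),
        precision=mean([m.precision for m in per]),
        sensitivity=mean([m.sensitivity for m in per]),
        specificity=mean([m.specificity for m in per]),
        youden=mean([m.youden for m in per]),
        accuracy=float(np.trace(cm) / cm.sum()),
    )


def _search_space(kind: str, n_train: int) -> dict:
    if kind == "decision_tree":
        return {
            "max_depth": Integer(1, 10),
            "min_samples_split": Integer(2, 10),
            "criterion": Categorical(("gini", "entropy")),
        }
    if kind == "elastic_net":
        return {"C": Real(1e-3, 1e2, log=True), "l1_ratio": Real(0.0, 1.0)}
    if kind == "svm":
        return {
            "C": Real(1e-2, 1e3, log=True),
            "gamma": Real(1e-4, 10.0, log=True),
            "kernel": Categorical(("rbf", "linear")),
        }
    if kind == "random_forest":
        return {
            "n_estimators": Integer(50, 200),
            "max_depth": Integer(2, 12),
            "max_features": Categorical(("sqrt", "log2")),
        }
    if kind == "knn":
        # n_train here is the smallest number of samples any CV fit sees
        return {
            "n_neighbors": Integer(1, max(2, min(25, n_train - 1))),
            "weights": Categorical(("uniform", "distance")),
            "p": Categorical((1, 2)),
        }
    if kind == "gaussian_nb":
        return {"var_smoothing": Real(1e-12, 1e-6, log=True)}
    if kind == "multinomial_nb":
        return {"alpha": Real(1e-3, 10.0, log=True)}
    raise ValueError(f"unknown model kind {kind!r}")


def build_model(kind: str, params: dict, seed: int = 0):
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "elastic_net":
        return LogisticRegression(
            penalty="elasticnet", solver="saga", max_iter=5000,
            random_state=seed, **params,
        )
    if kind == "svm":
        return SVC(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if kind == "knn":
        return KNeighborsClassifier(**params)
    if kind == "gaussian_nb":
        return GaussianNB(**params)
    if kind == "multinomial_nb":
        # min-max scaling makes train non-negative; clip guards test rows
        # that extrapolate below the train minimum
        return make_pipeline(
            FunctionTransformer(lambda X: np.clip(X, 0.0, None)),
            MultinomialNB(**params),
        )
    raise ValueError(f"unknown model kind {kind!r}")


def _scorer(y: pd.Series):
    if set(y.unique()) <= {POSITIVE_CLASS, "CG"}:
        return make_scorer(
            f1_score, pos_label=POSITIVE_CLASS, zero_division=0
        )
    return make_scorer(f1_score, average="macro", zero_division=0)


def tune_and_train(
    kind: str,
    X: pd.DataFrame,
    y: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_iter: int = 32,
):
    """Bayes-search the model's space on mean CV F1; refit on all of X.

    Returns (fitted model, best params, best CV F1, search trace).  If the
    smallest class cannot sustain the requested fold count, the largest
    feasible count is used with a warning.
    """
    smallest = y.value_counts().min()
    if folds > smallest:
        warnings.warn(
            f"reducing folds from {folds} to {smallest} (smallest class)",
            stacklevel=2,
        )
        folds = int(smallest)
    if folds < 2:
        raise ValueError("need at least 2 feasible CV folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scorer = _scorer(y)

    def objective(params: dict) -> float:
        model = build_model(kind, params, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = cross_val_score(model, X.values, y.values, cv=cv, scoring=scorer)
        mean = float(scores.mean())
        return mean if np.isfinite(mean) else 0.0  # failed fits score zero

    fold_train = len(X) * (folds - 1) // folds
    best_params, best_score, trace = bayes_search(
        objective, _search_space(kind, fold_train), n_iter=n_iter, seed=seed
    )
    model = build_model(kind, best_params, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X.values, y.values)
    return model, best_params, best_score, trace


@dataclass
class EvalResult:
    metrics: ClassificationMetrics
    confusion: np.ndarray
    classes: list[str]
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)
    auc: float | None = None


def _positive_scores(model, X: np.ndarray, classes: list[str]) -> np.ndarray | None:
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        model_classes = list(getattr(model, "classes_", classes))
        if hasattr(model, "steps"):
            model_classes = list(model.steps[-1][1].classes_)
        return proba[:, model_classes.index(POSITIVE_CLASS)]
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    return None


def evaluate(
    model, X: pd.DataFrame, y: pd.Series, positive_class: str = POSITIVE_CLASS
) -> EvalResult:
    """Held-out metrics; binary adds ROC points and trapezoidal AUC."""
    if len(X) == 0:
        raise ValueError("empty test set")
    classes = sorted(set(y.unique()))
    model_classes = getattr(model, "classes_", None)
    if model_classes is not None:
        unseen = set(y.unique()) - set(model_classes)
        if unseen:
            raise ValueError(f"classes in test unseen by the model: {unseen}")
    y_pred = model.predict(X.values)
    cm = confusion_matrix(y.values, y_pred, labels=classes)
    if len(classes) == 2 and positive_class in classes:
        pos = classes.index(positive_class)
        neg = 1 - pos
        metrics = metrics_from_confusion(
            tp=int(cm[pos, pos]), fp=int(cm[neg, pos]),
            fn=int(cm[pos, neg]), tn=int(cm[neg, neg]),
        )
        scores = _positive_scores(model, X.values, classes)
        roc = auc = None
        if scores is not None and len(np.unique(y.values)) == 2:
            fpr, tpr, _ = roc_curve(y.values, scores, pos_label=positive_class)
            roc, auc = (fpr, tpr), float(np.trapezoid(tpr, fpr))
        return EvalResult(metrics=metrics, confusion=cm, classes=classes, roc=roc, auc=auc)
    return EvalResult(metrics=multiclass_metrics(cm), confusion=cm, classes=classes)


@dataclass
class ModelResult:
    kind: str
    name: str
    params: dict
    cv_f1: float
    test: EvalResult


@dataclass
class BenchmarkReport:
    mode: str
    results: list[ModelResult]
    selected_features: list[str]
    feature_scores: dict[str, float]
    train_ids: list
    test_ids: list
    audit: dict = field(default_factory=dict)

    def best(self) -> ModelResult:
        return max(self.results, key=lambda r: (r.test.metrics.f1, r.name))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            m = r.test.metrics
            rows.append(
                {
                    "model": r.name,
                    "cv_f1": r.cv_f1,
                    "f1": m.f1,
                    "precision": m.precision,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "youden": m.youden,
                    "accuracy": m.accuracy,
                    "auc": r.test.auc,
                }
            )
        return pd.DataFrame(rows).set_index("model")


def run_benchmark(
    table: pd.DataFrame,
    mode: str = "binary",
    select_features: bool = True,
    k: int = 50,
    train_frac: float = 0.8,
    folds: int = 10,
    seed: int = 0,
    n_iter: int = 32,
    split: tuple[list, list] | None = None,
    audit: dict | None = None,
) -> BenchmarkReport:
    """Benchmark all seven classifiers on a shared split and selection."""
    if mode not in ("binary", "multiclass"):
        raise ValueError("mode must be 'binary' or 'multiclass'")
    table = table.copy()
    if mode == "binary":
        table[LABEL_COLUMN] = binarize_labels(table[LABEL_COLUMN]).values
    train_ids, test_ids = split if split is not None else stratified_split(
        table, train_frac=train_frac, seed=seed
    )
    X, y = split_xy(table)
    X_train, X_test = X.loc[train_ids], X.loc[test_ids]
    y_train, y_test = y.loc[train_ids], y.loc[test_ids]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_train, X_test, _ = minmax_scale(X_train, X_test)

    if select_features:
        selected, scores = select_features_anova(X_train, y_train, k=min(k, X.shape[1]))
    else:
        selected = list(X.columns)
        _, scores = select_features_anova(X_train, y_train, k=X.shape[1])
    X_train, X_test = X_train[selected], X_test[selected]

    results = []
    for kind in MODEL_KINDS:
        model, params, cv_f1, _ = tune_and_train(
            kind, X_train, y_train, folds=folds, seed=seed, n_iter=n_iter
        )
        results.append(
            ModelResult(
                kind=kind,
                name=MODEL_NAMES[kind],
                params=params,
                cv_f1=cv_f1,
                test=evaluate(model, X_test, y_test),
            )
        )
    full_audit = {
        "scaler_fit_on": list(train_ids),
        "selector_fit_on": list(train_ids),
        "search_cv_on": list(train_ids),
        "test_subjects": list(test_ids),
    }
    if audit:
        full_audit.update(audit)
    return BenchmarkReport(
        mode=mode,
        results=results,
        selected_features=selected,
        feature_scores=scores,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        audit=full_audit,
    )
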