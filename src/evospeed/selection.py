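"""Supervised model selection over divergence models with kappa weighting.

Classifiers from several algorithm families are trained on labelled summary
vectors (one row per completed simulation, label = divergence model M0-M3),
evaluated on an untouched holdout third, and combined: per-clade class
probabilities from each algorithm are averaged with weights equal to each
algorithm's holdout Cohen's kappa, yielding model-averaged support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ALGORITHMS",
    "AlgorithmResult",
    "TrainedEnsemble",
    "SupportProfile",
    "cohen_kappa",
    "kappa_weighted_support",
    "train_classifiers",
    "variable_importance",
    "classify_clade",
]

#: the seven default algorithm families and their (small) tuning grids
ALGORITHMS = ("lda", "cart", "rf", "gbm", "nb", "svm", "nnet")


def _estimator_and_grid(name: str, seed: int):
    if name == "lda":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto"), {}
    if name == "cart":
        return DecisionTreeClassifier(random_state=seed), {"max_depth": [3, 6, None]}
    if name == "rf":
        return RandomForestClassifier(n_estimators=300, random_state=seed), {
            "max_features": ["sqrt", 0.5]
        }
    if name == "gbm":
        return HistGradientBoostingClassifier(random_state=seed), {
            "learning_rate": [0.1, 0.3]
        }
    if name == "nb":
        return GaussianNB(), {}
    if name == "svm":
        return SVC(probability=True, random_state=seed), {"C": [1.0, 10.0]}
    if name == "nnet":
        return (
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=2000, random_state=seed),
            {"alpha": [1e-4, 1e-2]},
        )
    raise ValueError(f"unknown algorithm {name!r}")


@dataclass
class AlgorithmResult:
    """One fitted algorithm with its holdout diagnostics."""

    name: str
    estimator: object
    confusion: np.ndarray
    accuracy: float
    kappa: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    importance: pd.Series  # permutation importance, scaled to [0, 100]


@dataclass
class TrainedEnsemble:
    """Per-algorithm classifiers plus shared preprocessing state."""

    algorithms: dict[str, AlgorithmResult]
    feature_names: list[str]
    classes: list[str]
    medians: pd.Series  # training-split medians for imputation
    center: np.ndarray
    scale: np.ndarray

    def preprocess(self, X: pd.DataFrame) -> np.ndarray:
        X = X.reindex(columns=self.feature_names)
        X = X.fillna(self.medians)
        return (X.to_numpy(dtype=float) - self.center) / self.scale

    @property
    def kappas(self) -> dict[str, float]:
        return {n: a.kappa for n, a in self.algorithms.items()}


@dataclass
class SupportProfile:
    """Kappa-weighted model-averaged support for one clade."""

    support: dict[str, float]
    best_model: str
    per_algorithm: dict[str, dict[str, float]]


def cohen_kappa(confusion) -> float:
    """Cohen's kappa from a confusion matrix.

    ``kappa = (p_o - p_e)/(1 - p_e)`` with the observed agreement ``p_o`` on
    the diagonal and the chance agreement ``p_e`` from the row/column
    marginal products.  Degenerate marginals (``p_e = 1``) yield NaN.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(M < 0):
        raise ValueError("confusion matrix entries must be >= 0")
    total = M.sum()
    if total <= 0:
        raise ValueError("confusion matrix must have positive total")
    p_o = np.trace(M) / total
    p_e = float((M.sum(axis=1) * M.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0:
        warnings.warn("degenerate marginals (p_e = 1); kappa undefined")
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def kappa_weighted_support(
    probabilities: dict[str, np.ndarray | dict[str, float]],
    kappas: dict[str, float],
    classes: list[str] | None = None,
) -> SupportProfile:
    """Combine per-algorithm class probabilities into model-averaged support.

    Weights are the holdout kappas floored at zero (an algorithm worse than
    chance should not invert support); if every kappa is zero, an unweighted
    mean is used with a warning.  Support sums to one; the best model is the
    argmax with ties broken toward the lower model index.
    """
    if not probabilities:
        raise ValueError("no probabilities supplied")
    names = list(probabilities)
    first = probabilities[names[0]]
    if classes is None:
        if not isinstance(first, dict):
            raise ValueError("classes required when probabilities are arrays")
        classes = list(first)
    per_alg = {}
    P = np.zeros((len(names), len(classes)))
    for i, n in enumerate(names):
        p = probabilities[n]
        vec = np.array([p[c] for c in classes]) if isinstance(p, dict) else np.asarray(p, float)
        if not np.isclose(vec.sum(), 1.0, atol=1e-6):
            raise ValueError(f"probabilities of {n!r} do not sum to 1")
        P[i] = vec
        per_alg[n] = dict(zip(classes, vec.tolist()))
    w = np.array([max(kappas[n], 0.0) for n in names])
    if w.sum() == 0:
        warnings.warn("all kappas are zero; falling back to unweighted mean")
        w = np.ones(len(names))
    support = (w[:, None] * P).sum(axis=0) / w.sum()
    support = support / support.sum()
    best = classes[int(np.argmax(support))]
    return SupportProfile(
        support=dict(zip(classes, support.tolist())),
        best_model=best,
        per_algorithm=per_alg,
    )


def _split_features(table: pd.DataFrame) -> pd.DataFrame:
    from evospeed.design import META_COLUMNS

    drop = [c for c in table.columns if c in META_COLUMNS]
    return table.drop(columns=drop)


def train_classifiers(
    table: pd.DataFrame,
    algorithms: tuple[str, ...] = ALGORITHMS,
    folds: int = 10,
    repeats: int = 10,
    test_fraction: float = 1.0 / 3.0,
    seed: int = 0,
    label_column: str = "model",
    importance_repeats: int = 5,
    select_k: int | str | None = "auto",
) -> TrainedEnsemble:
    """Train the classifier ensemble on a labelled summary-statistic table.

    A stratified two-thirds/one-third split separates tuning from evaluation:
    hyperparameters are tuned by ``repeats`` x ``folds``-fold stratified CV on
    the training split, and all reported metrics (confusion, accuracy, kappa,
    sensitivity/specificity, permutation importance) come from the untouched
    test split.  Features are imputed with training-split medians and
    standardized with training-split statistics.

    In the small-sample regime (fewer than 4 training rows per feature) the
    feature set is first reduced by a univariate ANOVA F-score ranking fitted
    on the training split (``select_k="auto"``, keeping ``max(8, n_train//2)``
    features); pass ``select_k=None`` to disable or an integer to fix k.
    Large tables are unaffected.
    """
    y = table[label_column].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = y.value_counts()
    offending = small[small < folds]
    if len(offending):
        raise ValueError(
            f"class(es) with fewer members than folds={folds}: {sorted(offending.index)}"
        )
    X = _split_features(table.drop(columns=[label_column], errors="ignore"))
    X = X.select_dtypes(include=[np.number])
    # drop all-missing features; keep the rest, imputed below
    X = X.loc[:, X.notna().any(axis=0)]
    feature_names = list(X.columns)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    medians = X_tr.median(numeric_only=True)
    X_tr = X_tr.fillna(medians)
    X_te = X_te.fillna(medians)

    if select_k == "auto":
        k = max(8, len(X_tr) // 2) if len(X_tr) < 4 * X_tr.shape[1] else None
    else:
        k = select_k
    if k is not None and k < X_tr.shape[1]:
        from sklearn.feature_selection import f_classif

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            F, _ = f_classif(X_tr.to_numpy(dtype=float), y_tr.to_numpy())
        F = np.nan_to_num(F, nan=0.0)
        keep = np.sort(np.argsort(F)[::-1][:k])
        feature_names = [feature_names[i] for i in keep]
        X_tr = X_tr.iloc[:, keep]
        X_te = X_te.iloc[:, keep]
        medians = medians[feature_names]
    center = X_tr.mean().to_numpy(dtype=float)
    scale = X_tr.std(ddof=0).replace(0.0, 1.0).to_numpy(dtype=float)
    Z_tr = (X_tr.to_numpy(dtype=float) - center) / scale
    Z_te = (X_te.to_numpy(dtype=float) - center) / scale

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    results: dict[str, AlgorithmResult] = {}
    class_index = {c: i for i, c in enumerate(classes)}
    y_tr_arr = y_tr.to_numpy()
    y_te_arr = y_te.to_numpy()
    for name in algorithms:
        est, grid = _estimator_and_grid(name, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if grid:
                search = GridSearchCV(est, grid, cv=cv, n_jobs=None)
                search.fit(Z_tr, y_tr_arr)
                fitted = search.best_estimator_
            else:
                fitted = est.fit(Z_tr, y_tr_arr)
            pred = fitted.predict(Z_te)
        confusion = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_te_arr, pred):
            confusion[class_index[t], class_index[p]] += 1
        accuracy = float(np.trace(confusion) / confusion.sum())
        kappa = cohen_kappa(confusion)
        sens = {}
        spec = {}
        for c, i in class_index.items():
            tp = confusion[i, i]
            fn = confusion[i].sum() - tp
            fp = confusion[:, i].sum() - tp
            tn = confusion.sum() - tp - fn - fp
            sens[c] = float(tp / (tp + fn)) if tp + fn else float("nan")
            spec[c] = float(tn / (tn + fp)) if tn + fp else float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            imp = permutation_importance(
                fitted, Z_te, y_te_arr, n_repeats=importance_repeats, random_state=seed
            )
        raw = np.maximum(imp.importances_mean, 0.0)
        scaled = raw / raw.max() * 100.0 if raw.max() > 0 else raw
        results[name] = AlgorithmResult(
            name=name,
            estimator=fitted,
            confusion=confusion,
            accuracy=accuracy,
            kappa=kappa,
            sensitivity=sens,
            specificity=spec,
            importance=pd.Series(scaled, index=feature_names),
        )
    return TrainedEnsemble(
        algorithms=results,
        feature_names=feature_names,
        classes=classes,
        medians=medians,
        center=center,
        scale=scale,
    )


def variable_importance(ensemble: TrainedEnsemble) -> pd.Series:
    """Kappa-weighted mean of the per-algorithm permutation importances.

    Per-algorithm importances are already scaled to [0, 100]; the weighted
    mean is returned sorted descending.
    """
    names = list(ensemble.algorithms)
    w = np.array([max(ensemble.algorithms[n].kappa, 0.0) for n in names])
    if w.sum() == 0:
        w = np.ones(len(names))
    stack = pd.concat([ensemble.algorithms[n].importance for n in names], axis=1)
    combined = (stack * w).sum(axis=1) / w.sum()
    return combined.sort_values(ascending=False)


def classify_clade(ensemble: TrainedEnsemble, vector) -> SupportProfile:
    """Kappa-weighted support profile for one summary vector.

    ``vector`` may be a :class:`~evospeed.summaries.SummaryVector`, a mapping
    or a Series covering the ensemble's feature list; missing entries are
    imputed with training medians, but a vector missing more than half of the
    features is refused.
    """
    if hasattr(vector, "to_series"):
        series = vector.to_series()
    else:
        series = pd.Series(dict(vector), dtype=float)
    present = series.reindex(ensemble.feature_names).notna().sum()
    if present < 0.5 * len(ensemble.feature_names):
        raise ValueError(
            f"vector covers only {present} of {len(ensemble.feature_names)} features"
        )
    Z = ensemble.preprocess(series.to_frame().T)
    probs = {}
    for name, alg in ensemble.algorithms.items():
        p = alg.estimator.predict_proba(Z)[0]
        order = list(alg.estimator.classes_)
        probs[name] = {c: float(p[order.index(c)]) for c in ensemble.classes}
    return kappa_weighted_support(probs, ensemble.kappas, classes=ensemble.classes)
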