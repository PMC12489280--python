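"""Statistical pipeline: standardization, PCA, classifier bench, Shapley attribution.

The pipeline mirrors the chemometric workflow used on the campaign data:
features are standardized (train statistics only), a 10-component PCA
summarises structure, five classifier families (LR, kNN, Gaussian NB, random
forest, SVM) are tuned by exhaustive grid search under stratified 10-fold
cross-validation scored by accuracy, and the winner is explained with Shapley
values — exactly for linear one-vs-rest decision functions, by a permutation
Monte-Carlo estimate otherwise. The most influential spectroscopy features
are clustered into contiguous emission-wavelength regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, confusion_matrix, precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datamodel import AttributionReport, Dataset, EvaluationReport, parse_feature_name
from .errors import StratificationError, UsageError
from .signature import dataset_xy

FAMILIES = ("LR", "kNN", "NaiveBayes", "RandomForest", "SVM")

#: Default hyperparameter grids; the SVM grid spans the linear C=0.1
#: gamma='scale' optimum reported for the campaign data.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "LR": [{"C": [0.01, 0.1, 1.0, 10.0, 100.0]}],
    "kNN": [{"n_neighbors": [3, 5, 7, 9], "metric": ["euclidean"]}],
    "NaiveBayes": [{"var_smoothing": [1e-9]}],
    "RandomForest": [{"n_estimators": [100, 300, 500]}],
    "SVM": [{"kernel": ["linear", "rbf"], "C": [0.01, 0.1, 1.0, 10.0, 100.0], "gamma": ["scale"]}],
}


def _base_estimator(family: str, seed: Optional[int] = None):
    if family == "LR":
        return LogisticRegression(max_iter=5000)
    if family == "kNN":
        return KNeighborsClassifier()
    if family == "NaiveBayes":
        return GaussianNB()
    if family == "RandomForest":
        return RandomForestClassifier(random_state=seed)
    if family == "SVM":
        return SVC(decision_function_shape="ovr", random_state=seed)
    raise UsageError(f"unknown classifier family {family!r}; expected one of {FAMILIES}")


@dataclass
class ClassifierSpec:
    """A tuned classifier: family, searched grid, winning hyperparameters."""

    family: str
    grid: list[dict]
    best_params: dict
    cv_accuracy: float
    estimator: object = None  # fitted on the full training set

    def __post_init__(self) -> None:
        if not self.grid:
            raise UsageError("hyperparameter grid must be non-empty")


def _as_xy(data, y=None) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(data, Dataset):
        return dataset_xy(data)
    X = pd.DataFrame(data)
    return X, pd.Series(np.asarray(y), index=X.index, name="species")


def stratified_split(
    data: Union[Dataset, pd.DataFrame],
    y: Optional[pd.Series] = None,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """Per-class random split into train and test.

    Each class contributes ``round(train_fraction * n_class)`` loads to the
    training set (round-half-up) and the remainder to the test set. Returns
    (X_train, y_train, X_test, y_test).
    """
    X, y = _as_xy(data, y)
    if not 0.0 < train_fraction <= 1.0:
        raise UsageError("train_fraction must be in (0, 1]")
    if train_fraction == 1.0:
        warnings.warn("train_fraction=1.0 leaves an empty test set", stacklevel=2)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
    train_idx: list = []
    test_idx: list = []
    for cls in sorted(y.unique()):
        members = y.index[y == cls].to_numpy()
        if members.size < 2:
            raise StratificationError(
                f"class {cls!r} has {members.size} load(s); need >= 2 to stratify"
            )
        n_train = int(np.floor(train_fraction * members.size + 0.5))
        n_train = min(n_train, members.size)
        order = rng.permutation(members.size)
        train_idx.extend(members[order[:n_train]])
        test_idx.extend(members[order[n_train:]])
    return X.loc[train_idx], y.loc[train_idx], X.loc[test_idx], y.loc[test_idx]


@dataclass
class Standardizer:
    """Per-feature (mean, sd) fitted on train; zero-sd features map to 0."""

    scaler: StandardScaler

    @property
    def mean(self) -> np.ndarray:
        return self.scaler.mean_

    @property
    def sd(self) -> np.ndarray:
        return self.scaler.scale_

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(self.scaler.transform(X), index=X.index, columns=X.columns)


def standardize(
    train: pd.DataFrame, apply_to: Optional[Iterable[pd.DataFrame]] = None
) -> tuple[pd.DataFrame, list[pd.DataFrame], Standardizer]:
    """Standardize features with train statistics only.

    Returns the transformed train table, the transformed ``apply_to`` tables
    (with train's mean/sd — their own means are generally non-zero after the
    transform), and the fitted parameters.
    """
    scaler = StandardScaler().fit(train)
    st = Standardizer(scaler)
    others = [st.transform(t) for t in (apply_to or [])]
    return st.transform(train), others, st


@dataclass
class PcaResult:
    """PCA of standardized features."""

    scores: pd.DataFrame
    loadings: pd.DataFrame  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    n_components: int


def run_pca(features: pd.DataFrame, n_components: int = 10) -> PcaResult:
    """Standardize then PCA, keeping ``n_components`` components.

    When the data rank is below ``n_components`` the missing components are
    padded with zero loadings and zero variance ratio (with a warning) so the
    result shape is stable.
    """
    Xs, _, _ = standardize(features)
    k = min(n_components, len(features) - 1 if len(features) > 1 else 1, features.shape[1])
    if k < n_components:
        warnings.warn(
            f"data supports only {k} components; padding to {n_components} "
            "with zero-variance components",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xs)
    loadings = pca.components_
    ratios = pca.explained_variance_ratio_
    if k < n_components:
        pad = n_components - k
        scores = np.hstack([scores, np.zeros((scores.shape[0], pad))])
        loadings = np.vstack([loadings, np.zeros((pad, loadings.shape[1]))])
        ratios = np.concatenate([ratios, np.zeros(pad)])
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=features.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=comp_names, columns=features.columns),
        explained_variance_ratio=np.asarray(ratios),
        n_components=n_components,
    )


def grid_search_cv(
    family: str,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    k: int = 10,
    seed: int = 0,
    grid: Optional[list[dict]] = None,
) -> ClassifierSpec:
    """Exhaustive grid search scored by mean stratified-k-fold CV accuracy.

    Ties are broken by first-in-grid order; the winner is refit on the full
    training set. If the smallest class has fewer than ``k`` members, k is
    lowered to that count (with a warning).
    """
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid or all(not g for g in grid):
        raise UsageError("hyperparameter grid must be non-empty")
    min_class = int(y_train.value_counts().min())
    if min_class < 2:
        raise StratificationError("every class needs >= 2 training members for CV")
    if min_class < k:
        warnings.warn(f"lowering cv folds from {k} to smallest class count {min_class}",
                      stacklevel=2)
        k = min_class
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    search = GridSearchCV(
        _base_estimator(family, seed),
        grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(X_train.to_numpy(), y_train.to_numpy())
    return ClassifierSpec(
        family=family,
        grid=grid,
        best_params=dict(search.best_params_),
        cv_accuracy=float(search.best_score_),
        estimator=search.best_estimator_,
    )


def _class_scores(model, X: np.ndarray) -> np.ndarray:
    """Per-class score matrix (n_samples, n_classes) from proba or decision values."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    scores = np.asarray(model.decision_function(X))
    if scores.ndim == 1:  # binary: build two-column scores
        scores = np.column_stack([-scores, scores])
    return scores


def compute_report(
    y_true: Sequence, y_pred: Sequence, scores: Optional[np.ndarray] = None,
    labels: Optional[Sequence[str]] = None,
) -> EvaluationReport:
    """Build an :class:`EvaluationReport` from predictions.

    Per-class recall = TP/(TP+FN), precision = TP/(TP+FP) and
    F1 = 2PR/(P+R) (zero when undefined); accuracy is the diagonal fraction
    of the confusion matrix; ROC-AUC-OVR is the unweighted macro mean over
    classes of the one-vs-rest AUC computed from ``scores`` (None if no
    scores are given).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = tuple(labels) if labels is not None else tuple(sorted(np.unique(y_true)))
    cm = confusion_matrix(y_true, y_pred, labels=list(labels))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(labels), zero_division=0
    )
    auc: Optional[float] = None
    if scores is not None:
        present = np.unique(y_true)
        if present.size < 2:
            raise UsageError("ROC-AUC-OVR is undefined for a single-class test set")
        aucs = []
        for j, cls in enumerate(labels):
            mask = y_true == cls
            if mask.any() and not mask.all():
                aucs.append(roc_auc_score(mask.astype(int), scores[:, j]))
        auc = float(np.mean(aucs))
    return EvaluationReport(
        labels=labels,
        confusion=cm,
        accuracy=float(accuracy_score(y_true, y_pred)),
        recall=recall,
        precision=precision,
        f1=f1,
        roc_auc_ovr=auc,
        n_test=int(y_true.size),
    )


def evaluate(model, X_test: pd.DataFrame, y_test: pd.Series) -> EvaluationReport:
    """Evaluate a fitted classifier on held-out data."""
    if len(y_test) == 0:
        raise UsageError("test set is empty")
    X = np.asarray(X_test)
    y_pred = model.predict(X)
    scores = _class_scores(model, X)
    return compute_report(y_test, y_pred, scores=scores, labels=list(model.classes_))


@dataclass
class BenchResult:
    """One row per classifier family, plus the per-family reports and specs."""

    table: pd.DataFrame
    reports: dict[str, EvaluationReport]
    specs: dict[str, ClassifierSpec]


def bench_all(
    data: Union[Dataset, pd.DataFrame],
    y: Optional[pd.Series] = None,
    seed: int = 0,
    families: Sequence[str] = FAMILIES,
    train_fraction: float = 0.7,
    k: int = 10,
    grids: Optional[dict[str, list[dict]]] = None,
) -> BenchResult:
    """Split, standardize, tune and evaluate every classifier family.

    Reports both the CV accuracy of the winning hyperparameters and the
    held-out test metrics, since a single printed accuracy can refer to
    either.
    """
    X, y = _as_xy(data, y)
    X_tr, y_tr, X_te, y_te = stratified_split(X, y, train_fraction=train_fraction, seed=seed)
    Xs_tr, (Xs_te,), _ = standardize(X_tr, [X_te])
    reports: dict[str, EvaluationReport] = {}
    specs: dict[str, ClassifierSpec] = {}
    rows = []
    for family in families:
        grid = grids.get(family) if grids else None
        spec = grid_search_cv(family, Xs_tr, y_tr, k=k, seed=seed, grid=grid)
        report = evaluate(spec.estimator, Xs_te, y_te)
        reports[family] = report
        specs[family] = spec
        rows.append(
            {
                "family": family,
                "cv_accuracy": spec.cv_accuracy,
                "test_accuracy": report.accuracy,
                "macro_f1": float(np.mean(report.f1)),
                "roc_auc_ovr": report.roc_auc_ovr,
            }
        )
    return BenchResult(table=pd.DataFrame(rows).set_index("family"), reports=reports, specs=specs)


# --- Shapley attribution ----------------------------------------------------


def fit_ovr_linear(spec: ClassifierSpec, X_train: pd.DataFrame, y_train: pd.Series):
    """Refit a tuned linear-kernel model one-vs-rest, exposing per-class weights."""
    params = dict(spec.best_params)
    if spec.family == "SVM":
        if params.get("kernel") != "linear":
            raise UsageError("one-vs-rest linear refit requires kernel='linear'")
        base = SVC(**params)
    elif spec.family == "LR":
        base = LogisticRegression(max_iter=5000, **params)
    else:
        raise UsageError(f"{spec.family} has no linear one-vs-rest form")
    ovr = OneVsRestClassifier(base)
    ovr.fit(np.asarray(X_train), np.asarray(y_train))
    return ovr


def _linear_weights(model) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """(W, b) with W of shape (n_classes, n_features) for linear per-class scorers."""
    if isinstance(model, OneVsRestClassifier):
        try:
            W = np.vstack([est.coef_.ravel() for est in model.estimators_])
            b = np.array([float(np.ravel(est.intercept_)[0]) for est in model.estimators_])
            return W, b
        except AttributeError:
            return None
    coef = getattr(model, "coef_", None)
    if coef is None:
        return None
    coef = np.asarray(coef)
    intercept = np.ravel(np.asarray(getattr(model, "intercept_", np.zeros(coef.shape[0]))))
    n_classes = len(getattr(model, "classes_", []))
    if coef.shape[0] == n_classes:
        return coef, intercept
    if coef.shape[0] == 1 and n_classes == 2:  # binary linear model
        return np.vstack([-coef[0], coef[0]]), np.array([-intercept[0], intercept[0]])
    return None  # e.g. one-vs-one SVC coefficients: not per-class linear


def shapley_attribution(
    model,
    X: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 256,
    seed: int = 0,
    top_k: int = 20,
) -> AttributionReport:
    """Per-sample, per-feature, per-class Shapley values of the class scores.

    For models with a per-class linear decision function the interventional
    Shapley value is exact and closed-form:
    ``phi[i, j, c] = W[c, j] * (x[i, j] - mean(background[:, j]))``, which
    satisfies local accuracy ``sum_j phi = f_c(x) - f_c(background mean)``
    on every sample. Other models use a permutation Monte-Carlo estimate
    averaged over the full background set.

    Aggregates: ``mean_abs`` (feature x class, as in per-class importance
    bars), ``signed_mean`` (per feature, direction-aware), and the ``top_k``
    features ranked by global mean absolute value.
    """
    if not hasattr(model, "classes_") and _linear_weights(model) is None:
        raise UsageError("shapley_attribution requires a fitted classifier")
    feature_names = tuple(X.columns)
    Xv = np.asarray(X, dtype=np.float64)
    Bv = np.asarray(background, dtype=np.float64)
    lin = _linear_weights(model)
    if lin is not None:
        W, _ = lin
        mu = Bv.mean(axis=0)
        phi = (Xv[:, :, None] - mu[:, None]) * W.T[None, :, :]
        method = "linear-exact"
    else:
        phi = _mc_shapley(model, Xv, Bv, n_permutations, seed)
        method = "permutation-mc"
    class_names = tuple(str(c) for c in getattr(model, "classes_", range(phi.shape[2])))
    mean_abs = np.abs(phi).mean(axis=0)  # (n_features, n_classes)
    signed_mean = phi.mean(axis=(0, 2))
    global_imp = np.abs(phi).mean(axis=(0, 2))
    order = np.argsort(-global_imp, kind="stable")[:top_k]
    return AttributionReport(
        feature_names=feature_names,
        class_names=class_names,
        phi=phi,
        mean_abs=mean_abs,
        signed_mean=signed_mean,
        top20=tuple(feature_names[i] for i in order),
        method=method,
    )


def _mc_shapley(model, X: np.ndarray, B: np.ndarray, n_permutations: int, seed: int) -> np.ndarray:
    """Permutation Monte-Carlo Shapley estimate averaged over the background set."""
    score = lambda Z: _class_scores(model, Z)
    n, p = X.shape
    n_classes = score(X[:1]).shape[1]
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
    phi = np.zeros((n, p, n_classes))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        for i in range(n):
            Z = B.copy()
            prev = score(Z).mean(axis=0)
            for j in perm:
                Z[:, j] = X[i, j]
                cur = score(Z).mean(axis=0)
                phi[i, j] += cur - prev
                prev = cur
    return phi / n_permutations


def cluster_regions(
    top_features: Sequence[str], gap_nm: float = 40.0
) -> list[tuple[int, int]]:
    """Cluster spectroscopy feature names into contiguous emission regions.

    Emission wavelengths are sorted; a gap larger than ``gap_nm`` opens a new
    region; each region is reported as (min_nm, max_nm). Analyser names have
    no emission axis and are rejected.
    """
    wavelengths = []
    for name in top_features:
        modality, _, detail = parse_feature_name(name)
        if modality != "spectroscopy":
            raise UsageError(
                f"cluster_regions needs spectroscopy names (Lk_nm); got {name!r}"
            )
        wavelengths.append(int(detail))
    if not wavelengths:
        return []
    wls = sorted(set(wavelengths))
    regions = []
    start = prev = wls[0]
    for wl in wls[1:]:
        if wl - prev > gap_nm:
            regions.append((start, prev))
            start = wl
        prev = wl
    regions.append((start, prev))
    return regions
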