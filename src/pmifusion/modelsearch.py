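"""Per-organ model search: 4 feature selectors x 5 classifiers.

Each organ's standardized feature matrix feeds a grid of 20 pipelines —
every combination of a feature-selection method (LASSO, RFE, SFS, SBS)
with a multi-class classifier (LR, SVM, RF, GBDT, MLPC). Selection and
fitting use training data only; each fitted pipeline is scored on the
internal (held-out 30%) and external (independent cohort) matrices with
accuracy, macro precision, macro recall and macro one-vs-rest AUC.

Selector tuning is 5-fold stratified cross-validated accuracy throughout
(LASSO penalty strength, RFE subset size, SFS/SBS greedy steps). Fold
counts adapt downwards when a class has fewer members than folds, so the
search also runs on miniature cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import accuracy_score, precision_score, recall_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .peaks import FeatureMatrix

logger = logging.getLogger(__name__)

SELECTORS = ("LASSO", "RFE", "SBS", "SFS")
CLASSIFIERS = ("LR", "SVM", "RF", "GBDT", "MLPC")
METRICS = ("accuracy", "precision", "recall", "auc")


@dataclass(frozen=True)
class PipelineSpec:
    """One (selector, classifier) pipeline for one organ."""

    organ: str
    selector: str
    classifier: str
    seed: int = 0
    hyperparameters: tuple = ()

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def name(self) -> str:
        return f"{self.selector}+{self.classifier}"


@dataclass
class EvaluationRecord:
    """Validation metrics of one fitted pipeline."""

    spec: PipelineSpec
    selected_features: list[int]
    internal: dict[str, float]
    external: dict[str, float]
    failed: bool = False
    error: str = ""

    def metric(self, cohort: str, name: str) -> float:
        return (self.internal if cohort == "internal" else self.external)[name]


def _cv_splitter(y, folds: int, seed: int):
    """Stratified k-fold, degrading gracefully on tiny class counts."""
    counts = pd.Series(y).value_counts()
    k = min(folds, int(counts.min()))
    if k >= 2:
        return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return KFold(n_splits=min(2, len(y)), shuffle=True, random_state=seed)


def _greedy_scorer(seed: int):
    """Estimator scoring candidate feature subsets inside SFS/SBS."""
    return LogisticRegression(max_iter=1000, random_state=seed)


def _sequential_select(
    X: np.ndarray, y: np.ndarray, seed: int, folds: int, forward: bool
) -> list[int]:
    """Greedy forward/backward feature search on CV accuracy.

    Adds (removes) the single feature whose inclusion (exclusion) most
    improves 5-fold CV accuracy; stops when no candidate step strictly
    improves the score. Backward search keeps at least one feature.
    """
    p = X.shape[1]
    cv = _cv_splitter(y, folds, seed)
    est = _greedy_scorer(seed)

    def score(cols: list[int]) -> float:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            return float(np.mean(cross_val_score(clone(est), X[:, cols], y, cv=cv)))

    current: list[int] = [] if forward else list(range(p))
    current_score = -np.inf if forward else score(current)
    while True:
        candidates = []
        if forward:
            for j in range(p):
                if j in current:
                    continue
                candidates.append((score(current + [j]), j))
        else:
            if len(current) <= 1:
                break
            for j in current:
                candidates.append((score([c for c in current if c != j]), j))
        if not candidates:
            break
        best_score, best_j = max(candidates, key=lambda c: (c[0], -c[1]))
        if best_score <= current_score:
            break
        current_score = best_score
        if forward:
            current.append(best_j)
        else:
            current.remove(best_j)
    if forward and not current:  # first step never improved over -inf guard
        current = [max(range(p), key=lambda j: score([j]))]
    return sorted(current)


def select_features(
    method: str, train: FeatureMatrix, seed: int = 0, folds: int = 5
) -> list[int]:
    """Select a nonempty fragment subset on training data only.

    * ``LASSO`` — fragments with any nonzero coefficient in an L1
      multinomial logistic model, penalty tuned by CV accuracy;
    * ``RFE`` — recursive elimination (step 1) on random-forest
      importances, subset size by CV accuracy;
    * ``SFS`` / ``SBS`` — greedy forward / backward search on CV accuracy
      with a no-improvement stop.
    """
    if method not in SELECTORS:
        raise ValueError(f"unknown selector {method!r}")
    X = train.X.to_numpy(dtype=float)
    y = train.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("feature selection needs >= 2 classes")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("all features have zero variance")
    cols = list(train.X.columns)
    cv = _cv_splitter(y, folds, seed)

    if method == "LASSO":
        model = LogisticRegressionCV(
            penalty="l1",
            solver="saga",
            Cs=np.logspace(-2, 2, 10),
            cv=cv,
            scoring="accuracy",
            max_iter=5000,
            random_state=seed,
        )
        import warnings as _warnings

        # saga on heavily penalized folds stalls before max_iter; the CV
        # score still identifies the useful penalty range
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            model.fit(X, y)
        mask = np.any(np.abs(model.coef_) > 1e-10, axis=0)
        if not mask.any():
            logger.warning("LASSO selected zero features; falling back to all")
            mask[:] = True
        idx = np.flatnonzero(mask)
    elif method == "RFE":
        selector = RFECV(
            RandomForestClassifier(n_estimators=100, random_state=seed),
            step=1,
            cv=cv,
            scoring="accuracy",
            min_features_to_select=1,
        )
        selector.fit(X, y)
        idx = np.flatnonzero(selector.support_)
    else:
        idx = _sequential_select(X, y, seed, folds, forward=(method == "SFS"))
    return [cols[j] for j in idx]


def make_classifier(algo: str, seed: int, n_train: int | None = None):
    """Instantiate a seeded probabilistic multi-class classifier."""
    if algo == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if algo == "SVM":
        # probability calibration required downstream by soft voting
        return SVC(kernel="rbf", probability=True, random_state=seed)
    if algo == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algo == "GBDT":
        return GradientBoostingClassifier(
            n_estimators=100, max_depth=3, random_state=seed
        )
    if algo == "MLPC":
        early = n_train is None or n_train >= 20
        return MLPClassifier(
            hidden_layer_sizes=(100,),
            early_stopping=early,
            max_iter=500,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {algo!r}")


def train_classifier(
    algo: str,
    train: FeatureMatrix,
    features: list[int],
    seed: int = 0,
    expected_classes=None,
):
    """Fit one classifier on the selected fragment columns."""
    X = train.X[features].to_numpy(dtype=float)
    y = train.y.to_numpy()
    if expected_classes is not None:
        missing = set(expected_classes) - set(y)
        if missing:
            raise ValueError(f"classes absent from training data: {sorted(missing)}")
    model = make_classifier(algo, seed, n_train=len(y))
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # MLP convergence chatter on tiny data
        model.fit(X, y)
    return model


def _macro_ovr_auc(y_true: np.ndarray, proba: np.ndarray, classes: np.ndarray) -> float:
    """Macro one-vs-rest AUC over the classes present in ``y_true``."""
    aucs = []
    for k, cls in enumerate(classes):
        pos = y_true == cls
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos, proba[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


def evaluate(model, matrix: FeatureMatrix, features: list[int]) -> dict[str, float]:
    """Accuracy, macro precision/recall and macro OvR AUC on one cohort."""
    X = matrix.X[features].to_numpy(dtype=float)
    y = matrix.y.to_numpy()
    pred = model.predict(X)
    out = {
        "accuracy": float(accuracy_score(y, pred)),
        "precision": float(precision_score(y, pred, average="macro", zero_division=0)),
        "recall": float(recall_score(y, pred, average="macro", zero_division=0)),
    }
    try:
        proba = model.predict_proba(X)
        out["auc"] = _macro_ovr_auc(y, proba, model.classes_)
    except AttributeError:
        out["auc"] = float("nan")
    return out


def evaluate_predictions(
    y_true: np.ndarray, pred: np.ndarray, proba: np.ndarray | None, classes
) -> dict[str, float]:
    """Metric suite from precomputed predictions (used by ensembles)."""
    out = {
        "accuracy": float(accuracy_score(y_true, pred)),
        "precision": float(precision_score(y_true, pred, average="macro", zero_division=0)),
        "recall": float(recall_score(y_true, pred, average="macro", zero_division=0)),
    }
    out["auc"] = (
        _macro_ovr_auc(np.asarray(y_true), proba, np.asarray(classes))
        if proba is not None
        else float("nan")
    )
    return out


@dataclass
class OrganData:
    """The three aligned cohorts of one organ, standardized."""

    organ: str
    train: FeatureMatrix
    internal: FeatureMatrix
    external: FeatureMatrix


def run_cross_combination(
    data: OrganData, seed: int = 0, folds: int = 5
) -> list[EvaluationRecord]:
    """Evaluate all 20 (selector, classifier) pipelines for one organ.

    Feature selection runs once per selector (it does not depend on the
    downstream classifier) on training data only; each classifier is then
    fit on the selected columns and scored on the internal and external
    cohorts. A failing pipeline is recorded as failed and does not abort
    the rest.
    """
    records: list[EvaluationRecord] = []
    selections: dict[str, list[int]] = {}
    for selector in SELECTORS:
        try:
            selections[selector] = select_features(
                selector, data.train, seed=seed, folds=folds
            )
        except Exception as exc:  # noqa: BLE001 — record-and-continue policy
            logger.warning("selector %s failed for %s: %s", selector, data.organ, exc)
            selections[selector] = []
            for classifier in CLASSIFIERS:
                records.append(
                    EvaluationRecord(
                        spec=PipelineSpec(data.organ, selector, classifier, seed),
                        selected_features=[],
                        internal={},
                        external={},
                        failed=True,
                        error=str(exc),
                    )
                )
    for selector in SELECTORS:
        features = selections[selector]
        if not features:
            continue
        for classifier in CLASSIFIERS:
            spec = PipelineSpec(data.organ, selector, classifier, seed)
            try:
                model = train_classifier(classifier, data.train, features, seed=seed)
                records.append(
                    EvaluationRecord(
                        spec=spec,
                        selected_features=list(features),
                        internal=evaluate(model, data.internal, features),
                        external=evaluate(model, data.external, features),
                    )
                )
            except Exception as exc:  # noqa: BLE001
                logger.warning("pipeline %s failed for %s: %s", spec.name, data.organ, exc)
                records.append(
                    EvaluationRecord(
                        spec=spec,
                        selected_features=list(features),
                        internal={},
                        external={},
                        failed=True,
                        error=str(exc),
                    )
                )
    return records


def records_to_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Tidy (organ, selector, classifier, cohort, metric, value) table."""
    rows = []
    for rec in records:
        for cohort, metrics in (("internal", rec.internal), ("external", rec.external)):
            for name in METRICS:
                rows.append(
                    {
                        "organ": rec.spec.organ,
                        "selector": rec.spec.selector,
                        "classifier": rec.spec.classifier,
                        "cohort": cohort,
                        "metric": name,
                        "value": metrics.get(name, float("nan")),
                    }
                )
    return pd.DataFrame(rows)
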