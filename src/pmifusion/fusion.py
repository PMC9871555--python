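"""Ensembles: soft voting, soft-weighted voting, stacking, and pruning.

Single-organ ensembles combine the five classifiers trained on one
organ's selected fragments; multi-organ fusion runs each organ's best
pipeline in parallel on that organ's features and fuses the four
class-probability vectors per rat into one PMI call. Greedy backward
pruning then removes ensemble members one at a time while removal
strictly improves an internal-validation score.

All combiners operate on member class-probability matrices over a shared
ordered class set (PMI days ascending); argmax ties resolve toward the
earlier PMI day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .modelsearch import evaluate_predictions, make_classifier
from .peaks import FeatureMatrix

logger = logging.getLogger(__name__)

COMBINERS = ("stacking", "soft_voting", "soft_weighted_voting")


def _check_members(probas: Sequence[np.ndarray]) -> tuple[int, int]:
    if not probas:
        raise ValueError("no member probability matrices")
    n, k = probas[0].shape
    for p in probas[1:]:
        if p.shape != (n, k):
            raise ValueError(
                f"member probability shapes differ: {p.shape} vs {(n, k)}"
            )
    return n, k


def _argmax_earliest(fused: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Argmax with ties resolved toward the earlier PMI class.

    ``classes`` must be ascending; ``np.argmax`` returns the first maximal
    index, i.e. the earliest day.
    """
    mx = fused.max(axis=1, keepdims=True)
    near = fused >= mx - 1e-9  # float-tolerant tie detection
    idx = near.argmax(axis=1)  # first maximal column = earliest day
    ties = near.sum(axis=1) > 1
    if ties.any():
        logger.info("%d fused predictions tied; resolved to earlier PMI", int(ties.sum()))
    return np.asarray(classes)[idx]


def soft_vote(
    probas: Sequence[np.ndarray], classes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean of member probabilities; prediction by argmax."""
    _check_members(probas)
    fused = np.mean(probas, axis=0)
    return _argmax_earliest(fused, classes), fused


def soft_weighted_vote(
    probas: Sequence[np.ndarray], weights: Sequence[float], classes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted mean of member probabilities (weights normalized to 1)."""
    _check_members(probas)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(probas):
        raise ValueError("one weight per member required")
    if (w < 0).any():
        raise ValueError("weights must be >= 0")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    w = w / w.sum()
    fused = np.tensordot(w, np.stack(probas), axes=1)
    return _argmax_earliest(fused, classes), fused


@dataclass
class FittedPipeline:
    """A feature subset plus a fitted classifier for one view (organ)."""

    name: str
    algo: str
    features: list[int]
    seed: int
    model: object = None

    def factory(self, n_train: int):
        return make_classifier(self.algo, self.seed, n_train=n_train)

    def fit(self, matrix: FeatureMatrix) -> "FittedPipeline":
        import warnings as _w

        X = matrix.X[self.features].to_numpy(dtype=float)
        y = matrix.y.to_numpy()
        self.model = self.factory(len(y))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            self.model.fit(X, y)
        return self

    def predict_proba(
        self, matrix: FeatureMatrix, classes: np.ndarray
    ) -> np.ndarray:
        X = matrix.X[self.features].to_numpy(dtype=float)
        raw = self.model.predict_proba(X)
        return _align_proba(raw, self.model.classes_, classes)


def _align_proba(
    raw: np.ndarray, model_classes: np.ndarray, classes: np.ndarray
) -> np.ndarray:
    """Expand a probability matrix onto the full ordered class set."""
    if np.array_equal(model_classes, classes):
        return raw
    out = np.zeros((raw.shape[0], len(classes)))
    pos = {c: i for i, c in enumerate(classes)}
    for j, c in enumerate(model_classes):
        out[:, pos[c]] = raw[:, j]
    return out


class StackingEnsemble:
    """Multinomial-logistic meta-learner over out-of-fold member probabilities.

    Members may see different feature matrices (multi-view: one per
    organ) but must share the sample axis. Meta-features are each
    member's out-of-fold class probabilities on the training data,
    concatenated; members are refit on the full training data afterwards.
    """

    def __init__(self, pipelines: list[FittedPipeline], folds: int = 5, seed: int = 0):
        if len(pipelines) < 2:
            raise ValueError("stacking needs >= 2 members")
        if folds < 2:
            raise ValueError("stacking needs >= 2 folds")
        self.pipelines = pipelines
        self.folds = folds
        self.seed = seed
        self.meta = None
        self.classes_: np.ndarray | None = None

    def fit(self, matrices: list[FeatureMatrix]) -> "StackingEnsemble":
        import warnings as _w

        y = matrices[0].y.to_numpy()
        for m in matrices[1:]:
            if not np.array_equal(m.y.to_numpy(), y):
                raise ValueError("member training matrices disagree on labels")
        self.classes_ = np.unique(y)
        min_count = int(pd.Series(y).value_counts().min())
        k = min(self.folds, min_count)
        if k < 2:
            raise ValueError(
                "stratification error: a class has fewer than 2 training "
                "samples, out-of-fold meta-features are undefined"
            )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.seed)
        n = len(y)
        oof = np.zeros((n, len(self.pipelines) * len(self.classes_)))
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            for tr, te in skf.split(np.zeros(n), y):
                for i, (pipe, mat) in enumerate(zip(self.pipelines, matrices)):
                    Xf = mat.X[pipe.features].to_numpy(dtype=float)
                    est = pipe.factory(len(tr))
                    est.fit(Xf[tr], y[tr])
                    block = _align_proba(
                        est.predict_proba(Xf[te]), est.classes_, self.classes_
                    )
                    oof[np.ix_(te, range(i * len(self.classes_), (i + 1) * len(self.classes_)))] = block
            self.meta = LogisticRegression(max_iter=2000, random_state=self.seed)
            self.meta.fit(oof, y)
            for pipe, mat in zip(self.pipelines, matrices):
                pipe.fit(mat)
        self._oof = oof
        return self

    def predict_proba(self, matrices: list[FeatureMatrix]) -> np.ndarray:
        blocks = [
            pipe.predict_proba(mat, self.classes_)
            for pipe, mat in zip(self.pipelines, matrices)
        ]
        meta_X = np.hstack(blocks)
        return _align_proba(
            self.meta.predict_proba(meta_X), self.meta.classes_, self.classes_
        )

    def predict(self, matrices: list[FeatureMatrix]) -> np.ndarray:
        return _argmax_earliest(self.predict_proba(matrices), self.classes_)


def fit_stacking(
    pipelines: list[FittedPipeline],
    matrices: list[FeatureMatrix],
    folds: int = 5,
    seed: int = 0,
) -> StackingEnsemble:
    """Convenience wrapper: build and fit a :class:`StackingEnsemble`."""
    return StackingEnsemble(pipelines, folds=folds, seed=seed).fit(matrices)


def align_by_rat(matrices: dict[str, FeatureMatrix]) -> tuple[list, pd.Series]:
    """Order every organ matrix by rat and verify full organ coverage.

    Returns the sorted rat ids and the per-rat PMI labels; raises when any
    rat misses an organ sample (no silent imputation).
    """
    rat_sets = {
        organ: set(m.meta["rat_id"]) for organ, m in matrices.items()
    }
    all_rats = sorted(set.union(*rat_sets.values()))
    missing = {
        organ: sorted(set(all_rats) - rats)
        for organ, rats in rat_sets.items()
        if set(all_rats) - rats
    }
    if missing:
        raise ValueError(f"rats missing organ samples: {missing}")
    first = next(iter(matrices.values()))
    labels = (
        first.meta.assign(pmi_day=first.y)
        .set_index("rat_id")["pmi_day"]
        .loc[all_rats]
    )
    return all_rats, labels


def reindex_by_rat(matrix: FeatureMatrix, rat_order: list) -> FeatureMatrix:
    """Return the matrix with rows ordered by the given rat ids."""
    by_rat = matrix.meta.reset_index().set_index("rat_id")
    sample_order = by_rat.loc[rat_order, "sample_id"].tolist()
    return FeatureMatrix(
        matrix.X.loc[sample_order],
        matrix.y.loc[sample_order],
        matrix.meta.loc[sample_order],
        matrix.organ,
    )


@dataclass
class FusionSpec:
    """A fused multi-member model and its (possibly pruned) active set."""

    members: list[str]
    combiner: str
    weights: dict[str, float] | None = None
    active_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")
        if not self.active_members:
            self.active_members = list(self.members)


def fuse_organs(
    pipelines: dict[str, FittedPipeline],
    matrices: dict[str, FeatureMatrix],
    combiner: str,
    classes: np.ndarray,
    weights: dict[str, float] | None = None,
    stacker: StackingEnsemble | None = None,
    members: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Fuse per-organ pipeline probabilities into one prediction per rat.

    Returns ``(predictions, fused probabilities, rat order)``. For
    stacking a fitted :class:`StackingEnsemble` over the same member order
    must be supplied.
    """
    members = list(members or pipelines.keys())
    rats, _ = align_by_rat({o: matrices[o] for o in members})
    aligned = [reindex_by_rat(matrices[o], rats) for o in members]
    if combiner == "stacking":
        if stacker is None:
            raise ValueError("stacking requires a fitted StackingEnsemble")
        fused = stacker.predict_proba(aligned)
        return _argmax_earliest(fused, stacker.classes_), fused, rats
    probas = [
        pipelines[o].predict_proba(mat, classes) for o, mat in zip(members, aligned)
    ]
    if combiner == "soft_voting":
        pred, fused = soft_vote(probas, classes)
    elif combiner == "soft_weighted_voting":
        if weights is None:
            raise ValueError("soft_weighted_voting requires member weights")
        pred, fused = soft_weighted_vote(
            probas, [weights[o] for o in members], classes
        )
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return pred, fused, rats


def prune_ensemble(
    spec: FusionSpec,
    evaluate: Callable[[list[str]], float],
    member_quality: dict[str, float] | None = None,
) -> tuple[FusionSpec, list[dict]]:
    """Greedy backward elimination on an internal-validation score.

    At each step every active member's removal is scored; the removal with
    the largest strictly positive improvement is applied (ties broken by
    removing the member with the lowest individual quality, then by name).
    Stops when no removal strictly improves the score. Returns the pruned
    spec and the score trajectory.
    """
    active = list(spec.active_members)
    score = evaluate(active)
    trajectory = [{"step": 0, "removed": None, "score": score}]
    step = 0
    while len(active) > 1:
        candidates = []
        for member in active:
            rest = [m for m in active if m != member]
            candidates.append((evaluate(rest), member))
        best_score = max(c[0] for c in candidates)
        if best_score <= score:
            break
        tied = [m for s, m in candidates if s == best_score]
        if len(tied) > 1 and member_quality:
            tied.sort(key=lambda m: (member_quality.get(m, np.inf), m))
        else:
            tied.sort()
        removed = tied[0]
        active.remove(removed)
        score = best_score
        step += 1
        trajectory.append({"step": step, "removed": removed, "score": score})
    pruned = FusionSpec(
        members=list(spec.members),
        combiner=spec.combiner,
        weights=spec.weights,
        active_members=active,
    )
    return pruned, trajectory
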