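"""Rank-sum model selection over the 8 validation metrics.

Candidate models are compared column-by-column on accuracy, precision,
recall and AUC of both internal and external validation. Within each of
the 8 columns the best model scores M (the number of models), the worst
1, and ties share the average of their positions — the convention that
yields half-integer totals. A model's total score is the sum over the 8
columns; the model with the highest total is selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .modelsearch import METRICS, EvaluationRecord

logger = logging.getLogger(__name__)

METRIC_COLUMNS = tuple(
    f"{cohort}_{metric}" for cohort in ("internal", "external") for metric in METRICS
)


@dataclass
class RankTable:
    """Per-metric rank scores and totals for a set of candidate models."""

    models: list[str]
    metrics: pd.DataFrame  # model x 8 metric columns (raw values)
    scores: pd.DataFrame  # model x 8 metric columns (rank scores)
    totals: pd.Series  # model -> total score

    def __len__(self) -> int:
        return len(self.models)


def rank_models(records: list[EvaluationRecord]) -> RankTable:
    """Score models per metric column (best = M, ties averaged) and sum.

    All 8 metrics must be present on every record; larger is better for
    every metric.
    """
    if not records:
        raise ValueError("no records to rank")
    rows = {}
    for rec in records:
        values = {}
        for col in METRIC_COLUMNS:
            cohort, metric = col.split("_", 1)
            source = rec.internal if cohort == "internal" else rec.external
            if metric not in source or not np.isfinite(source[metric]):
                raise ValueError(
                    f"record {rec.spec.name} ({rec.spec.organ}) is missing "
                    f"metric {col}"
                )
            values[col] = source[metric]
        rows[rec.spec.name] = values
    metrics = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_COLUMNS)]
    # rankdata averages ties and gives 1 to the smallest value, so the best
    # of M models receives M directly
    scores = metrics.apply(lambda col: rankdata(col.to_numpy()), axis=0)
    totals = scores.sum(axis=1)
    return RankTable(
        models=list(metrics.index), metrics=metrics, scores=scores, totals=totals
    )


def select_best(table: RankTable) -> str:
    """Model with the maximum total score.

    Ties are broken by higher external accuracy, then lexicographically
    smallest model name (logged when exercised).
    """
    if not table.models:
        raise ValueError("empty rank table")
    best_total = table.totals.max()
    tied = table.totals[table.totals == best_total].index.tolist()
    if len(tied) > 1:
        ext_acc = table.metrics.loc[tied, "external_accuracy"]
        best_acc = ext_acc.max()
        tied = sorted(ext_acc[ext_acc == best_acc].index)
        logger.info(
            "rank-sum tie at %.1f broken by external accuracy -> %s",
            best_total,
            tied[0],
        )
    return tied[0]
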