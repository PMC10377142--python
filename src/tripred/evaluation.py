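"""Ranking metrics: rank-based AUC with ROC export, and NDCG@n.

AUC is computed in the Mann-Whitney formulation — the probability that
a uniformly chosen positive outscores a uniformly chosen negative, with
ties counting one half.  NDCG@n discounts binary relevance by
1 / log2(rank + 1) and normalizes by the ideal ordering's gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)


def auc(labels, scores) -> float:
    """Rank-based AUC; ties count 1/2.  Both classes must be present."""
    y = np.asarray(labels, float).ravel()
    s = np.asarray(scores, float).ravel()
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties with the 1/2 convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(labels, scores) -> np.ndarray:
    """(fpr, tpr) pairs from (0, 0) to (1, 1), both coordinates non-decreasing."""
    fpr, tpr, _ = roc_curve(np.asarray(labels).ravel(), np.asarray(scores).ravel())
    return np.column_stack([fpr, tpr])


def dcg(rel, n: int) -> float:
    """Discounted cumulative gain of the top-n relevance list."""
    rel = np.asarray(rel, float).ravel()[:n]
    if rel.size == 0:
        return 0.0
    return float(np.sum(rel / np.log2(np.arange(2, rel.size + 2))))


def ndcg_at_n(rel, n: int) -> float:
    """NDCG@n of a relevance list already in score-rank order.

    Returns 0 when the list has no relevant item (IDCG = 0).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rel = np.asarray(rel, float).ravel()
    ideal = np.sort(rel)[::-1]
    idcg = dcg(ideal, n)
    if idcg == 0:
        return 0.0
    return dcg(rel, n) / idcg


def ranked_relevance(labels, scores) -> np.ndarray:
    """Relevance list sorted by descending score; ties broken by the
    stable original order."""
    s = np.asarray(scores, float).ravel()
    order = np.argsort(-s, kind="stable")
    return np.asarray(labels).ravel()[order]


@dataclass
class RankingMetrics:
    """AUC, NDCG@n map, and ROC curve points for one evaluation."""

    auc: float
    ndcg_at: dict[int, float]
    roc: np.ndarray = field(repr=False)


def evaluate_scores(
    labels,
    scores,
    group_ids=None,
    n_list=(1, 3, 5, 10),
    grouping="per-entity",
) -> RankingMetrics:
    """AUC over the pooled list; NDCG@n either over the pooled list
    (``grouping='global'``) or averaged over per-entity candidate lists
    with at least one positive (default, matching cold-start ranking
    per new drug / new disease)."""
    labels = np.asarray(labels, float).ravel()
    scores = np.asarray(scores, float).ravel()
    a = auc(labels, scores)
    roc = roc_points(labels, scores)

    ndcg: dict[int, float] = {}
    if grouping == "global" or group_ids is None:
        rel = ranked_relevance(labels, scores)
        for n in n_list:
            ndcg[n] = ndcg_at_n(rel, n)
    elif grouping == "per-entity":
        group_ids = np.asarray(group_ids).ravel()
        per_entity: dict[int, list[float]] = {n: [] for n in n_list}
        skipped = 0
        for g in np.unique(group_ids):
            mask = group_ids == g
            if labels[mask].sum() == 0:
                skipped += 1
                continue
            rel = ranked_relevance(labels[mask], scores[mask])
            for n in n_list:
                per_entity[n].append(ndcg_at_n(rel, n))
        if skipped:
            logger.info("NDCG: skipped %d entities with no positives", skipped)
        for n in n_list:
            vals = per_entity[n]
            ndcg[n] = float(np.mean(vals)) if vals else 0.0
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return RankingMetrics(auc=a, ndcg_at=ndcg, roc=roc)


def evaluate_fold(
    model,
    X_test,
    y_test,
    side_axis: int,
    n_list=(1, 3, 5, 10),
    grouping="per-entity",
) -> RankingMetrics:
    """Score a fold's test triples with a fitted model and compute
    ranking metrics, grouping NDCG by the cold-start-side entity."""
    X_test = np.asarray(X_test)
    scores = model.predict_proba(X_test)[:, 1]
    return evaluate_scores(
        y_test, scores, group_ids=X_test[:, side_axis], n_list=n_list, grouping=grouping
    )
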