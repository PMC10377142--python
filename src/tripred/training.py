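"""Evaluation protocol: negative sampling, entity-wise cold-start folds,
cross-validated training, and hyperparameter sweeps.

The tensor is extremely sparse, so training labels are formed by keeping
every positive cell and drawing ``alpha`` unlinked cells per positive
(uniformly, without replacement) as negatives — the 1:alpha implicit-
feedback scheme with alpha = 10 by default.

Cross-validation is entity-wise on one side (drug or disease): each
sided entity is assigned to exactly one of 10 folds, all of its labeled
triples follow it, fold t is tested with fold (t+1) mod 10 held out for
early-stopping validation and the remaining folds used for training.
A test entity therefore contributes zero training triples — the
cold-start ("new drug" / "new disease") setting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .core_data import TripleTensor
from .evaluation import RankingMetrics, evaluate_fold, evaluate_scores
from .models import ROLE_AXES, MODEL_REGISTRY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingConfig:
    """Protocol hyperparameters (defaults follow the evaluation setup:
    alpha = 10 negatives per positive, 10 entity-wise folds)."""

    neg_ratio: int = 10
    n_folds: int = 10
    side: str = "drug"
    rank: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.neg_ratio < 1 or int(self.neg_ratio) != self.neg_ratio:
            raise ValueError("neg_ratio must be a positive integer")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.side not in ("drug", "disease"):
            raise ValueError("side must be 'drug' or 'disease'")


@dataclass
class LabeledTripleSet:
    """Labeled (i, j, k) triples: all positives plus sampled negatives."""

    triples: np.ndarray  # (n, 3) int
    labels: np.ndarray   # (n,) in {0, 1}

    def __post_init__(self):
        if self.triples.shape[0] != self.labels.shape[0]:
            raise ValueError("triples / labels length mismatch")

    def __len__(self):
        return len(self.labels)


def sample_negatives(tensor: TripleTensor, alpha: int, seed: int) -> LabeledTripleSet:
    """All positives plus alpha x |positives| distinct non-positive cells
    sampled uniformly without replacement."""
    pos = tensor.positives_array()
    n_pos = len(pos)
    n_neg = alpha * n_pos
    n_free = tensor.n_cells - n_pos
    if n_free < n_neg:
        raise ValueError(
            f"cannot draw {n_neg} negatives from {n_free} unlinked cells"
        )
    rng = np.random.default_rng(seed)
    I, J, K = tensor.shape
    pos_flat = np.ravel_multi_index((pos[:, 0], pos[:, 1], pos[:, 2]), (I, J, K)) if n_pos else np.array([], dtype=np.int64)

    if tensor.n_cells <= 5_000_000:
        free = np.setdiff1d(np.arange(tensor.n_cells), pos_flat, assume_unique=False)
        neg_flat = rng.choice(free, size=n_neg, replace=False)
    else:  # rejection sampling for very large tensors
        taken = set(pos_flat.tolist())
        out = []
        while len(out) < n_neg:
            cand = rng.integers(0, tensor.n_cells, size=2 * (n_neg - len(out)))
            for c in cand:
                if c not in taken:
                    taken.add(c)
                    out.append(c)
                    if len(out) == n_neg:
                        break
        neg_flat = np.array(out, dtype=np.int64)

    neg = np.column_stack(np.unravel_index(neg_flat, (I, J, K))).astype(np.int64)
    triples = np.vstack([pos, neg]) if n_pos else neg
    labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
    return LabeledTripleSet(triples, labels)


@dataclass
class FoldAssignment:
    """Entity-wise fold partition on one side with derived triple splits."""

    side: str
    n_folds: int
    entity_fold: np.ndarray          # (n_sided_entities,) int fold ids
    data: LabeledTripleSet = field(repr=False)

    @property
    def side_axis(self) -> int:
        return ROLE_AXES[self.side]

    def triple_folds(self) -> np.ndarray:
        """Fold id of every labeled triple (follows its sided entity)."""
        return self.entity_fold[self.data.triples[:, self.side_axis]]

    def split(self, fold: int):
        """(train, validation, test) index arrays for one fold; fold t is
        the test fold, fold (t+1) mod n validates, the rest train."""
        if not 0 <= fold < self.n_folds:
            raise ValueError("fold out of range")
        tf = self.triple_folds()
        val_fold = (fold + 1) % self.n_folds
        test = np.flatnonzero(tf == fold)
        val = np.flatnonzero(tf == val_fold)
        train = np.flatnonzero((tf != fold) & (tf != val_fold))
        return train, val, test


def split_folds_by_entity(
    data: LabeledTripleSet, side: str, n_folds: int, seed: int, n_entities: int | None = None
) -> FoldAssignment:
    """Greedy balanced partition of sided entities into folds.

    Entities are sorted by descending positive count (ties shuffled by
    seed) and each is assigned to the currently lightest fold, so known
    positives spread evenly; entities with no positives follow the same
    rule with zero weight.  All of an entity's labeled triples inherit
    its fold.
    """
    axis = ROLE_AXES[side]
    ents = data.triples[:, axis]
    if n_entities is None:
        n_entities = int(ents.max()) + 1 if len(ents) else 0
    pos_count = np.bincount(ents[data.labels == 1], minlength=n_entities)
    if (pos_count > 0).sum() < n_folds:
        raise ValueError(
            f"need >= {n_folds} {side} entities with positives, "
            f"got {(pos_count > 0).sum()}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_entities)
    order = order[np.argsort(-pos_count[order], kind="stable")]

    entity_fold = np.zeros(n_entities, dtype=int)
    load = np.zeros(n_folds)
    tiny = 1e-9  # spreads zero-positive entities round-robin
    for e in order:
        f = int(np.argmin(load))
        entity_fold[e] = f
        load[f] += pos_count[e] + tiny
    return FoldAssignment(side, n_folds, entity_fold, data)


def make_model(name: str, cfg: TrainingConfig, similarities=None, shape=None, seed_offset=0):
    cls = MODEL_REGISTRY[name]
    return cls(
        rank=cfg.rank,
        similarities=similarities,
        shape=shape,
        learning_rate=cfg.learning_rate,
        max_epochs=cfg.max_epochs,
        patience=cfg.patience,
        random_state=cfg.seed + seed_offset,
    )


def train_model(model, folds: FoldAssignment, fold: int):
    """Clone-and-fit ``model`` on one fold's train split with validation-
    AUC early stopping; returns (fitted model, validation trace)."""
    train, val, test = folds.split(fold)
    X, y = folds.data.triples, folds.data.labels
    m = clone(model)
    m.fit(X[train], y[train], validation_data=(X[val], y[val]))
    return m, m.history_


def cross_validate(
    model,
    folds: FoldAssignment,
    fold_ids=None,
    n_list=(1, 3, 5, 10),
    grouping="per-entity",
):
    """Train/evaluate over folds.  Returns (per-fold RankingMetrics list,
    pooled RankingMetrics over all test scores, fitted models)."""
    fold_ids = range(folds.n_folds) if fold_ids is None else fold_ids
    X, y = folds.data.triples, folds.data.labels
    per_fold, models = [], []
    pooled_y, pooled_s, pooled_g = [], [], []
    for f in fold_ids:
        m, _ = train_model(model, folds, f)
        _, _, test = folds.split(f)
        metrics = evaluate_fold(m, X[test], y[test], folds.side_axis, n_list, grouping)
        per_fold.append(metrics)
        models.append(m)
        pooled_y.append(y[test])
        pooled_s.append(m.predict_proba(X[test])[:, 1])
        pooled_g.append(X[test, folds.side_axis])
    pooled = evaluate_scores(
        np.concatenate(pooled_y),
        np.concatenate(pooled_s),
        group_ids=np.concatenate(pooled_g),
        n_list=n_list,
        grouping=grouping,
    )
    return per_fold, pooled, models


def sweep(
    tensor: TripleTensor,
    model_names,
    ranks,
    alphas,
    cfg: TrainingConfig,
    similarities=None,
    fold_ids=(0,),
) -> pd.DataFrame:
    """Grid sweep over (model, rank, alpha); one row per setting with the
    mean test AUC over the evaluated folds.  Seeds are fixed per cell."""
    rows = []
    for alpha in alphas:
        data = sample_negatives(tensor, alpha, cfg.seed)
        folds = split_folds_by_entity(
            data, cfg.side, cfg.n_folds, cfg.seed,
            n_entities=tensor.shape[ROLE_AXES[cfg.side]],
        )
        for rank in ranks:
            for name in model_names:
                sub_cfg = TrainingConfig(
                    neg_ratio=alpha, n_folds=cfg.n_folds, side=cfg.side, rank=rank,
                    learning_rate=cfg.learning_rate, max_epochs=cfg.max_epochs,
                    patience=cfg.patience, seed=cfg.seed,
                )
                model = make_model(name, sub_cfg, similarities=similarities, shape=tensor.shape)
                per_fold, pooled, _ = cross_validate(model, folds, fold_ids=fold_ids)
                rows.append(
                    {
                        "model": name,
                        "rank": rank,
                        "alpha": alpha,
                        "mean_test_auc": float(np.mean([m.auc for m in per_fold])),
                        "pooled_auc": pooled.auc,
                    }
                )
                logger.info("sweep %s rank=%d alpha=%d auc=%.3f", name, rank, alpha, rows[-1]["mean_test_auc"])
    return pd.DataFrame(rows)
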