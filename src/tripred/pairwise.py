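"""Pairwise association prediction from trained triple-model latents.

Once a triple model is fitted, every drug, gene, and disease has a
latent vector; the score of a pair of entities from two roles is the
model's triple logit marginalized over the absent third role (a
head-weighted inner product of the pair's latents; see
:func:`model_pairwise_scores`).  For the ensemble, the default latent
is the concatenation of the GTD-path and MLP-path vectors, mirroring
the model's merge (a single path can be selected instead).

Cold-start pairwise evaluation reuses the triple-model fold assignment:
for each test-fold sided entity, all counterpart entities are ranked
and scored against the known association list (negatives are all
unknown pairs — pairwise matrices are small, so no subsampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import RankingMetrics, evaluate_scores
from .models import ROLE_AXES

logger = logging.getLogger(__name__)


@dataclass
class PairwiseScoreMatrix:
    """|A| x |B| inner-product score grid for an ordered role pair."""

    roles: tuple[str, str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        if not np.isfinite(self.scores).all():
            raise ValueError("pairwise scores must be finite")


def pairwise_scores(
    lat_a: np.ndarray, lat_b: np.ndarray, roles=("drug", "disease"), weights=None
) -> PairwiseScoreMatrix:
    """scores[a, b] = <lat_a[a], lat_b[b]>, optionally weighted per latent
    dimension: sum_q w_q lat_a[a, q] lat_b[b, q]."""
    lat_a, lat_b = np.asarray(lat_a, float), np.asarray(lat_b, float)
    if lat_a.ndim != 2 or lat_b.ndim != 2 or lat_a.shape[1] != lat_b.shape[1]:
        raise ValueError("latent matrices must be 2-D with equal latent dimension")
    if weights is not None:
        weights = np.asarray(weights, float)
        if weights.shape != (lat_a.shape[1],):
            raise ValueError("weights length must equal the latent dimension")
        lat_a = lat_a * weights
    return PairwiseScoreMatrix(tuple(roles), lat_a @ lat_b.T)


def model_pairwise_scores(model, role_a: str, role_b: str, path=None) -> PairwiseScoreMatrix:
    """Pairwise score matrix from a fitted triple model's latents.

    score[a, b] is the model's triple logit averaged over all entities of
    the absent third role.  Because every model's logit is linear in each
    role's latent (interaction product times the learned head h), that
    average equals sum_q h_q m_q lat_a[a, q] lat_b[b, q] with m the
    absent role's mean latent vector.  Using a plain unweighted inner
    product instead would flip every latent dimension whose head weight
    (or typical absent-role activation) is negative.
    """
    missing = (set(ROLE_AXES) - {role_a, role_b})
    if len(missing) != 1:
        raise ValueError(f"roles must be two distinct of {tuple(ROLE_AXES)}")
    missing = missing.pop()
    kw = {} if path is None else {"path": path}
    try:
        la = model.latent_vectors(role_a, **kw)
        lb = model.latent_vectors(role_b, **kw)
        lm = model.latent_vectors(missing, **kw)
        h = model.head_weights(**kw)
    except TypeError:  # single-path models take no path argument
        la, lb = model.latent_vectors(role_a), model.latent_vectors(role_b)
        lm, h = model.latent_vectors(missing), model.head_weights()
    return pairwise_scores(la, lb, roles=(role_a, role_b), weights=h * lm.mean(axis=0))


def evaluate_pairwise(
    scores: PairwiseScoreMatrix,
    known_pairs,
    fold_assignment,
    fold_ids=None,
    n_list=(1, 3, 5, 10),
) -> RankingMetrics:
    """Cold-start evaluation of a pairwise score matrix.

    ``known_pairs`` is an iterable of (a_index, b_index) integer pairs on
    the score matrix's axes; ``fold_assignment`` is the triple-model
    FoldAssignment whose side matches the first role.  Test entities
    with no known pairs are skipped (logged).
    """
    side_role = fold_assignment.side
    if side_role not in scores.roles:
        raise ValueError(f"fold side {side_role!r} not among score roles {scores.roles}")
    transpose = scores.roles.index(side_role) == 1
    grid = scores.scores.T if transpose else scores.scores
    n_a, n_b = grid.shape
    known = np.zeros((n_a, n_b), dtype=bool)
    for a, b in known_pairs:
        if transpose:
            a, b = b, a
        known[a, b] = True

    fold_ids = range(fold_assignment.n_folds) if fold_ids is None else fold_ids
    fold_set = set(fold_ids)
    test_entities = [
        e for e in range(min(n_a, len(fold_assignment.entity_fold)))
        if fold_assignment.entity_fold[e] in fold_set
    ]
    ys, ss, gs, skipped = [], [], [], 0
    for e in test_entities:
        if not known[e].any():
            skipped += 1
            continue
        ys.append(known[e].astype(float))
        ss.append(grid[e])
        gs.append(np.full(n_b, e))
    if skipped:
        logger.info("pairwise eval: skipped %d test entities with no known pairs", skipped)
    if not ys:
        raise ValueError("no test entities with known pairs")
    return evaluate_scores(
        np.concatenate(ys), np.concatenate(ss), group_ids=np.concatenate(gs), n_list=n_list
    )


def top_candidates(scores: PairwiseScoreMatrix, entity: int, n: int = 10, exclude=None):
    """Indices of the top-n counterpart entities for one entity, optionally
    excluding already-known partners."""
    row = scores.scores[entity].copy()
    if exclude is not None:
        row[list(exclude)] = -np.inf
    order = np.argsort(-row, kind="stable")
    return order[:n]
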