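"""Data model and I/O for entities, associations, similarities, and the triple tensor.

A (drug, gene, disease) triple association exists when all three pairwise
links are present: drug i treats disease k, drug i binds gene j, and
disease k is caused by gene j.  The binary 3-way tensor built from those
closed triangles is the object the models complete.

External identifiers live only at the I/O boundary; internally every
entity is a 0-based integer index that is stable for the lifetime of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("drug", "gene", "disease")

ASSOCIATION_KINDS = {
    "drug-disease": ("drug", "disease"),
    "drug-gene": ("drug", "gene"),
    "disease-gene": ("disease", "gene"),
}


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class EntityIndex:
    """Ordered, unique external identifiers for one entity role."""

    role: str
    ids: tuple[str, ...]

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("entity identifiers must be unique")
        object.__setattr__(self, "_pos", {e: i for i, e in enumerate(self.ids)})

    @property
    def size(self) -> int:
        return len(self.ids)

    def position(self, entity_id: str) -> int:
        return self._pos[entity_id]

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._pos


@dataclass(frozen=True)
class AssociationList:
    """Deduplicated bipartite identifier pairs of one association kind."""

    kind: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        if self.kind not in ASSOCIATION_KINDS:
            raise ValueError(f"unknown association kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def roles(self) -> tuple[str, str]:
        return ASSOCIATION_KINDS[self.kind]

    def entity_ids(self, side: int) -> set[str]:
        return {p[side] for p in self.pairs}


@dataclass(frozen=True)
class TripleTensor:
    """Sparse binary drug x gene x disease tensor.

    ``positives`` holds the (i, j, k) integer index triples whose cell
    value is 1; every other cell is implicitly 0.
    """

    shape: tuple[int, int, int]
    positives: frozenset[tuple[int, int, int]]

    def __post_init__(self):
        I, J, K = self.shape
        for (i, j, k) in self.positives:
            if not (0 <= i < I and 0 <= j < J and 0 <= k < K):
                raise ValueError(f"triple {(i, j, k)} outside shape {self.shape}")

    @property
    def n_cells(self) -> int:
        I, J, K = self.shape
        return I * J * K

    @property
    def density(self) -> float:
        return len(self.positives) / self.n_cells

    def positives_array(self) -> np.ndarray:
        """Positives as an (n, 3) int array in sorted (i, j, k) order."""
        if not self.positives:
            return np.empty((0, 3), dtype=np.int64)
        return np.array(sorted(self.positives), dtype=np.int64)

    def dense(self) -> np.ndarray:
        x = np.zeros(self.shape, dtype=np.int8)
        for (i, j, k) in self.positives:
            x[i, j, k] = 1
        return x


@dataclass
class SimilarityMatrix:
    """Square symmetric entity similarity, values in [0, 1], unit diagonal."""

    role: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("similarity matrix must be symmetric")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("similarity values must lie in [0, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def size(self) -> int:
        return self.values.shape[0]


def load_association_table(path, kind: str) -> AssociationList:
    """Read a two-column TSV edge list (header row names the id columns)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    except pd.errors.EmptyDataError:
        logger.warning("association file %s is empty", path)
        return AssociationList(kind, frozenset())
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: expected >=2 tab-separated identifier columns, got {df.shape[1]}"
        )
    a, b = df.columns[:2]
    pairs = frozenset(zip(df[a].astype(str), df[b].astype(str)))
    logger.info("%s: read %d rows, %d unique %s pairs", path, len(df), len(pairs), kind)
    return AssociationList(kind, pairs)


def write_association_table(assoc: AssociationList, path) -> None:
    ra, rb = assoc.roles
    df = pd.DataFrame(sorted(assoc.pairs), columns=[ra, rb])
    df.to_csv(path, sep="\t", index=False)


def build_triple_tensor(
    dd: AssociationList,
    dg: AssociationList,
    sg: AssociationList,
    idx_d: EntityIndex,
    idx_g: EntityIndex,
    idx_s: EntityIndex,
) -> TripleTensor:
    """Close triangles: (i, j, k) is positive iff drug i-disease k, drug
    i-gene j, and disease k-gene j are all known pairs.

    Identifiers that do not resolve in the entity indexes are dropped
    (counted in the log).  Implemented by intersecting, per (drug, gene)
    edge, the drug's disease set with the gene's disease set.
    """
    if dd.kind != "drug-disease" or dg.kind != "drug-gene" or sg.kind != "disease-gene":
        raise ValueError("association lists passed in wrong order")

    def _resolve(pairs, ia, ib):
        out, dropped = [], 0
        for x, y in pairs:
            if x in ia and y in ib:
                out.append((ia.position(x), ib.position(y)))
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d pairs with unresolvable identifiers", dropped)
        return out

    dd_ix = _resolve(dd.pairs, idx_d, idx_s)   # (i, k)
    dg_ix = _resolve(dg.pairs, idx_d, idx_g)   # (i, j)
    sg_ix = _resolve(sg.pairs, idx_s, idx_g)   # (k, j)

    diseases_of_drug: dict[int, set[int]] = {}
    for i, k in dd_ix:
        diseases_of_drug.setdefault(i, set()).add(k)
    diseases_of_gene: dict[int, set[int]] = {}
    for k, j in sg_ix:
        diseases_of_gene.setdefault(j, set()).add(k)

    positives = set()
    for i, j in dg_ix:
        common = diseases_of_drug.get(i, set()) & diseases_of_gene.get(j, set())
        for k in common:
            positives.add((i, j, k))

    if not positives:
        logger.warning("no closed drug-gene-disease triangles: tensor is empty")
    tensor = TripleTensor((idx_d.size, idx_g.size, idx_s.size), frozenset(positives))
    logger.info("triple tensor: %d positives, density %.2e", len(positives), tensor.density)
    return tensor


def filter_low_degree_genes(
    dg: AssociationList, sg: AssociationList, min_degree: int = 10
) -> tuple[AssociationList, AssociationList]:
    """Optionally drop genes with fewer than ``min_degree`` drug-gene or
    disease-gene associations (sparsity control; off by default upstream)."""
    from collections import Counter

    deg = Counter(g for _, g in dg.pairs) + Counter(g for _, g in sg.pairs)
    keep = {g for g, c in deg.items() if c >= min_degree}
    return (
        AssociationList(dg.kind, frozenset(p for p in dg.pairs if p[1] in keep)),
        AssociationList(sg.kind, frozenset(p for p in sg.pairs if p[1] in keep)),
    )


def load_similarity_matrix(path, idx: EntityIndex) -> SimilarityMatrix:
    """Read a square TSV similarity matrix (row/column id headers) and
    reindex it to ``idx`` order.

    Values outside [0, 1] trigger min-max normalization over the whole
    matrix; asymmetry beyond 1e-8 is resolved by averaging with the
    transpose.  Entities missing from the file get a zero row with unit
    diagonal.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    n = idx.size
    values = np.zeros((n, n), dtype=float)
    present = [e for e in idx.ids if e in df.index and e in df.columns]
    missing = [e for e in idx.ids if e not in present]
    if missing:
        logger.info("%d %s entities absent from %s; zero rows used", len(missing), idx.role, path)
    if present:
        sub = df.loc[present, present].to_numpy(dtype=float)
        pos = np.array([idx.position(e) for e in present])
        values[np.ix_(pos, pos)] = sub

    if not np.allclose(values, values.T, atol=1e-8):
        values = 0.5 * (values + values.T)
    if values.min() < 0 or values.max() > 1:
        lo, hi = values.min(), values.max()
        values = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(idx.role, values)


def write_similarity_matrix(sim: SimilarityMatrix, idx: EntityIndex, path) -> None:
    pd.DataFrame(sim.values, index=idx.ids, columns=idx.ids).to_csv(path, sep="\t")
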