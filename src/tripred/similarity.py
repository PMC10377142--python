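"""Similarity kernels: multi-level ATC-code Jaccard and ontology
information-content semantic similarity with best-match averaging.

Two families of side information feed the triple-association models:

* Drug-drug similarity from WHO ATC codes.  A 7-character ATC code
  decomposes into 5 cumulative levels (anatomical group through chemical
  substance).  Per level, similarity is the Jaccard index of the two
  drugs' level-k prefix sets; the final score averages the five levels.

* Gene-gene and disease-disease similarity from an ontology (GO, HPO)
  plus annotations.  A term's information content is IC(C) = -log P(C),
  where P(C) is the fraction of annotated entities whose ancestor-
  propagated annotation set contains C.  Two terms are compared by the
  IC mass of their shared ancestors over the IC mass of all their
  ancestors; two entities by the best-match average over their term sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_data import EntityIndex, SimilarityMatrix

logger = logging.getLogger(__name__)

ATC_LEVEL_SLICES = (1, 3, 4, 5, 7)  # cumulative prefix lengths of the 5 levels


# ---------------------------------------------------------------------------
# ATC codes


@dataclass(frozen=True)
class AtcCodeSet:
    """Non-empty set of 7-character ATC codes assigned to one drug."""

    drug_id: str
    codes: frozenset[str]

    def __post_init__(self):
        if not self.codes:
            raise ValueError(f"drug {self.drug_id}: ATC code set is empty")
        for c in self.codes:
            if len(c) != 7:
                raise ValueError(f"ATC code {c!r} is not 7 characters")

    def level_prefixes(self, k: int) -> frozenset[str]:
        """The drug's set of level-k code prefixes (k in 1..5)."""
        if not 1 <= k <= 5:
            raise ValueError("ATC level must be in 1..5")
        n = ATC_LEVEL_SLICES[k - 1]
        return frozenset(c[:n] for c in self.codes)


def atc_level_similarity(a: AtcCodeSet, b: AtcCodeSet, k: int) -> float:
    """Jaccard index of the two drugs' level-k ATC prefix sets."""
    pa, pb = a.level_prefixes(k), b.level_prefixes(k)
    return len(pa & pb) / len(pa | pb)


def atc_similarity(a: AtcCodeSet, b: AtcCodeSet) -> float:
    """Mean of the level-wise Jaccard similarities over the 5 ATC levels."""
    return sum(atc_level_similarity(a, b, k) for k in range(1, 6)) / 5.0


def load_atc_table(path) -> dict[str, AtcCodeSet]:
    """Read a (drug-id, code) TSV with header; multiple rows per drug."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    out: dict[str, set[str]] = {}
    for drug, code in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(drug), set()).add(str(code))
    return {d: AtcCodeSet(d, frozenset(cs)) for d, cs in out.items()}


# ---------------------------------------------------------------------------
# Ontology + annotations


@dataclass
class Ontology:
    """DAG of terms; ``parents`` maps child -> set of direct parents.

    Ancestor sets include the term itself, so that a term's similarity
    with itself is exactly 1.
    """

    parents: dict[str, set[str]]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        # include isolated parents as terms and check acyclicity
        for ps in list(self.parents.values()):
            for p in ps:
                self.parents.setdefault(p, set())
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        g.add_edges_from((c, p) for c, ps in self.parents.items() for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology parent edges contain a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term``, the term itself included."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"unknown ontology term {term!r}")
        out = {term}
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(out)
        self._ancestors[term] = result
        return result

    def descendants(self, root: str) -> frozenset[str]:
        """All terms whose ancestor set contains ``root`` (root included)."""
        return frozenset(t for t in self.parents if root in self.ancestors(t))


def load_obo(path) -> Ontology:
    """Read an OBO file (id / is_a stanzas) into an Ontology."""
    import obonet

    g = obonet.read_obo(path)
    parents: dict[str, set[str]] = {t: set() for t in g.nodes}
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return Ontology(parents)


@dataclass
class AnnotationCorpus:
    """Entity -> term annotations with propagated term probabilities.

    ``P(C)`` is the fraction of annotated entities whose ancestor-closed
    annotation set contains C; ``IC(C) = -ln P(C)``.  Natural log: the
    IC-ratio score is base-invariant.
    """

    ontology: Ontology
    annotations: dict[str, frozenset[str]]
    ic: dict[str, float] = field(init=False, repr=False)
    _closed: dict[str, frozenset[str]] = field(init=False, repr=False)

    def __post_init__(self):
        self.annotations = {
            e: frozenset(t for t in ts if t in self.ontology.parents)
            for e, ts in self.annotations.items()
        }
        self.annotations = {e: ts for e, ts in self.annotations.items() if ts}
        self._closed = {
            e: frozenset().union(*(self.ontology.ancestors(t) for t in ts))
            for e, ts in self.annotations.items()
        }
        n = len(self._closed)
        counts: dict[str, int] = {}
        for ts in self._closed.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        self.ic = {t: -math.log(c / n) for t, c in counts.items()} if n else {}

    def terms_of(self, entity: str) -> frozenset[str]:
        return self.annotations.get(entity, frozenset())

    def restricted(self, roots: set[str]) -> "AnnotationCorpus":
        """Corpus limited to descendants of the given sub-ontology roots
        (e.g. GO biological_process, HPO Phenotypic abnormality)."""
        allowed = frozenset().union(*(self.ontology.descendants(r) for r in roots))
        sub_parents = {
            t: {p for p in ps if p in allowed}
            for t, ps in self.ontology.parents.items()
            if t in allowed
        }
        sub_onto = Ontology(sub_parents)
        anns = {
            e: frozenset(t for t in ts if t in allowed)
            for e, ts in self.annotations.items()
        }
        return AnnotationCorpus(sub_onto, {e: ts for e, ts in anns.items() if ts})


def load_annotations(
    path,
    ontology: Ontology,
    drop_iea: bool = True,
    drop_not: bool = True,
) -> AnnotationCorpus:
    """Read an annotation TSV (entity-id, term-id[, evidence[, qualifier]]).

    When evidence / qualifier columns are present, IEA-evidence rows and
    rows whose qualifier contains "NOT" are dropped by default.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] >= 3 and drop_iea:
        df = df[df.iloc[:, 2].fillna("").str.upper() != "IEA"]
    if df.shape[1] >= 4 and drop_not:
        df = df[~df.iloc[:, 3].fillna("").str.upper().str.contains("NOT")]
    anns: dict[str, set[str]] = {}
    for e, t in zip(df.iloc[:, 0], df.iloc[:, 1]):
        anns.setdefault(str(e), set()).add(str(t))
    return AnnotationCorpus(ontology, {e: frozenset(ts) for e, ts in anns.items()})


def term_semantic_similarity(
    onto: Ontology, corpus: AnnotationCorpus, c1: str, c2: str
) -> float:
    """IC-ratio similarity of two terms: shared-ancestor IC mass over
    total-ancestor IC mass.  Terms with only zero-IC ancestors score 0."""
    a1, a2 = onto.ancestors(c1), onto.ancestors(c2)
    ic = corpus.ic
    num = sum(ic.get(t, 0.0) for t in a1 & a2)
    den = sum(ic.get(t, 0.0) for t in a1 | a2)
    return num / den if den > 0 else 0.0


def bma_similarity(
    onto: Ontology, corpus: AnnotationCorpus, e1: str, e2: str
) -> float:
    """Best-match-average similarity of two annotated entities."""
    t1, t2 = corpus.terms_of(e1), corpus.terms_of(e2)
    if not t1 or not t2:
        raise ValueError(f"entity {e1 if not t1 else e2!r} has no annotations")
    sim = {
        (a, b): term_semantic_similarity(onto, corpus, a, b)
        for a in t1
        for b in t2
    }
    row = sum(max(sim[(a, b)] for b in t2) for a in t1)
    col = sum(max(sim[(a, b)] for a in t1) for b in t2)
    return (row + col) / (len(t1) + len(t2))


# ---------------------------------------------------------------------------
# Matrix builders


def build_atc_similarity_matrix(
    entities: EntityIndex, codes: dict[str, AtcCodeSet]
) -> SimilarityMatrix:
    """Full symmetric ATC-similarity matrix; drugs without codes get a
    zero row with unit diagonal."""
    n = entities.size
    values = np.eye(n)
    have = [e for e in entities.ids if e in codes]
    if len(have) < n:
        logger.info("%d drugs lack ATC codes; zero similarity rows", n - len(have))
    for ii, ei in enumerate(entities.ids):
        if ei not in codes:
            continue
        for ej in entities.ids[ii + 1:]:
            if ej not in codes:
                continue
            jj = entities.position(ej)
            s = atc_similarity(codes[ei], codes[ej])
            values[ii, jj] = values[jj, ii] = s
    return SimilarityMatrix(entities.role, values)


def build_semantic_similarity_matrix(
    entities: EntityIndex,
    ontology: Ontology,
    corpus: AnnotationCorpus,
    roots: list[set[str]] | None = None,
    pair_whitelist: set[tuple[str, str]] | None = None,
) -> SimilarityMatrix:
    """Full symmetric BMA semantic-similarity matrix.

    ``roots`` is an optional list of sub-ontology root sets; the score of
    a pair is the mean of its per-sub-ontology BMA scores over the
    sub-ontologies where both entities are annotated (GO combines
    biological process and molecular function this way).  With
    ``pair_whitelist``, off-diagonal pairs not whitelisted (either
    orientation) stay 0 — used to restrict gene pairs to known PPIs.
    Entities without annotations get a zero row with unit diagonal.
    """
    corpora = (
        [(ontology, corpus)]
        if not roots
        else [(c.ontology, c) for c in (corpus.restricted(r) for r in roots)]
    )
    n = entities.size
    values = np.eye(n)
    for ii, ei in enumerate(entities.ids):
        for jj in range(ii + 1, n):
            ej = entities.ids[jj]
            if pair_whitelist is not None and (
                (ei, ej) not in pair_whitelist and (ej, ei) not in pair_whitelist
            ):
                continue
            scores = [
                bma_similarity(o, c, ei, ej)
                for o, c in corpora
                if c.terms_of(ei) and c.terms_of(ej)
            ]
            if scores:
                values[ii, jj] = values[jj, ii] = float(np.mean(scores))
    n_missing = sum(
        1
        for e in entities.ids
        if not any(c.terms_of(e) for _, c in corpora)
    )
    if n_missing:
        logger.info("%d %s entities lack annotations; zero rows", n_missing, entities.role)
    return SimilarityMatrix(entities.role, values)
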