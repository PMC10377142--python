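"""Self-contained synthetic fixtures: planted low-rank tensors with
correlated side information, toy ATC code sets, and toy DAG ontologies
with annotations.

These generators define the study conditions every module is tested
under without external downloads.  The planted tensor emulates the
sparsity regime of real drug-gene-disease data (hundreds of positive
cells in a tensor of millions) with known ground truth: positives are
the top cells of an exact rank-R* CP tensor, and the similarity
matrices are derived from the ground-truth factors so that side
information is genuinely informative for cold-start prediction.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .core_data import SimilarityMatrix, TripleTensor
from .models import cp_reconstruct
from .similarity import AnnotationCorpus, AtcCodeSet, Ontology


@dataclass(frozen=True)
class PlantedTensorSpec:
    """Conditions for a planted low-rank benchmark tensor."""

    shape: tuple[int, int, int] = (50, 80, 40)
    rank: int = 4
    n_positives: int = 300
    factor_sparsity: float = 0.3
    noise: float = 0.0
    seed: int = 0
    informative_similarity: bool = True

    def __post_init__(self):
        I, J, K = self.shape
        if self.n_positives > I * J * K:
            raise ValueError("n_positives exceeds tensor size")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise rate must be in [0, 0.5)")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if not 0 <= self.factor_sparsity < 1:
            raise ValueError("factor_sparsity must be in [0, 1)")


@dataclass
class PlantedTensor:
    """A planted benchmark instance with its ground truth."""

    spec: PlantedTensorSpec
    tensor: TripleTensor
    factors: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False)
    similarities: dict = field(repr=False)

    @property
    def similarity_arrays(self) -> dict:
        return {role: s.values for role, s in self.similarities.items()}


def _factor_cosine_similarity(F: np.ndarray) -> np.ndarray:
    """Cosine similarity of non-negative factor rows, in [0, 1]; rows of
    zero norm get zero similarity (diagonal forced to 1 downstream)."""
    norms = np.linalg.norm(F, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    G = (F / safe[:, None]) @ (F / safe[:, None]).T
    G[norms == 0, :] = 0.0
    G[:, norms == 0] = 0.0
    return np.clip(G, 0.0, 1.0)


def generate_planted_tensor(spec: PlantedTensorSpec) -> PlantedTensor:
    """Draw non-negative sparse factors, mark the top-``n_positives``
    cells of the CP reconstruction positive (ties resolved in
    lexicographic (i, j, k) order), optionally flip labels at the noise
    rate, and derive per-role similarity matrices from the factors."""
    rng = np.random.default_rng(spec.seed)
    I, J, K = spec.shape
    factors = []
    for n in (I, J, K):
        F = rng.uniform(0.0, 1.0, size=(n, spec.rank))
        F *= rng.random(F.shape) >= spec.factor_sparsity
        factors.append(F)
    A, B, C = factors

    scores = cp_reconstruct(A, B, C).ravel()
    # stable sort on -scores: ties fall in flat (= lexicographic ijk) order
    top = np.argsort(-scores, kind="stable")[: spec.n_positives]
    positive_flags = np.zeros(scores.size, dtype=bool)
    positive_flags[top] = True

    n_flip = int(round(spec.noise * spec.n_positives))
    if n_flip:
        pos_idx = np.flatnonzero(positive_flags)
        off = rng.choice(pos_idx, size=n_flip, replace=False)
        zero_idx = np.flatnonzero(~positive_flags)
        on = rng.choice(zero_idx, size=n_flip, replace=False)
        positive_flags[off] = False
        positive_flags[on] = True

    triples = np.column_stack(np.unravel_index(np.flatnonzero(positive_flags), (I, J, K)))
    tensor = TripleTensor((I, J, K), frozenset(map(tuple, triples.tolist())))

    sims = {}
    for role, F in zip(("drug", "gene", "disease"), factors):
        if spec.informative_similarity:
            values = _factor_cosine_similarity(F)
        else:
            raw = rng.uniform(0.0, 1.0, size=(F.shape[0], F.shape[0]))
            values = 0.5 * (raw + raw.T)
        np.fill_diagonal(values, 1.0)
        sims[role] = SimilarityMatrix(role, values)
    return PlantedTensor(spec, tensor, (A, B, C), sims)


# ---------------------------------------------------------------------------
# Toy ontology with annotations


def generate_toy_ontology(
    depth: int,
    branching: int,
    n_entities: int,
    terms_per_entity: int,
    seed: int,
    extra_edge_prob: float = 0.1,
) -> tuple[Ontology, AnnotationCorpus]:
    """Complete tree of the given depth/branching (root = ``T0``) plus a
    few random extra DAG edges; entities annotated to random leaves."""
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    parents: dict[str, set[str]] = {"T0": set()}
    levels = [["T0"]]
    counter = 1
    for _ in range(depth - 1):
        nxt = []
        for p in levels[-1]:
            for _ in range(branching):
                t = f"T{counter}"
                counter += 1
                parents[t] = {p}
                nxt.append(t)
        levels.append(nxt)
    # extra DAG edges from deeper to strictly shallower levels
    for li in range(2, len(levels)):
        for t in levels[li]:
            if rng.random() < extra_edge_prob:
                shallower = levels[rng.integers(0, li - 1)]
                parents[t].add(shallower[rng.integers(0, len(shallower))])
    onto = Ontology(parents)

    leaves = levels[-1]
    anns = {
        f"E{e}": frozenset(
            rng.choice(leaves, size=min(terms_per_entity, len(leaves)), replace=False)
        )
        for e in range(n_entities)
    }
    return onto, AnnotationCorpus(onto, anns)


# ---------------------------------------------------------------------------
# Toy ATC code sets


def generate_toy_atc(
    n_drugs: int,
    n_families: int,
    codes_per_drug: int,
    seed: int,
    shared_level: int = 4,
) -> dict[str, AtcCodeSet]:
    """Valid 7-character toy ATC codes in ``n_families`` families.

    Families are pairwise disjoint at level 1 (distinct anatomical-group
    letters), and all drugs within a family share code prefixes through
    ``shared_level`` (5 means identical codes family-wide).
    """
    if not 1 <= n_families <= 26:
        raise ValueError("n_families must be in 1..26 (one level-1 letter each)")
    if not 1 <= shared_level <= 5:
        raise ValueError("shared_level must be in 1..5")
    rng = np.random.default_rng(seed)
    letters = string.ascii_uppercase

    level_len = (1, 3, 4, 5, 7)  # cumulative code length at each level

    def random_levels(from_level: int) -> str:
        # level pieces 2..5: 2 digits, letter, letter, 2 digits
        parts = [
            f"{rng.integers(0, 100):02d}",
            letters[rng.integers(0, 26)],
            letters[rng.integers(0, 26)],
            f"{rng.integers(0, 100):02d}",
        ]
        return "".join(parts[from_level - 2 :])

    family_prefix = [
        (letters[f] + random_levels(2))[: level_len[shared_level - 1]]
        for f in range(n_families)
    ]
    out = {}
    for d in range(n_drugs):
        prefix = family_prefix[d % n_families]
        codes = set()
        while len(codes) < codes_per_drug:
            codes.add(prefix if shared_level == 5 else prefix + random_levels(shared_level + 1))
            if shared_level == 5:
                break
        out[f"D{d}"] = AtcCodeSet(f"D{d}", frozenset(codes))
    return out


# ---------------------------------------------------------------------------
# Fixture writers (same TSV/OBO dialects the loaders read)


def write_planted_fixture(planted: PlantedTensor, out_dir) -> None:
    """Write association TSVs and similarity TSVs for a planted tensor.

    The three pairwise lists are the projections of the positive triples,
    so triangle closure over them reproduces at least the planted
    positives.
    """
    import pathlib

    import pandas as pd

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    I, J, K = planted.tensor.shape
    ids = {
        "drug": [f"D{i}" for i in range(I)],
        "gene": [f"G{j}" for j in range(J)],
        "disease": [f"S{k}" for k in range(K)],
    }
    pos = planted.tensor.positives_array()
    pd.DataFrame(
        {"drug": [ids["drug"][i] for i in pos[:, 0]], "disease": [ids["disease"][k] for k in pos[:, 2]]}
    ).drop_duplicates().to_csv(out / "drug_disease.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"drug": [ids["drug"][i] for i in pos[:, 0]], "gene": [ids["gene"][j] for j in pos[:, 1]]}
    ).drop_duplicates().to_csv(out / "drug_gene.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"disease": [ids["disease"][k] for k in pos[:, 2]], "gene": [ids["gene"][j] for j in pos[:, 1]]}
    ).drop_duplicates().to_csv(out / "disease_gene.tsv", sep="\t", index=False)
    for role, sim in planted.similarities.items():
        pd.DataFrame(sim.values, index=ids[role], columns=ids[role]).to_csv(
            out / f"{role}_similarity.tsv", sep="\t"
        )


def write_toy_obo(onto: Ontology, path) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(onto.parents):
            fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            for p in sorted(onto.parents[term]):
                fh.write(f"is_a: {p} ! {p}\n")


def write_annotations(corpus: AnnotationCorpus, path) -> None:
    import pandas as pd

    rows = [
        {"entity": e, "term": t}
        for e in sorted(corpus.annotations)
        for t in sorted(corpus.annotations[e])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_atc_table(codes: dict[str, AtcCodeSet], path) -> None:
    import pandas as pd

    rows = [
        {"drug": d, "code": c}
        for d in sorted(codes)
        for c in sorted(codes[d].codes)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
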