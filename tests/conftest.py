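import numpy as np
import pytest

from tripred.similarity import AnnotationCorpus, Ontology
from tripred.synthetic import PlantedTensorSpec, generate_planted_tensor


@pytest.fixture(scope="session")
def hand_dag():
    """Small DAG with hand-enumerable ancestor sets.

          R
         / \\
        A   B
       / \\ / \\
      C   D   E

    D has two parents (A and B).  Annotated entities: g1 -> {C},
    g2 -> {D}, g3 -> {E}, g4 -> {A}, g5 -> {C, E}.
    """
    parents = {
        "R": set(),
        "A": {"R"},
        "B": {"R"},
        "C": {"A"},
        "D": {"A", "B"},
        "E": {"B"},
    }
    onto = Ontology(parents)
    anns = {
        "g1": frozenset({"C"}),
        "g2": frozenset({"D"}),
        "g3": frozenset({"E"}),
        "g4": frozenset({"A"}),
        "g5": frozenset({"C", "E"}),
    }
    return onto, AnnotationCorpus(onto, anns)


@pytest.fixture(scope="session")
def small_planted():
    """Easy planted instance for quick training tests: large and dense
    enough that factor-derived similarities genuinely inform cold-start
    prediction (very small rank-2 instances have near-degenerate cosine
    similarity rows and are adversarial rather than easy)."""
    spec = PlantedTensorSpec(shape=(30, 30, 30), rank=4, n_positives=150, seed=3)
    return generate_planted_tensor(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
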