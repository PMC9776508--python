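import numpy as np
import pytest

from mdanet.io_data import (
    AssociationMatrix,
    DiseaseOntology,
    EntityCatalog,
    SimilarityMatrix,
)


@pytest.fixture
def sibling_ontology():
    """d1 and d2 share only the root parent p; d3 is an unrelated root."""
    return DiseaseOntology({"d1": [("d1", "p")], "d2": [("d2", "p")], "d3": []})


@pytest.fixture
def chain_ontology():
    """Single disease d with ancestor chain d -> p -> g."""
    return DiseaseOntology({"d": [("d", "p"), ("p", "g")]})


@pytest.fixture
def small_catalog():
    return EntityCatalog(("m1", "m2", "m3"), ("d1", "d2"))


@pytest.fixture
def small_assoc(small_catalog):
    values = np.array([[1, 0], [0, 1], [1, 1]])
    return AssociationMatrix(values, small_catalog)


@pytest.fixture
def random_similarity():
    rng = np.random.default_rng(42)
    n = 20
    s = rng.random((n, n))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, tuple(f"x{i}" for i in range(n)), kind="functional")
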