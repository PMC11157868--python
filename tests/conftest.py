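import numpy as np
import pytest

from circdis import DiseaseOntology, generate_synthetic_dataset
from circdis.pipeline import PipelineConfig


@pytest.fixture
def chain_ontology():
    """r <- a <- b : a three-term chain (edges point child -> parent)."""
    return DiseaseOntology({"r", "a", "b"}, {("b", "a"), ("a", "r")})


@pytest.fixture
def diamond_ontology():
    """b has two parents a1, a2, both children of root r."""
    return DiseaseOntology(
        {"r", "a1", "a2", "b"},
        {("b", "a1"), ("b", "a2"), ("a1", "r"), ("a2", "r")},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Planted 40 x 15 fixture with 80 positives, used by slower tests."""
    return generate_synthetic_dataset(40, 15, 80, latent_rank=3, dag_depth=4, seed=2)


@pytest.fixture(scope="session")
def small_config():
    """Problem-sized knobs for the 40 x 15 fixture (k must be <= 15)."""
    return PipelineConfig(k=8, num_walks=5, walk_length=40, ae_epochs=100)


def random_dag(rng: np.random.Generator, max_nodes: int = 20) -> DiseaseOntology:
    """Random multi-parent DAG: node i attaches to 1-2 earlier nodes."""
    m = int(rng.integers(2, max_nodes + 1))
    terms = [f"t{i}" for i in range(m)]
    edges = set()
    for i in range(1, m):
        n_par = int(rng.integers(1, min(i, 2) + 1))
        parents = rng.choice(i, size=n_par, replace=False)
        for p in parents:
            edges.add((terms[i], terms[int(p)]))
    return DiseaseOntology(set(terms), edges)
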