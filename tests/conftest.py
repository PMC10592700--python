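import numpy as np
import pandas as pd
import pytest

from sctab import (
    ExpressionDataset,
    NormalizedMatrix,
    OntologyDAG,
    SimConfig,
    normalize,
    simulate,
    split_by_donor,
)


@pytest.fixture(scope="session")
def sim_corpus():
    """Default separable synthetic corpus: 8 types, 20 donors, 200 genes, 10k cells."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_split(sim_corpus):
    donors = sim_corpus.dataset.cell_meta["donor_id"].unique().tolist()
    return split_by_donor(donors, seed=1)


@pytest.fixture(scope="session")
def sim_normalized(sim_corpus):
    return normalize(sim_corpus.dataset)


@pytest.fixture
def chain_ontology():
    """root <- a <- b <- c linear chain."""
    return OntologyDAG(
        terms={"root", "a", "b", "c"},
        is_a_edges={("a", "root"), ("b", "a"), ("c", "b")},
        root="root",
    )


@pytest.fixture
def tiny_dataset():
    """5 cells x 10 genes with complete metadata."""
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 20, size=(5, 10))
    counts[:, 0] += 1  # no all-zero cells
    meta = pd.DataFrame(
        {
            "donor_id": ["d1", "d1", "d2", "d2", "d3"],
            "cell_type": ["a", "a", "b", "b", "c"],
            "assay": "10x 3' v3",
            "tissue": "blood",
            "dataset_id": "ds1",
            "is_primary": True,
        }
    )
    return ExpressionDataset(
        counts=counts, gene_ids=[f"G{i}" for i in range(10)], cell_meta=meta
    )


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    """Random rooted DAG: term i>0 gets 1-2 parents among terms < i."""
    terms = [f"T{i}" for i in range(n_terms)]
    edges = set()
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        for p in rng.choice(i, size=min(n_parents, i), replace=False):
            edges.add((terms[i], terms[int(p)]))
    return OntologyDAG(terms=set(terms), is_a_edges=edges, root="T0")
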