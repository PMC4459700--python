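import numpy as np
import pytest

from netcca import (
    OmicsBlock,
    SyntheticSpec,
    build_knowledge_graph,
    generate_multiomics,
    generate_prior_graph,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def gaussian_blocks(rng):
    """Paired Gaussian blocks, n=40, p=5, q=3, mild cross-correlation."""
    X = rng.standard_normal((40, 5))
    Y = 0.4 * X[:, :3] + rng.standard_normal((40, 3))
    return X, Y


@pytest.fixture()
def toy_block():
    """Small deterministic omics block with one correlated pair."""
    rng = np.random.default_rng(7)
    base = rng.standard_normal(20)
    vals = np.column_stack(
        [
            base,
            base + 0.05 * rng.standard_normal(20),  # near-copy of col 0
            rng.standard_normal(20),
            rng.standard_normal(20),
        ]
    )
    return OmicsBlock([f"s{i}" for i in range(20)], ["A", "B", "C", "D"], vals)


@pytest.fixture(scope="session")
def synthetic_study():
    """Default-condition synthetic study: data, truth and prior graph."""
    spec = SyntheticSpec(seed=42)
    X, Y, truth = generate_multiomics(spec)
    graph = generate_prior_graph(truth, spec)
    return spec, X, Y, truth, graph


@pytest.fixture()
def toy_graph():
    """Hand-sized knowledge graph used across grouping tests.

    Reactions: CHEBI:16196 is a substrate of R1 (genes G1, G2); CHEBI:900
    is a product of R2 (gene G5). Interactions: G1-G3 retained (0.9),
    G3-G4 dropped (0.2), plus a directed 3-cycle G1->G6->G7->G1.
    """
    import pandas as pd

    reactions = pd.DataFrame(
        [
            {"metabolite_id": "CHEBI:16196", "gene_id": "G1", "reaction_id": "R1", "role": "substrate"},
            {"metabolite_id": "CHEBI:16196", "gene_id": "G2", "reaction_id": "R1", "role": "substrate"},
            {"metabolite_id": "CHEBI:900", "gene_id": "G5", "reaction_id": "R2", "role": "product"},
        ]
    )
    interactions = pd.DataFrame(
        [
            {"gene_a": "G1", "gene_b": "G3", "channel": "ppi", "score": 0.9, "directed": 0},
            {"gene_a": "G3", "gene_b": "G4", "channel": "textmining", "score": 0.2, "directed": 0},
            {"gene_a": "G1", "gene_b": "G6", "channel": "other", "score": 0.8, "directed": 1},
            {"gene_a": "G6", "gene_b": "G7", "channel": "other", "score": 0.8, "directed": 1},
            {"gene_a": "G7", "gene_b": "G1", "channel": "other", "score": 0.8, "directed": 1},
        ]
    )
    return build_knowledge_graph(reactions, interactions, score_threshold=0.7)
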