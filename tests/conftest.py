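import numpy as np
import pytest

from presim import (
    EdgeRecord, NodeRecord, SyntheticParams, build_graph, generate_kg,
)


def make_graph(node_specs, edge_specs):
    """node_specs: (id, type[, role]); edge_specs: (src, dst, relation)."""
    nodes = [
        NodeRecord(id=s[0], node_type=s[1], role=s[2] if len(s) > 2 else "none")
        for s in node_specs
    ]
    edges = [EdgeRecord(*e) for e in edge_specs]
    return build_graph(nodes, edges)


@pytest.fixture
def tiny_graph():
    """Two prescriptions sharing one herb; one herb attribute; one disease."""
    return make_graph(
        [
            ("P1", "prescription", "target"),
            ("P2", "prescription", "candidate"),
            ("H1", "herb"),
            ("H2", "herb"),
            ("F1", "flavor"),
            ("D1", "disease"),
            ("S1", "symptom"),
        ],
        [
            ("P1", "H1", "prescription-herb"),
            ("P1", "H2", "prescription-herb"),
            ("P2", "H1", "prescription-herb"),
            ("P1", "D1", "prescription-disease"),
            ("P2", "S1", "prescription-symptom"),
            ("H1", "F1", "herb-flavor"),
        ],
    )


MINI_PARAMS = dict(
    n_target=5, n_candidate=12, n_disease=9, n_symptom=12, n_disease_target=60,
    n_herb=19, n_ingredient=25, n_ingredient_target=40,
    targets_per_disease=6, ingredients_per_herb=3, seed=42,
)


@pytest.fixture(scope="session")
def mini_synthetic():
    """~250-node synthetic graph: fast enough to train in every test."""
    params = SyntheticParams(**MINI_PARAMS)
    nodes, edges, truth = generate_kg(params)
    graph = build_graph(nodes.to_dict("records"), edges.to_dict("records"))
    return graph, truth


@pytest.fixture(scope="session")
def default_synthetic():
    """Default 1/10-scale synthetic graph (20 target, 67 candidate)."""
    params = SyntheticParams(seed=7)
    nodes, edges, truth = generate_kg(params)
    graph = build_graph(nodes.to_dict("records"), edges.to_dict("records"))
    return graph, truth


def random_binary_graph(rng, n):
    """Random symmetric zero-diagonal binary adjacency as dense ndarray."""
    A = (rng.random((n, n)) < 0.35).astype(float)
    A = np.triu(A, 1)
    return A + A.T
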