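import numpy as np
import pytest

from drugraph.graph import CancerGraph, NodeAnnotation
from drugraph.simulate import SimConfig, worked_example_fixture, worked_example_tables, generate_dataset


@pytest.fixture(scope="session")
def worked_example():
    """The 13-node worked-example graph and its cluster table."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def raw_example_tables():
    """The worked example as raw omics tables plus the disease mapping."""
    return worked_example_tables()


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The planted-signal benchmark: ~475 reduced graphs over 5 tissues,
    with the ground-truth table.  Generated once per session (seed 1)."""
    graphs, truth = generate_dataset(SimConfig(), seed=1)
    return graphs, truth


def random_annotated_graph(rng: np.random.Generator, n_nodes: int = 30,
                           edge_p: float = 0.12, kinase_frac: float = 0.2):
    """A random annotated graph plus a random cluster map, for property tests."""
    names = [f"n{i:03d}" for i in range(n_nodes)]
    nodes = []
    for g in names:
        is_kin = rng.random() < kinase_frac
        nodes.append(
            NodeAnnotation(
                gene_id=g,
                is_kinase=is_kin,
                dge=["up", "down", "normal"][rng.integers(3)],
                dga_disease=round(float(rng.uniform(1, 10)), 2)
                if rng.random() < 0.4 else None,
                dga_disgenet=round(float(rng.uniform(0.01, 1)), 3)
                if rng.random() < 0.3 else None,
                pic50=round(float(rng.uniform(6.31, 10)), 2)
                if (is_kin and rng.random() < 0.5) else None,
            )
        )
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_p:
                edges[(names[i], names[j])] = float(rng.integers(500, 1001))
    clusters = {g: f"BP{rng.integers(4)}" for g in names}
    graph = CancerGraph(
        instance_id=(f"cl{rng.integers(100)}", "drugX"),
        tissue="skin",
        nodes=nodes,
        edges=edges,
        label=int(rng.integers(2)),
        min_confidence=500.0,
    )
    return graph, clusters
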