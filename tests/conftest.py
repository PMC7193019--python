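"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from dlslink import (
    BipartiteGraph,
    GeneratorConfig,
    worked_example,
    planted_graph,
    random_bipartite,
    strong_signal_config,
)


@pytest.fixture(scope="session")
def example():
    """Worked-example graph and its distinguished unconnected pair."""
    return worked_example()


@pytest.fixture(scope="session")
def small_random():
    """An 8x8 sparse random bipartite graph with a fixed seed."""
    return random_bipartite(
        GeneratorConfig(n_drugs=8, n_proteins=8, mode="density", density=0.2, seed=3)
    )


@pytest.fixture(scope="session")
def medium_random():
    """A 40x120 power-law graph, large enough for 10-fold evaluation."""
    return random_bipartite(
        GeneratorConfig(n_drugs=40, n_proteins=120, mode="powerlaw", n_edges=600, seed=11)
    )


@pytest.fixture(scope="session")
def strong_planted():
    """A planted-structure graph (training part) plus its held-out edges."""
    return planted_graph(strong_signal_config(seed=42))


@pytest.fixture
def path_graph() -> BipartiteGraph:
    """d1-p1-d2-p2: a single length-3 path between (d1, p2)."""
    return BipartiteGraph.from_edges([("d1", "p1"), ("d2", "p1"), ("d2", "p2")])
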