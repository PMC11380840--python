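import math
import random

import pytest

from netprio import PPINetwork, SyntheticScenario, generate_scenario

#: Toy fixture graph used throughout: degrees A=2 B=2 C=3 D=3 E=1 F=1.
G1_EDGES = [("A", "C"), ("B", "C"), ("A", "D"), ("B", "D"), ("D", "E"), ("C", "F")]


@pytest.fixture
def g1() -> PPINetwork:
    return PPINetwork.from_edges(G1_EDGES)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact two-disease synthetic study shared by slower tests."""
    scn = SyntheticScenario(
        n_nodes=300, attach_m=2,
        modules=((20, 0.7), (25, 0.7)),
        seed_fraction=0.3, validation_noise=0.3,
        n_terms=60, term_enrichment_bias=25.0, rng_seed=7,
    )
    return generate_scenario(scn)


def random_edge_list(rng: random.Random, n_nodes: int, p: float):
    """A random simple graph as an explicit edge list (for oracle tests)."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p
    ]
    return nodes, edges


class BruteForceIndices:
    """Independent oracle: materializes neighbor sets straight from an
    edge list and evaluates each index from its definition."""

    def __init__(self, edges):
        self.adj: dict[str, set[str]] = {}
        for x, y in edges:
            if x == y:
                continue
            self.adj.setdefault(x, set()).add(y)
            self.adj.setdefault(y, set()).add(x)

    def gamma(self, x):
        return self.adj.get(x, set())

    def pac(self, x, y):
        return len(self.gamma(x)) * len(self.gamma(y))

    def aa(self, x, y):
        return sum(1.0 / math.log(len(self.gamma(z)))
                   for z in self.gamma(x) & self.gamma(y))

    def jc(self, x, y):
        union = self.gamma(x) | self.gamma(y)
        return len(self.gamma(x) & self.gamma(y)) / len(union) if union else 0.0

    def rai(self, x, y):
        return sum(1.0 / len(self.gamma(z))
                   for z in self.gamma(x) & self.gamma(y))

    def score(self, index, x, y):
        return {"PAC": self.pac, "AA": self.aa, "JC": self.jc,
                "RAI": self.rai}[index](x, y)
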