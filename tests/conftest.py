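import math

import networkx as nx
import numpy as np
import pytest

from trireg.semantics import OntologyDAG

from trireg.network import RELATIONS, Edge, RegulatoryNetwork
from trireg.synthetic import GeneratorConfig, generate_bundle

#: desk-scale config for cheap unit tests (the default config is paper-scale)
SMALL_CONFIG = GeneratorConfig(
    n_tf=20, n_mirna=60, n_lncrna=120, n_edges=400,
    module_size=20, n_seeds=12, seed_purity=0.9,
    n_terms=40, ontology_depth=4, rng_seed=7,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_bundle():
    """Paper-scale synthetic bundle under the default study conditions."""
    return generate_bundle(GeneratorConfig())


def random_typed_network(rng: np.random.Generator, max_nodes: int = 20,
                         n_edges: int = 25) -> RegulatoryNetwork:
    """Small random network over the five allowed relation types."""
    pools = {
        "TF": [f"TF{i}" for i in range(max(2, max_nodes // 4))],
        "miRNA": [f"M{i}" for i in range(max(2, max_nodes // 3))],
        "lncRNA": [f"L{i}" for i in range(max(2, max_nodes // 3))],
    }
    relations = sorted(RELATIONS)
    edges = set()
    for _ in range(n_edges * 4):
        if len(edges) >= n_edges:
            break
        rel = relations[rng.integers(0, len(relations))]
        sk, tk = RELATIONS[rel]
        src = pools[sk][rng.integers(0, len(pools[sk]))]
        tgt = pools[tk][rng.integers(0, len(pools[tk]))]
        edges.add(Edge(src, tgt, rel))
    return RegulatoryNetwork(edges)


def rwr_linear_solve(W, p0, alpha):
    """Closed-form stationary vector: p = alpha (I - (1-alpha) W^T)^-1 p0.

    Independent oracle for the iterative engine (dense solve).
    """
    n = len(p0)
    A = np.eye(n) - (1 - alpha) * W.W.toarray().T
    return alpha * np.linalg.solve(A, p0)


def make_dag(edges, namespaces=None):
    """OntologyDAG from (child, parent, relation) triples."""
    g = nx.MultiDiGraph()
    for child, parent, rel in edges:
        g.add_edge(child, parent, key=rel)
    for n in g.nodes:
        g.nodes[n]["namespace"] = (namespaces or {}).get(n, "biological_process")
    return OntologyDAG(g)


def brute_force_hypergeom_tail(N, K, n, k):
    """P(X >= k) for a hypergeometric draw, by explicit summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def pairwise_auc(scores, labels):
    """Mann-Whitney AUC by double loop: fraction of (positive, negative)
    pairs with the positive scored higher, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
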