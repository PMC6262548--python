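"""Functional analysis: over-representation and ontology semantic similarity.

Enrichment is a one-sided hypergeometric test per term, run after
propagating annotations up the ontology (true-path rule). Term–term
similarity follows the Wang graph-based measure: each term contributes
semantic values to its ancestors with multiplicative decay along is_a
(0.8) and part_of (0.6) edges, and two terms are compared through their
shared ancestors. Term *sets* are combined with the rcmax rule — the
larger of the two best-match directional averages — and significance is
assessed by drawing random term sets of the same size and counting how
often the null score exceeds the real one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "OntologyDAG",
    "AnnotationTable",
    "EnrichmentResult",
    "SimilarityScore",
    "read_obo",
    "read_annotations",
    "enrich",
    "term_similarity",
    "setsim_rcmax",
    "permutation_test",
    "WANG_WEIGHTS",
]

WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


class OntologyError(ValueError):
    pass


@dataclass
class OntologyDAG:
    """Term DAG with child→parent edges typed is_a / part_of.

    ``graph`` orients edges child→parent, so ancestors of a term are its
    descendants in graph direction. One root per namespace is expected.
    """

    graph: nx.MultiDiGraph
    _svalue_cache: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for _, _, rel in self.graph.edges(keys=True):
            if rel not in WANG_WEIGHTS:
                raise OntologyError(f"unsupported edge type {rel!r}")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyError("ontology graph is cyclic")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph, term)

    def svalues(self, term: str) -> dict[str, float]:
        """Wang semantic contributions of ``term`` to itself (1.0) and its
        ancestors, decaying multiplicatively along the best path."""
        cached = self._svalue_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.graph:
            raise OntologyError(f"unknown term {term!r}")
        anc = self.ancestors(term) | {term}
        sub = self.graph.subgraph(anc)
        s: dict[str, float] = {term: 1.0}
        for t in nx.topological_sort(sub):  # children before parents
            st = s.get(t)
            if st is None:
                continue
            for _, parent, rel in sub.out_edges(t, keys=True):
                cand = WANG_WEIGHTS[rel] * st
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        self._svalue_cache[term] = s
        return s


def read_obo(path) -> OntologyDAG:
    """Parse an OBO 1.2 ontology; keeps is_a/part_of edges, drops obsolete
    terms and any other relationship types."""
    raw = obonet.read_obo(path)  # obsolete terms excluded by default
    g = nx.MultiDiGraph()
    for node, data in raw.nodes(data=True):
        g.add_node(node, **{k: data[k] for k in ("name", "namespace") if k in data})
    for child, parent, rel in raw.edges(keys=True):
        if rel in WANG_WEIGHTS:
            g.add_edge(child, parent, key=rel)
    return OntologyDAG(g)


@dataclass
class AnnotationTable:
    """Gene→term annotations over a background universe.

    ``propagated`` applies the true-path rule: a gene annotated to a term
    is implicitly annotated to every ancestor of that term.
    """

    direct: dict[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        dag: OntologyDAG,
        universe: Iterable[str] | None = None,
    ) -> "AnnotationTable":
        direct: dict[str, set[str]] = {}
        for gene, term in pairs:
            if term not in dag.terms:
                raise OntologyError(f"annotation to unknown term {term!r}")
            direct.setdefault(gene, set()).add(term)
        uni = frozenset(universe) if universe is not None else frozenset(direct)
        return cls({g: frozenset(t) for g, t in direct.items()}, uni)

    def propagated(self, dag: OntologyDAG) -> dict[str, frozenset[str]]:
        out = {}
        anc_cache: dict[str, set[str]] = {}
        for gene, terms in self.direct.items():
            full: set[str] = set()
            for t in terms:
                if t not in anc_cache:
                    anc_cache[t] = dag.ancestors(t) | {t}
                full |= anc_cache[t]
            out[gene] = frozenset(full)
        return out

    def annotated_terms(self, dag: OntologyDAG, namespace: str | None = None) -> list[str]:
        """Terms with at least one (direct) annotation, optionally limited
        to one namespace; sorted for reproducible sampling."""
        used = set().union(*self.direct.values()) if self.direct else set()
        if namespace is not None:
            used = {t for t in used if dag.namespace(t) == namespace}
        return sorted(used)


def read_annotations(path, dag: OntologyDAG,
                     universe: Iterable[str] | None = None) -> AnnotationTable:
    """Two-column TSV (gene, term). GAF 2.x is also accepted: lines starting
    with '!' are skipped and columns 2 and 5 (DB object id, GO id) are used."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            fields = line.split("\t")
            if len(fields) >= 5 and fields[4].startswith(("GO:", "T:")):
                pairs.append((fields[1], fields[4]))
            elif len(fields) >= 2:
                pairs.append((fields[0], fields[1]))
            else:
                raise OntologyError(f"malformed annotation line: {line!r}")
    if pairs and pairs[0] == ("gene", "term"):
        pairs = pairs[1:]
    return AnnotationTable.from_pairs(pairs, dag, universe=universe)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame   # term, overlap, term_size, expected, p_value[, p_bh]
    significant: list[str]
    threshold: float


def enrich(
    query: Iterable[str],
    annotations: AnnotationTable,
    dag: OntologyDAG,
    threshold: float = 0.05,
    bh_correct: bool = False,
) -> EnrichmentResult:
    """One-sided hypergeometric over-representation per term.

    Tests every term with at least one query overlap, after true-path
    propagation. P(X ≥ k) with population = universe size, successes =
    genes annotated to the term, draws = query size. The significant set
    uses the raw p-value cutoff unless ``bh_correct`` applies a
    Benjamini–Hochberg adjustment first.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    extra = query - annotations.universe
    if extra:
        raise ValueError(f"query genes outside the background universe: {sorted(extra)[:5]}")
    prop = annotations.propagated(dag)
    term_genes: dict[str, set[str]] = {}
    for gene in annotations.universe:
        for t in prop.get(gene, ()):
            term_genes.setdefault(t, set()).add(gene)
    N = len(annotations.universe)
    n = len(query)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        k = len(query & genes)
        if k == 0:
            continue
        K = len(genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, K * n / N, p))
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size",
                                        "expected", "p_value"])
    pcol = "p_value"
    if bh_correct and len(table):
        p = table["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        table["p_bh"] = np.minimum(adj, 1.0)
        pcol = "p_bh"
    significant = table.loc[table[pcol] < threshold, "term"].tolist() if len(table) else []
    return EnrichmentResult(table=table.sort_values("p_value", ignore_index=True),
                            significant=significant, threshold=threshold)


def term_similarity(t1: str, t2: str, dag: OntologyDAG) -> float:
    """Wang similarity between two terms of the same namespace:
    Σ over shared ancestors of (S₁ + S₂) / (SV(t1) + SV(t2)), with the
    S-values decaying 0.8 per is_a and 0.6 per part_of edge."""
    ns1, ns2 = dag.namespace(t1), dag.namespace(t2)
    if ns1 != ns2:
        raise OntologyError(f"terms {t1!r} and {t2!r} are in different namespaces")
    s1 = dag.svalues(t1)
    s2 = dag.svalues(t2)
    shared = set(s1) & set(s2)
    if not shared:
        return 0.0
    num = sum(s1[t] + s2[t] for t in shared)
    return num / (sum(s1.values()) + sum(s2.values()))


@dataclass
class SimilarityScore:
    score: float
    method: str = "wang/rcmax"
    p_value: float | None = None
    null_scores: list[float] = field(default_factory=list)


def setsim_rcmax(
    set1: Iterable[str], set2: Iterable[str], dag: OntologyDAG
) -> SimilarityScore:
    """rcmax combination of the pairwise Wang similarity matrix:
    max(mean over rows of the row maxima, mean over columns of the column
    maxima). Equal sets — and supersets on the saturated side — score 1."""
    s1, s2 = sorted(set(set1)), sorted(set(set2))
    if not s1 or not s2:
        raise ValueError("term sets must be non-empty")
    M = np.array([[term_similarity(a, b, dag) for b in s2] for a in s1])
    score = float(max(M.max(axis=1).mean(), M.max(axis=0).mean()))
    return SimilarityScore(score=score)


def permutation_test(
    real_set: Iterable[str],
    reference_set: Iterable[str],
    dag: OntologyDAG,
    annotations: AnnotationTable,
    n_reps: int = 1000,
    rng: np.random.Generator | int | None = None,
    namespace: str | None = None,
) -> SimilarityScore:
    """Randomization significance for a set-similarity score.

    Each replicate draws |real_set| terms uniformly (without replacement)
    from the namespace's annotated terms and scores them against the
    reference set with rcmax. The empirical p is the fraction of null
    scores *strictly greater* than the real score, so ties do not count
    against it and p = 0 is possible; with n_reps = 0 the p-value is
    reported as absent.
    """
    real_set = sorted(set(real_set))
    rng = np.random.default_rng(rng)
    if namespace is None and real_set:
        namespace = dag.namespace(real_set[0])
    pool = np.array(annotations.annotated_terms(dag, namespace=namespace))
    if len(real_set) > len(pool):
        raise ValueError("real set larger than the pool of annotated terms")
    real = setsim_rcmax(real_set, reference_set, dag)
    if n_reps == 0:
        return SimilarityScore(score=real.score, p_value=None)
    null_scores = []
    for _ in range(n_reps):
        draw = rng.choice(pool, size=len(real_set), replace=False)
        null_scores.append(setsim_rcmax(draw, reference_set, dag).score)
    p = sum(s > real.score for s in null_scores) / n_reps
    return SimilarityScore(score=real.score, p_value=p, null_scores=null_scores)
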