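"""Typed directed regulatory networks over TFs, miRNAs and lncRNAs.

The network admits exactly five relation types — TF→miRNA, TF→lncRNA,
miRNA→lncRNA, miRNA→TF and lncRNA→TF — mirroring the transcriptional and
post-transcriptional regulation layers that databases such as TransmiR,
ChIPBase, miRTarBase/miRecords, LncBase and LncReg/LncRNA2Target record.
Every relation joins two *different* node kinds, so the graph is tripartite
and self-loops cannot arise.

This module covers parsing and filtering of per-relation edge tables,
merging edge sets by union or intersection, induced subnetworks by node
kind, topology characterization (degree tallies, per-kind medians,
log–log power-law fits) and degree-preserving randomization within each
relation class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "KINDS",
    "RELATIONS",
    "Edge",
    "FilterSpec",
    "RegulatoryNetwork",
    "TopologySummary",
    "PowerLawFit",
    "read_edge_table",
    "read_alias_table",
    "merge_networks",
    "subnetwork",
    "topology_summary",
    "degree_preserving_randomize",
    "write_network",
    "read_network",
]

KINDS = ("TF", "miRNA", "lncRNA")

#: relation name -> (source kind, target kind)
RELATIONS: Mapping[str, tuple[str, str]] = {
    "TF->miRNA": ("TF", "miRNA"),
    "TF->lncRNA": ("TF", "lncRNA"),
    "miRNA->lncRNA": ("miRNA", "lncRNA"),
    "miRNA->TF": ("miRNA", "TF"),
    "lncRNA->TF": ("lncRNA", "TF"),
}


class NetworkError(ValueError):
    """Validation failure while building or merging a network."""


@dataclass(frozen=True, order=True)
class Edge:
    """One directed, typed regulation.

    ``support`` carries either a dataset count or a prediction score,
    depending on the source table; it is not part of edge identity.
    """

    source: str
    target: str
    relation: str
    support: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise NetworkError(
                f"unknown relation {self.relation!r}; allowed: {sorted(RELATIONS)}"
            )
        if not self.source or not self.target:
            raise NetworkError("edge endpoints must be non-empty identifiers")
        if self.source == self.target:
            raise NetworkError(f"self-edge {self.source!r} is not a valid regulation")
        if self.support is not None and self.support < 0:
            raise NetworkError(f"negative support on edge {self.source}->{self.target}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.relation)

    @property
    def source_kind(self) -> str:
        return RELATIONS[self.relation][0]

    @property
    def target_kind(self) -> str:
        return RELATIONS[self.relation][1]


@dataclass(frozen=True)
class FilterSpec:
    """Edge filter applied while reading a table.

    mode ``none`` keeps everything; ``support_count`` keeps edges with
    support strictly greater than ``threshold`` (dataset counts, e.g.
    "identified in more than 20 datasets" → threshold 20);
    ``support_score`` keeps edges with support greater than or equal to
    ``threshold`` (prediction scores, e.g. score ≥ 0.95).
    """

    mode: str = "none"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "support_count", "support_score"):
            raise NetworkError(f"unknown filter mode {self.mode!r}")

    def accepts(self, support: float | None) -> bool:
        if self.mode == "none":
            return True
        if support is None:
            raise NetworkError(
                f"filter {self.mode} requires a support column, but a row lacks it"
            )
        if self.mode == "support_count":
            return support > self.threshold
        return support >= self.threshold


def _node_kinds_from_edges(edges: Iterable[Edge]) -> dict[str, str]:
    kinds: dict[str, str] = {}
    conflicts: set[str] = set()
    for e in edges:
        for nid, kind in ((e.source, e.source_kind), (e.target, e.target_kind)):
            prev = kinds.setdefault(nid, kind)
            if prev != kind:
                conflicts.add(nid)
    if conflicts:
        raise NetworkError(
            "conflicting node kinds for ids: " + ", ".join(sorted(conflicts))
        )
    return kinds


class RegulatoryNetwork:
    """Directed tripartite regulatory network with a fixed node ordering.

    Nodes are ordered lexicographically by id, so the adjacency matrix and
    every probability vector derived from it are reproducible across runs.
    """

    def __init__(
        self,
        edges: Iterable[Edge],
        extra_nodes: Mapping[str, str] | None = None,
    ) -> None:
        self.edges: tuple[Edge, ...] = tuple(
            sorted(set(edges), key=lambda e: e.key)
        )
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            if e.key in seen:  # pragma: no cover - set() above dedups
                raise NetworkError(f"duplicate edge {e.key}")
            seen.add(e.key)
        kinds = _node_kinds_from_edges(self.edges)
        if extra_nodes:
            for nid, kind in extra_nodes.items():
                if kind not in KINDS:
                    raise NetworkError(f"unknown node kind {kind!r} for {nid!r}")
                prev = kinds.setdefault(nid, kind)
                if prev != kind:
                    raise NetworkError(
                        f"conflicting node kinds for ids: {nid}"
                    )
        self.kinds: dict[str, str] = kinds
        self.node_order: tuple[str, ...] = tuple(sorted(kinds))
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.node_order)}
        self._adjacency: sp.csr_matrix | None = None

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.node_order)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.kinds

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.kinds == other.kinds
            and {e.key for e in self.edges} == {e.key for e in other.edges}
        )

    def __repr__(self) -> str:
        by_kind = self.node_counts()
        return (
            f"RegulatoryNetwork({len(self)} nodes "
            f"[{by_kind.get('TF', 0)} TF, {by_kind.get('miRNA', 0)} miRNA, "
            f"{by_kind.get('lncRNA', 0)} lncRNA], {len(self.edges)} edges)"
        )

    def node_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in KINDS}
        for kind in self.kinds.values():
            counts[kind] += 1
        return counts

    def edge_counts_by_relation(self) -> dict[str, int]:
        counts = {r: 0 for r in RELATIONS}
        for e in self.edges:
            counts[e.relation] += 1
        return counts

    def adjacency(self) -> sp.csr_matrix:
        """Binary |V|×|V| adjacency; A[i, j] = 1 iff edge i→j exists."""
        if self._adjacency is None:
            n = len(self)
            rows = [self.index[e.source] for e in self.edges]
            cols = [self.index[e.target] for e in self.edges]
            data = np.ones(len(rows))
            self._adjacency = sp.csr_matrix(
                (data, (rows, cols)), shape=(n, n), dtype=float
            )
        return self._adjacency

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel().astype(int)

    def in_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=0)).ravel().astype(int)


def read_edge_table(
    path,
    relation: str,
    filter_spec: FilterSpec | None = None,
    aliases: Mapping[str, str] | None = None,
) -> set[Edge]:
    """Read one per-relation TSV (columns ``source``, ``target``, optional
    ``support``) and return the edges passing ``filter_spec``.

    Node kinds are implied by ``relation``; ``aliases`` optionally maps raw
    identifiers to canonical symbols before edge construction.
    """
    if relation not in RELATIONS:
        raise NetworkError(f"unknown relation {relation!r}")
    filter_spec = filter_spec or FilterSpec()
    try:
        df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    except Exception as exc:  # surface the path in parse failures
        raise NetworkError(f"cannot parse edge table {path}: {exc}") from exc
    for col in ("source", "target"):
        if col not in df.columns:
            raise NetworkError(f"{path}: missing required column {col!r}")
    has_support = "support" in df.columns
    edges: set[Edge] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        src, tgt = row.source, row.target
        if pd.isna(src) or pd.isna(tgt) or not str(src) or not str(tgt):
            raise NetworkError(f"{path}: malformed row at line {i}")
        support = None
        if has_support and not pd.isna(row.support):
            support = float(row.support)
        if aliases:
            src = aliases.get(src, src)
            tgt = aliases.get(tgt, tgt)
        if not filter_spec.accepts(support):
            continue
        edges.add(Edge(str(src), str(tgt), relation, support))
    return edges


def read_alias_table(path) -> dict[str, str]:
    """Two-column TSV (alias, canonical) for identifier harmonization."""
    df = pd.read_csv(path, sep="\t", header=None, names=["alias", "canonical"],
                     dtype=str)
    return dict(zip(df["alias"], df["canonical"]))


def merge_networks(
    edge_sets: Sequence[Iterable[Edge]], combine: str = "union"
) -> RegulatoryNetwork:
    """Merge per-source edge sets into one network.

    ``union`` deduplicates (source, target, relation) triples across sets;
    ``intersection`` keeps only triples present in every set (used when two
    evidence sources must agree, e.g. ChIP-derived edges confirmed by a
    binding-site scan). Conflicting node kinds abort with the offending ids.
    """
    if not edge_sets:
        raise NetworkError("merge requires at least one edge set")
    if combine not in ("union", "intersection"):
        raise NetworkError(f"unknown combine mode {combine!r}")
    sets = [{e.key: e for e in s} for s in edge_sets]
    if combine == "union":
        merged: dict[tuple, Edge] = {}
        for s in sets:
            merged.update(s)
    else:
        common = set(sets[0])
        for s in sets[1:]:
            common &= set(s)
        merged = {k: sets[0][k] for k in common}
    return RegulatoryNetwork(merged.values())


def subnetwork(net: RegulatoryNetwork, kinds: Iterable[str]) -> RegulatoryNetwork:
    """Induced subgraph on the requested node kinds.

    Isolated nodes are retained so that candidate sets stay comparable
    across partial networks (e.g. the miRNA+lncRNA or TF+miRNA views).
    """
    kinds = set(kinds)
    unknown = kinds - set(KINDS)
    if unknown:
        raise NetworkError(f"unknown node kinds: {sorted(unknown)}")
    if not kinds:
        raise NetworkError("kinds must be non-empty")
    keep_nodes = {n: k for n, k in net.kinds.items() if k in kinds}
    edges = [
        e for e in net.edges if e.source in keep_nodes and e.target in keep_nodes
    ]
    return RegulatoryNetwork(edges, extra_nodes=keep_nodes)


@dataclass(frozen=True)
class PowerLawFit:
    """y = a · x^b fitted by OLS of log10(frequency) on log10(value)."""

    a: float
    b: float
    r2: float


@dataclass
class TopologySummary:
    degree: pd.Series        # per-node total degree, indexed by node id
    in_degree: pd.Series
    out_degree: pd.Series
    kind_medians: pd.DataFrame  # index kind, columns in_degree/out_degree
    fits: dict[str, PowerLawFit | None]  # keys degree/in_degree/out_degree

    @property
    def degree_one_fraction(self) -> float:
        return float((self.degree == 1).mean())

    def degree_histogram(self) -> pd.Series:
        return self.degree.value_counts().sort_index()


def fit_power_law(values: np.ndarray) -> PowerLawFit | None:
    """OLS fit of log10(frequency) against log10(value) over the raw
    (unbinned) histogram, using only strictly positive values with
    frequency ≥ 1. Returns None when fewer than two distinct positive
    values exist (fit undefined)."""
    values = np.asarray(values)
    vals, counts = np.unique(values[values > 0], return_counts=True)
    if len(vals) < 2:
        return None
    x = np.log10(vals)
    y = np.log10(counts)
    b, loga = np.polyfit(x, y, 1)
    yhat = loga + b * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return PowerLawFit(a=float(10 ** loga), b=float(b), r2=r2)


def topology_summary(net: RegulatoryNetwork) -> TopologySummary:
    """Degree tallies, per-kind medians and log–log power-law fits."""
    if len(net) < 2:
        raise NetworkError("topology summary requires at least 2 nodes")
    idx = pd.Index(net.node_order, name="node")
    ind = pd.Series(net.in_degrees(), index=idx, name="in_degree")
    outd = pd.Series(net.out_degrees(), index=idx, name="out_degree")
    deg = (ind + outd).rename("degree")
    kind = pd.Series({n: net.kinds[n] for n in net.node_order}, name="kind")
    medians = (
        pd.DataFrame({"in_degree": ind, "out_degree": outd, "kind": kind})
        .groupby("kind")[["in_degree", "out_degree"]]
        .median()
    )
    fits = {
        "degree": fit_power_law(deg.to_numpy()),
        "in_degree": fit_power_law(ind.to_numpy()),
        "out_degree": fit_power_law(outd.to_numpy()),
    }
    return TopologySummary(deg, ind, outd, medians, fits)


def degree_preserving_randomize(
    net: RegulatoryNetwork,
    n_swaps: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> RegulatoryNetwork:
    """Rewire by double-edge swaps performed within each relation class.

    A swap picks two edges a→b, c→d of the same relation and replaces them
    with a→d, c→b; attempts that would duplicate an existing edge are
    rejected (self-loops cannot arise because every relation joins two
    different kinds). Every node's in- and out-degree within every relation
    class — hence globally — is preserved exactly. ``n_swaps`` counts
    attempted swaps (default 10·|E|); each attempt draws a relation class
    with probability proportional to its edge count. A class with fewer
    than 2 edges is left unchanged.
    """
    rng = np.random.default_rng(rng)
    if n_swaps is None:
        n_swaps = 10 * len(net.edges)
    if n_swaps < 0:
        raise NetworkError("n_swaps must be >= 0")

    by_rel: dict[str, list[tuple[str, str]]] = {r: [] for r in RELATIONS}
    for e in net.edges:
        by_rel[e.relation].append((e.source, e.target))
    swappable = [r for r in RELATIONS if len(by_rel[r]) >= 2]
    if swappable and n_swaps > 0:
        weights = np.array([len(by_rel[r]) for r in swappable], dtype=float)
        weights /= weights.sum()
        class_draws = rng.choice(len(swappable), size=n_swaps, p=weights)
        existing = {r: set(map(tuple, by_rel[r])) for r in swappable}
        for ci in class_draws:
            rel = swappable[ci]
            edges = by_rel[rel]
            i, j = rng.integers(0, len(edges), size=2)
            if i == j:
                continue
            (a, b), (c, d) = edges[i], edges[j]
            if b == d or a == c:
                continue  # swap would be a no-op
            if (a, d) in existing[rel] or (c, b) in existing[rel]:
                continue
            existing[rel].discard((a, b))
            existing[rel].discard((c, d))
            existing[rel].add((a, d))
            existing[rel].add((c, b))
            edges[i], edges[j] = (a, d), (c, b)
    new_edges = [
        Edge(s, t, rel)
        for rel, pairs in by_rel.items()
        for (s, t) in pairs
    ]
    return RegulatoryNetwork(new_edges, extra_nodes=net.kinds)


def write_network(net: RegulatoryNetwork, path) -> None:
    """Serialize as TSV: source, source_kind, target, target_kind, relation."""
    rows = [
        (e.source, e.source_kind, e.target, e.target_kind, e.relation)
        for e in net.edges
    ]
    df = pd.DataFrame(
        rows, columns=["source", "source_kind", "target", "target_kind", "relation"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_network(path) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", dtype=str)
    edges = [
        Edge(r.source, r.target, r.relation) for r in df.itertuples(index=False)
    ]
    return RegulatoryNetwork(edges)
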