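"""Synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates the regime of a curated TF/miRNA/lncRNA regulatory
network: sparse (|E| ≈ 2·|V|), lncRNA-heavy, approximately scale-free with
TF hubs, restricted to the five cross-kind relation types. A planted
module — a subset of nodes with boosted mutual connectivity, enriched for
TFs and miRNAs the way known autophagy regulators are — stands in for the
neighborhood of true regulators; seed lists are drawn mostly from it. A
toy is_a ontology with clade-biased annotations supports the functional
analysis stage: module genes draw their terms preferentially from one
designated clade, so enrichment and semantic-similarity signal is planted
by construction.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .network import KINDS, RELATIONS, Edge, RegulatoryNetwork, read_edge_table
from .semantics import AnnotationTable, OntologyDAG, read_obo
import networkx as nx

__all__ = [
    "GeneratorConfig",
    "SyntheticBundle",
    "generate_network",
    "generate_seeds",
    "generate_ontology",
    "generate_bundle",
    "write_bundle",
    "read_bundle",
    "EDGE_FILE_NAMES",
]

#: relation -> TSV file name used by write_bundle/read_bundle
EDGE_FILE_NAMES = {
    "TF->miRNA": "edges_tf_mirna.tsv",
    "TF->lncRNA": "edges_tf_lncrna.tsv",
    "miRNA->lncRNA": "edges_mirna_lncrna.tsv",
    "miRNA->TF": "edges_mirna_tf.tsv",
    "lncRNA->TF": "edges_lncrna_tf.tsv",
}

#: module kind composition: fraction of module nodes per kind. The module
#: emulates the known-regulator neighborhood, which is TF/miRNA-centric
#: (lncRNA–lncRNA pairs admit no relation type, so a module must be rich in
#: TFs and miRNAs to be densely interlinkable).
MODULE_KIND_FRACTIONS = {"TF": 0.25, "miRNA": 0.50, "lncRNA": 0.25}


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic bundle.

    Node counts mirror the curated network's kind ratios (155 TF : 681
    miRNA : 1332 lncRNA) and edge count (~4,500); the planted module of 60
    nodes with an 8× density boost and 40 seeds at 0.9 purity is the
    desk-scale analogue of a real seed set concentrated around true
    regulators.
    """

    n_tf: int = 155
    n_mirna: int = 681
    n_lncrna: int = 1332
    n_edges: int = 4500
    gamma_bias: float = 1.0
    module_size: int = 60
    module_density_boost: float = 8.0
    n_seeds: int = 40
    seed_purity: float = 0.9
    n_terms: int = 150
    ontology_depth: int = 5
    annotation_rate: float = 3.0
    module_term_bias: float = 20.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_lncrna", "n_edges", "module_size",
                     "n_seeds", "n_terms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.seed_purity <= 1:
            raise ValueError("seed_purity must lie in [0, 1]")
        if self.gamma_bias < 0:
            raise ValueError("gamma_bias must be >= 0")
        if self.module_density_boost < 1:
            raise ValueError("module_density_boost must be >= 1")
        total = self.n_tf + self.n_mirna + self.n_lncrna
        if self.module_size > total:
            raise ValueError("module_size exceeds total node count")
        if self.seed_purity > 0 and self.n_seeds > self.module_size / self.seed_purity:
            raise ValueError("n_seeds exceeds module_size / seed_purity")
        if self.ontology_depth < 2 or self.n_terms < self.ontology_depth:
            raise ValueError("need n_terms >= ontology_depth >= 2")

    @property
    def n_nodes(self) -> int:
        return self.n_tf + self.n_mirna + self.n_lncrna


@dataclass
class SyntheticBundle:
    network: RegulatoryNetwork
    seeds: list[str]
    module: frozenset[str]
    ontology: OntologyDAG
    annotations: AnnotationTable
    config: GeneratorConfig


def _node_ids(cfg: GeneratorConfig) -> dict[str, list[str]]:
    return {
        "TF": [f"TF{i:04d}" for i in range(1, cfg.n_tf + 1)],
        "miRNA": [f"MIR{i:04d}" for i in range(1, cfg.n_mirna + 1)],
        "lncRNA": [f"LNC{i:04d}" for i in range(1, cfg.n_lncrna + 1)],
    }


def _pick_module(cfg: GeneratorConfig, ids: dict[str, list[str]],
                 rng: np.random.Generator) -> frozenset[str]:
    # largest-remainder allocation of module slots to kinds
    raw = {k: cfg.module_size * MODULE_KIND_FRACTIONS[k] for k in KINDS}
    alloc = {k: min(int(raw[k]), len(ids[k])) for k in KINDS}
    while sum(alloc.values()) < cfg.module_size:
        rem = sorted(KINDS, key=lambda k: raw[k] - alloc[k], reverse=True)
        for k in rem:
            if alloc[k] < len(ids[k]):
                alloc[k] += 1
                break
        else:  # pragma: no cover - config validation prevents this
            raise GenerationError("module_size exceeds available nodes")
    module: set[str] = set()
    for k in KINDS:
        module |= set(rng.choice(ids[k], size=alloc[k], replace=False))
    return frozenset(module)


def _within_module_share(cfg: GeneratorConfig, ids, module) -> float:
    """Expected fraction of edges with both endpoints in the module, at
    boost-times the odds of the baseline typed random graph."""
    fracs = []
    counts = {k: sum(1 for n in ids[k] if n in module) for k in KINDS}
    for sk, tk in RELATIONS.values():
        fracs.append((counts[sk] / len(ids[sk])) * (counts[tk] / len(ids[tk])))
    q0 = float(np.mean(fracs))
    b = cfg.module_density_boost
    return b * q0 / (1.0 - q0 + b * q0)


def generate_network(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[RegulatoryNetwork, frozenset[str]]:
    """Typed directed network: scale-free background plus a planted module.

    Background edges are added one at a time: a relation type drawn
    uniformly from the five, then a source and a target of the required
    kinds with probability proportional to (current degree + 1)^gamma_bias.

    The planted module is a degree-corrected planted-partition overlay: a
    fixed internal-edge quota — the boosted within-module share,
    boost·q/(1−q+boost·q) of n_edges, where q is the within-module edge
    probability of the un-boosted typed random graph — is placed among
    module members only. Each internal edge targets a currently
    least-covered module node (co-functional neighborhoods are mutually
    interlinked rather than hub-dominated; the testable signal is that
    module members are mutually proximal), with a compatible relation and
    a uniform module source. With module_density_boost = 1 the overlay is
    skipped and the network is the plain typed random graph. Duplicates
    are rejected; self-loops cannot occur because every relation joins
    two different kinds.

    The overlay is degree-corrected: background proposals touching a
    module node are thinned by the factor that makes the module's expected
    total degree match the population (internal edges replace background
    links rather than adding to them). The planted signal is therefore
    purely positional — mutual proximity of module members — and is
    destroyed by degree-preserving rewiring, which is what makes the
    rewired network a sound null model for it.
    """
    rng = np.random.default_rng(cfg.rng_seed if rng is None else rng)
    ids = _node_ids(cfg)
    module = _pick_module(cfg, ids, rng)
    degree = {k: np.zeros(len(ids[k])) for k in KINDS}
    in_module = {k: np.array([n in module for n in ids[k]]) for k in KINDS}
    module_idx = {k: np.where(in_module[k])[0] for k in KINDS}
    node_pos = {k: {n: i for i, n in enumerate(ids[k])} for k in KINDS}
    kind_of = {n: k for k in KINDS for n in ids[k]}
    relations = sorted(RELATIONS)
    rel_by_target = {
        k: [r for r in relations if RELATIONS[r][1] == k] for k in KINDS
    }
    existing: set[tuple[str, str, str]] = set()
    edges: list[Edge] = []

    plant_module = cfg.module_density_boost > 1 and len(module) >= 2
    n_within = (
        round(cfg.n_edges * _within_module_share(cfg, ids, module))
        if plant_module else 0
    )
    n_background = cfg.n_edges - n_within
    # degree correction: module endpoints keep only the share of background
    # attachment not already provided by the internal quota
    per_member_internal = n_within / len(module) if module else 0.0
    per_node_background = cfg.n_edges / cfg.n_nodes  # expected in- (= out-) degree
    keep_module_endpoint = max(0.0, 1.0 - per_member_internal / per_node_background)

    # --- background: preferential-attachment typed random graph ----------
    def draw(kind: str) -> int:
        w = (degree[kind] + 1.0) ** cfg.gamma_bias
        c = np.cumsum(w)
        return int(np.searchsorted(c, rng.random() * c[-1], side="right"))

    max_attempts = 2000 * cfg.n_edges
    attempts = 0
    while len(edges) < n_background:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {cfg.n_edges} edges after {attempts} attempts; "
                "a relation class may be saturated"
            )
        rel = relations[rng.integers(0, len(relations))]
        sk, tk = RELATIONS[rel]
        si = draw(sk)
        ti = draw(tk)
        if plant_module and in_module[sk][si] and in_module[tk][ti]:
            continue  # module pairs are filled by the overlay quota
        if plant_module and in_module[sk][si] and rng.random() >= keep_module_endpoint:
            continue
        if plant_module and in_module[tk][ti] and rng.random() >= keep_module_endpoint:
            continue
        src, tgt = ids[sk][si], ids[tk][ti]
        if (src, tgt, rel) in existing:
            continue
        existing.add((src, tgt, rel))
        edges.append(Edge(src, tgt, rel))
        degree[sk][si] += 1
        degree[tk][ti] += 1

    # --- planted-module overlay: cover least-linked members --------------
    internal_in = {n: 0 for n in sorted(module)}
    placed = 0
    attempts = 0
    while placed < n_within:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                "planted-module overlay saturated before reaching its quota"
            )
        low = min(internal_in.values())
        pool = sorted(n for n, c in internal_in.items() if c == low)
        tgt = str(rng.choice(pool))
        tk = kind_of[tgt]
        rel_opts = [
            r for r in rel_by_target[tk]
            if len(module_idx[RELATIONS[r][0]]) > 0
        ]
        if not rel_opts:
            internal_in.pop(tgt)  # no module source kind can feed it
            if not internal_in:
                raise GenerationError("module has no feedable members")
            continue
        rel = rel_opts[rng.integers(0, len(rel_opts))]
        sk = RELATIONS[rel][0]
        si = int(rng.choice(module_idx[sk]))
        src = ids[sk][si]
        if src == tgt or (src, tgt, rel) in existing:
            continue
        existing.add((src, tgt, rel))
        edges.append(Edge(src, tgt, rel))
        degree[sk][si] += 1
        degree[tk][node_pos[tk][tgt]] += 1
        internal_in[tgt] += 1
        placed += 1

    extra = {n: k for k in KINDS for n in ids[k]}
    return RegulatoryNetwork(edges, extra_nodes=extra), module


def generate_seeds(
    module: frozenset[str],
    all_nodes: list[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Sample round(purity·n_seeds) seeds from the module and the remainder
    from outside it, without replacement."""
    rng = np.random.default_rng(cfg.rng_seed + 1 if rng is None else rng)
    n_mod = round(cfg.seed_purity * cfg.n_seeds)
    n_out = cfg.n_seeds - n_mod
    mod_pool = sorted(module)
    out_pool = sorted(set(all_nodes) - module)
    if n_mod > len(mod_pool):
        raise GenerationError("module too small for the requested seed count")
    if n_out > len(out_pool):
        raise GenerationError("not enough non-module nodes for seeds")
    seeds = list(rng.choice(mod_pool, size=n_mod, replace=False))
    if n_out:
        seeds += list(rng.choice(out_pool, size=n_out, replace=False))
    return sorted(seeds)


def generate_ontology(
    genes: list[str],
    module_genes: frozenset[str],
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> tuple[OntologyDAG, AnnotationTable]:
    """Random rooted is_a DAG plus clade-biased annotations.

    Terms are laid out in levels under a single root; each term takes one
    or two parents from the level above, guaranteeing acyclicity. One
    child of the root is designated the *module clade*: module genes draw
    their terms with weight ``module_term_bias`` on clade terms, so the
    module shares terms the way co-functional genes do.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2 if rng is None else rng)
    n_terms, depth = cfg.n_terms, cfg.ontology_depth
    terms = [f"T:{i:07d}" for i in range(1, n_terms + 1)]
    root = terms[0]
    # geometric level sizes: at least one term per level below the root
    levels: list[list[str]] = [[root]]
    remaining = terms[1:]
    sizes = np.array([2.0 ** l for l in range(1, depth)])
    sizes = np.maximum(np.round(sizes / sizes.sum() * len(remaining)), 1).astype(int)
    while sizes.sum() > len(remaining):
        sizes[np.argmax(sizes)] -= 1
    sizes[-1] += len(remaining) - sizes.sum()
    pos = 0
    for sz in sizes:
        levels.append(remaining[pos:pos + sz])
        pos += sz
    g = nx.MultiDiGraph()
    for t in terms:
        g.add_node(t, name=f"synthetic term {t}", namespace="biological_process")
    for lvl in range(1, len(levels)):
        parents = levels[lvl - 1]
        for t in levels[lvl]:
            n_par = 1 if len(parents) == 1 else int(rng.integers(1, 3))
            chosen = rng.choice(parents, size=min(n_par, len(parents)),
                                replace=False)
            for p in chosen:
                g.add_edge(t, p, key="is_a")
    dag = OntologyDAG(g)
    # module clade: the subtree under the first level-1 term
    clade_head = levels[1][0]
    clade = {t for t in terms[1:]
             if clade_head in dag.ancestors(t) or t == clade_head}
    non_root = np.array(terms[1:])
    clade_mask = np.array([t in clade for t in non_root])
    pairs: list[tuple[str, str]] = []
    for gene in genes:
        k = max(1, int(rng.poisson(cfg.annotation_rate)))
        k = min(k, len(non_root))
        if gene in module_genes:
            w = np.where(clade_mask, cfg.module_term_bias, 1.0)
            p = w / w.sum()
            drawn = rng.choice(non_root, size=k, replace=False, p=p)
        else:
            drawn = rng.choice(non_root, size=k, replace=False)
        for t in sorted(drawn):
            pairs.append((gene, t))
    ann = AnnotationTable.from_pairs(pairs, dag, universe=genes)
    return dag, ann


def generate_bundle(cfg: GeneratorConfig | None = None) -> SyntheticBundle:
    """One deterministic bundle per (config, rng_seed)."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    net, module = generate_network(cfg, rng)
    seeds = generate_seeds(module, list(net.node_order), cfg, rng)
    dag, ann = generate_ontology(list(net.node_order), module, cfg, rng)
    return SyntheticBundle(network=net, seeds=seeds, module=module,
                           ontology=dag, annotations=ann, config=cfg)


def _obo_text(dag: OntologyDAG) -> str:
    buf = io.StringIO()
    buf.write("format-version: 1.2\nontology: synthetic\n")
    for term in sorted(dag.graph.nodes):
        data = dag.graph.nodes[term]
        buf.write("\n[Term]\n")
        buf.write(f"id: {term}\n")
        buf.write(f"name: {data.get('name', term)}\n")
        buf.write(f"namespace: {data.get('namespace', 'biological_process')}\n")
        parents = sorted((p, rel) for _, p, rel in dag.graph.out_edges(term, keys=True))
        for p, rel in parents:
            if rel == "is_a":
                buf.write(f"is_a: {p}\n")
            else:
                buf.write(f"relationship: {rel} {p}\n")
    return buf.getvalue()


def write_bundle(bundle: SyntheticBundle, directory) -> list[Path]:
    """Write the bundle as plain-text files; deterministic ordering makes
    output byte-identical for a fixed rng_seed."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    by_rel: dict[str, list[Edge]] = {r: [] for r in RELATIONS}
    for e in bundle.network.edges:
        by_rel[e.relation].append(e)
    for rel, fname in EDGE_FILE_NAMES.items():
        path = directory / fname
        lines = ["source\ttarget"]
        lines += [f"{e.source}\t{e.target}" for e in sorted(by_rel[rel], key=lambda e: e.key)]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    seeds_path = directory / "seeds.txt"
    seeds_path.write_text(
        "".join(f"{s}\t{bundle.network.kinds[s]}\n" for s in sorted(bundle.seeds))
    )
    written.append(seeds_path)
    labels_path = directory / "labels.tsv"
    labels_path.write_text(
        "node\tkind\tin_module\n"
        + "".join(
            f"{n}\t{bundle.network.kinds[n]}\t{int(n in bundle.module)}\n"
            for n in bundle.network.node_order
        )
    )
    written.append(labels_path)
    obo_path = directory / "ontology.obo"
    obo_path.write_text(_obo_text(bundle.ontology))
    written.append(obo_path)
    ann_path = directory / "annotations.tsv"
    rows = sorted(
        (g, t) for g, terms in bundle.annotations.direct.items() for t in terms
    )
    ann_path.write_text("gene\tterm\n" + "".join(f"{g}\t{t}\n" for g, t in rows))
    written.append(ann_path)
    return written


def read_bundle(directory, cfg: GeneratorConfig | None = None) -> SyntheticBundle:
    """Read a bundle written by :func:`write_bundle`."""
    from .semantics import read_annotations

    directory = Path(directory)
    edge_sets = [
        read_edge_table(directory / fname, rel)
        for rel, fname in EDGE_FILE_NAMES.items()
    ]
    import pandas as pd

    labels = pd.read_csv(directory / "labels.tsv", sep="\t", dtype=str)
    extra = dict(zip(labels["node"], labels["kind"]))
    module = frozenset(labels.loc[labels["in_module"] == "1", "node"])
    all_edges = [e for s in edge_sets for e in s]
    net = RegulatoryNetwork(all_edges, extra_nodes=extra)
    seeds = []
    for line in (directory / "seeds.txt").read_text().splitlines():
        if line.strip():
            seeds.append(line.split("\t")[0])
    dag = read_obo(directory / "ontology.obo")
    ann = read_annotations(directory / "annotations.tsv", dag,
                           universe=list(net.node_order))
    return SyntheticBundle(network=net, seeds=sorted(seeds), module=module,
                           ontology=dag, annotations=ann,
                           config=cfg or GeneratorConfig())
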