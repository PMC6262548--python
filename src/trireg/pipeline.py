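"""End-to-end orchestration: network construction → seeding → propagation →
ranking → evaluation → functional analysis, from one JSON config.

Every stage is a pure function of (inputs, config, rng_seed); rerunning a
config reproduces the ranking file and report byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import evaluation as ev
from . import network as nw
from . import rwr
from . import semantics as sem

__all__ = ["PipelineConfig", "EdgeTableSpec", "map_seeds", "run_pipeline",
            "read_seed_list"]

log = logging.getLogger("trireg")


class EdgeTableSpec(BaseModel):
    path: str
    relation: str
    filter_mode: str = "none"
    threshold: float = 0.0

    @field_validator("relation")
    @classmethod
    def _known_relation(cls, v: str) -> str:
        if v not in nw.RELATIONS:
            raise ValueError(f"unknown relation {v!r}")
        return v


class PipelineConfig(BaseModel):
    """Validated run parameters; see the JSON examples under analysis/."""

    edge_tables: list[EdgeTableSpec]
    seed_paths: list[str]
    alias_path: Optional[str] = None
    combine: str = "union"
    alpha: float = Field(default=0.5, gt=0, le=1)
    tol: float = Field(default=1e-10, gt=0)
    max_iter: int = Field(default=10_000, ge=1)
    undirected: bool = False
    dangling: str = "none"
    run_loocv: bool = True
    random_seed_null_reps: int = 0
    network_null_reps: int = 0
    kind_subsets: list[list[str]] = Field(
        default_factory=lambda: [["miRNA", "lncRNA"], ["TF", "miRNA"], ["TF", "lncRNA"]]
    )
    ontology_path: Optional[str] = None
    annotation_path: Optional[str] = None
    n_permutations: int = 200
    top_k: int = 100
    out_dir: str = "results"
    rng_seed: int = 0

    def validate_paths(self) -> None:
        missing = [t.path for t in self.edge_tables if not Path(t.path).exists()]
        missing += [p for p in self.seed_paths if not Path(p).exists()]
        for p in (self.alias_path, self.ontology_path, self.annotation_path):
            if p is not None and not Path(p).exists():
                missing.append(p)
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def read_seed_list(path) -> list[str]:
    """One id per line; an optional second tab-separated column carries the
    node kind and is ignored here (kinds live in the network)."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line.split("\t")[0])
    return ids


def map_seeds(
    seed_lists: list[list[str]], net: nw.RegulatoryNetwork
) -> tuple[rwr.SeedSet, pd.DataFrame]:
    """Intersect collected regulator ids with the network nodes.

    Returns the mapped SeedSet and a per-kind accounting table of
    mapped/unmapped counts (unmapped ids are logged, not fatal — unless
    nothing maps at all).
    """
    collected = sorted({s for lst in seed_lists for s in lst})
    if not collected:
        raise ValueError("no seed ids supplied")
    mapped = [s for s in collected if s in net.kinds]
    unmapped = [s for s in collected if s not in net.kinds]
    if not mapped:
        raise ValueError("zero seed ids mapped onto the network")
    if unmapped:
        log.info("dropped %d unmapped seed ids (e.g. %s)", len(unmapped), unmapped[:5])
    rows = []
    for kind in nw.KINDS:
        n_kind = sum(1 for s in mapped if net.kinds[s] == kind)
        rows.append({"kind": kind, "mapped": n_kind})
    table = pd.DataFrame(rows)
    table.loc[len(table)] = {"kind": "unmapped", "mapped": len(unmapped)}
    return rwr.SeedSet(mapped), table


def _build_network(cfg: PipelineConfig) -> nw.RegulatoryNetwork:
    aliases = nw.read_alias_table(cfg.alias_path) if cfg.alias_path else None
    edge_sets = [
        nw.read_edge_table(
            t.path, t.relation,
            nw.FilterSpec(t.filter_mode, t.threshold), aliases=aliases,
        )
        for t in cfg.edge_tables
    ]
    return nw.merge_networks(edge_sets, combine=cfg.combine)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages and write artifacts under out_dir.

    Returns the run report (also written as report.json): network summary,
    seed accounting, top-k kind composition, AUCs and null AUCs, and the
    semantic-similarity score with its permutation p-value.
    """
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.rng_seed)

    log.info("stage: network construction")
    net = _build_network(cfg)
    seeds, seed_table = map_seeds(
        [read_seed_list(p) for p in cfg.seed_paths], net
    )

    log.info("stage: propagation and ranking (%d seeds)", seeds.n)
    rwr_kwargs = dict(alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter,
                      undirected=cfg.undirected, dangling=cfg.dangling)
    _, ranking = rwr.run_rwr(net, seeds, **rwr_kwargs)
    ranking_path = out / "ranking.tsv"
    ranking.to_csv(ranking_path, sep="\t", index=False)
    top = ranking.head(cfg.top_k)
    top_comp = {k: int((top["kind"] == k).sum()) for k in nw.KINDS}

    report: dict = {
        "network": {
            "nodes": len(net),
            "edges": len(net.edges),
            "nodes_by_kind": net.node_counts(),
            "edges_by_relation": net.edge_counts_by_relation(),
        },
        "seeds": {
            "n_mapped": seeds.n,
            "by_kind": {r.kind: int(r.mapped) for r in seed_table.itertuples()},
        },
        "ranking_path": str(ranking_path),
        "top_k": cfg.top_k,
        "top_k_composition": top_comp,
        "config": json.loads(cfg.model_dump_json()),
    }

    if cfg.run_loocv:
        log.info("stage: LOOCV evaluation")
        rep = ev.loocv(net, seeds, **rwr_kwargs)
        eval_out: dict = {
            "auc": rep.auc,
            "roc": rep.roc_points(),
            "per_fold_ranks": rep.per_fold_ranks.to_dict(),
        }
        if cfg.random_seed_null_reps:
            eval_out["random_seed_null_aucs"] = ev.random_seed_null(
                net, seeds.n, cfg.random_seed_null_reps, rng, **rwr_kwargs
            )
        if cfg.network_null_reps:
            eval_out["network_null_aucs"] = ev.random_network_null(
                net, seeds, cfg.network_null_reps, rng, **rwr_kwargs
            )
        comp = ev.compare_networks(
            net, seeds, [tuple(s) for s in cfg.kind_subsets], **rwr_kwargs
        )
        eval_out["partial_networks"] = comp.to_dict(orient="records")
        (out / "evaluation.json").write_text(json.dumps(eval_out, indent=2))
        report["evaluation"] = {
            k: v for k, v in eval_out.items() if k not in ("roc", "per_fold_ranks")
        }

    if cfg.ontology_path and cfg.annotation_path:
        log.info("stage: functional semantics")
        dag = sem.read_obo(cfg.ontology_path)
        ann = sem.read_annotations(cfg.annotation_path, dag)
        universe = ann.universe
        top_genes = [n for n in top["node"] if n in universe]
        seed_genes = [s for s in sorted(seeds.ids) if s in universe]
        sim_out: dict = {}
        if top_genes and seed_genes:
            top_terms = sem.enrich(top_genes, ann, dag).significant
            seed_terms = sem.enrich(seed_genes, ann, dag).significant
            if top_terms and seed_terms:
                score = sem.permutation_test(
                    top_terms, seed_terms, dag, ann,
                    n_reps=cfg.n_permutations, rng=rng,
                )
                sim_out = {
                    "n_enriched_top": len(top_terms),
                    "n_enriched_seeds": len(seed_terms),
                    "similarity": score.score,
                    "p_value": score.p_value,
                    "method": score.method,
                    "n_permutations": cfg.n_permutations,
                }
            else:
                sim_out = {"status": "no significantly enriched terms"}
        else:
            sim_out = {"status": "no annotated genes in top-k or seeds"}
        (out / "similarity.json").write_text(json.dumps(sim_out, indent=2))
        report["semantics"] = sim_out

    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("pipeline complete; artifacts under %s", out)
    return report
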