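"""Random walk with restart (RWR) on a regulatory network.

The walker starts on a set of seed nodes (known regulators), follows
out-edges with probability 1−α and teleports back to the seeds with
probability α. The stationary probability vector P∞ measures proximity to
the seed set and ranks candidate nodes.

Transition matrix: W(i, j) = A(i, j) / Σ_j A(i, j) where A is the binary
adjacency, with all-zero rows for nodes of out-degree zero (dangling
nodes). Update: p_{t+1} = (1−α)·Wᵀ·p_t + α·p0, iterated until the L1
difference between successive vectors drops below a tolerance
(default 1e-10). Because dangling rows are zero, walk mass can leak and
sum(P∞) may fall below 1; the optional ``dangling="restart"`` mode
redirects the leaked mass to the restart distribution instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import RegulatoryNetwork

__all__ = [
    "SeedSet",
    "TransitionMatrix",
    "PropagationResult",
    "ConvergenceError",
    "build_transition",
    "make_seed_vector",
    "propagate",
    "rank_candidates",
    "run_rwr",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class SeedSet:
    """Known-regulator identifiers mapped onto a network; the restart
    distribution puts mass 1/n on each of the n seeds."""

    ids: frozenset[str]

    def __init__(self, ids) -> None:
        object.__setattr__(self, "ids", frozenset(ids))
        if not self.ids:
            raise ValueError("seed set must be non-empty")

    @property
    def n(self) -> int:
        return len(self.ids)

    def without(self, node_id: str) -> "SeedSet":
        return SeedSet(self.ids - {node_id})

    def restrict_to(self, net: RegulatoryNetwork) -> "SeedSet":
        return SeedSet(self.ids & set(net.kinds))


@dataclass
class TransitionMatrix:
    W: sp.csr_matrix                 # row-stochastic except for dangling rows
    node_order: tuple[str, ...]
    dangling: frozenset[str]         # nodes with zero out-degree

    @property
    def n(self) -> int:
        return len(self.node_order)


@dataclass
class PropagationResult:
    p_inf: np.ndarray
    iterations: int
    residual: float
    alpha: float
    p0: np.ndarray
    node_order: tuple[str, ...] = field(repr=False, default=())


def build_transition(
    net: RegulatoryNetwork, undirected: bool = False
) -> TransitionMatrix:
    """Row-normalize the adjacency; zero rows for dangling nodes.

    With ``undirected=True`` the adjacency is symmetrized (A ∨ Aᵀ) before
    normalization, for sensitivity analysis against direction handling.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    A = net.adjacency()
    if undirected:
        A = ((A + A.T) > 0).astype(float)
    out = np.asarray(A.sum(axis=1)).ravel()
    inv = np.zeros_like(out)
    nz = out > 0
    inv[nz] = 1.0 / out[nz]
    W = sp.diags(inv) @ A
    dangling = frozenset(
        n for n, d in zip(net.node_order, out) if d == 0
    )
    return TransitionMatrix(W=W.tocsr(), node_order=net.node_order, dangling=dangling)


def make_seed_vector(
    net: RegulatoryNetwork, seeds: SeedSet, strict: bool = True
) -> np.ndarray:
    """p0(i) = 1/n for seeds, 0 otherwise; sums to 1 exactly.

    Unmapped seed ids raise (listing them) unless ``strict=False``, in
    which case they are dropped and n shrinks accordingly.
    """
    unmapped = sorted(seeds.ids - set(net.kinds))
    ids = seeds.ids
    if unmapped:
        if strict:
            raise ValueError(f"seed ids absent from network: {unmapped}")
        ids = ids - set(unmapped)
        if not ids:
            raise ValueError("no seed ids mapped onto the network")
    p0 = np.zeros(len(net))
    for s in ids:
        p0[net.index[s]] = 1.0
    p0 /= p0.sum()
    return p0


def propagate(
    W: TransitionMatrix,
    p0: np.ndarray,
    alpha: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    dangling: str = "none",
) -> PropagationResult:
    """Iterate p_{t+1} = (1−α)·Wᵀ·p_t + α·p0 to the stable vector P∞.

    Convergence is the L1 difference between successive vectors falling
    below ``tol``. ``dangling="restart"`` reinjects the walk mass sitting
    on zero-out-degree nodes into p0 instead of letting it leak.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if dangling not in ("none", "restart"):
        raise ValueError("dangling must be 'none' or 'restart'")
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("p0 must sum to 1")
    WT = W.W.T.tocsr()
    if dangling == "restart":
        dang_idx = np.array(
            [i for i, nid in enumerate(W.node_order) if nid in W.dangling],
            dtype=int,
        )
    p = p0.copy()
    for it in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (WT @ p) + alpha * p0
        if dangling == "restart" and len(dang_idx):
            leaked = float(p[dang_idx].sum())
            p_next += (1.0 - alpha) * leaked * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return PropagationResult(
                p_inf=p, iterations=it, residual=residual, alpha=alpha,
                p0=p0, node_order=W.node_order,
            )
    raise ConvergenceError(
        f"no convergence after {max_iter} iterations (residual {residual:.3e})"
    )


def rank_candidates(
    result: PropagationResult,
    seeds: SeedSet,
    net: RegulatoryNetwork,
) -> pd.DataFrame:
    """Rank non-seed nodes by P∞ descending; ties break by node id
    ascending so repeated runs give identical tables.

    Returns a DataFrame with columns rank, node, kind, score.
    """
    if tuple(result.node_order) != tuple(net.node_order):
        raise ValueError("propagation result and network node orders differ")
    rows = [
        (nid, net.kinds[nid], float(result.p_inf[i]))
        for i, nid in enumerate(net.node_order)
        if nid not in seeds.ids
    ]
    rows.sort(key=lambda r: (-r[2], r[0]))
    return pd.DataFrame(
        [(rank, nid, kind, score) for rank, (nid, kind, score) in
         enumerate(rows, start=1)],
        columns=["rank", "node", "kind", "score"],
    )


def run_rwr(
    net: RegulatoryNetwork,
    seeds: SeedSet,
    alpha: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    undirected: bool = False,
    dangling: str = "none",
) -> tuple[PropagationResult, pd.DataFrame]:
    """Convenience wrapper: transition → seed vector → propagate → rank."""
    W = build_transition(net, undirected=undirected)
    p0 = make_seed_vector(net, seeds)
    res = propagate(W, p0, alpha=alpha, tol=tol, max_iter=max_iter,
                    dangling=dangling)
    return res, rank_candidates(res, seeds, net)
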