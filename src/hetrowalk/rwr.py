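"""Random walk with restart (RWR) on the heterogeneous graph.

The walker starts on a seed distribution e and iterates

    p(t+1) = (1 - r) A p(t) + r e,       p(0) = e

where A is the column-normalized adjacency matrix (A[i, j] = 1/deg(j) for
i ~ j) and r is the restart probability. Iteration stops when the L1 norm of
successive proximity vectors falls below tau. The steady state p solves
p = r (I - (1-r) A)^{-1} e and is a probability distribution over nodes:
high p(i) means node i is topologically close to the seeds.

Defaults follow common practice for gene prioritization on knowledge
graphs: r = 0.25, tau = 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .graph import HeteroGraph, NodeRef

#: node count above which the stochastic operator is kept sparse
_DENSE_LIMIT = 2000


@dataclass
class WalkConfig:
    """Tunables of the walk: restart probability, convergence threshold,
    iteration cap."""

    r: float = 0.25
    tau: float = 1e-8
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError(f"restart probability must be in (0,1), got {self.r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class SeedSet:
    """Seed nodes with their restart distribution (uniform unless given)."""

    nodes: Sequence[NodeRef]
    weights: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError("seed set is empty")
        ids = [n.identifier for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate seed identifiers")
        if self.weights is None:
            w = 1.0 / len(ids)
            self.weights = {i: w for i in ids}
        else:
            vals = np.array([self.weights[i] for i in ids], dtype=float)
            if (vals < 0).any():
                raise ValueError("negative seed weight")
            total = vals.sum()
            if total <= 0:
                raise ValueError("seed weights sum to zero")
            self.weights = {i: v / total for i, v in zip(ids, vals)}

    @property
    def identifiers(self) -> list[str]:
        return [n.identifier for n in self.nodes]


@dataclass
class ProximityVector:
    """Steady-state visiting probabilities, with convergence diagnostics."""

    scores: dict[str, float]
    iterations: int
    residual: float
    kinds: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, identifier: str) -> float:
        return self.scores[identifier]

    def top(self, n: int = 10, kind: Optional[str] = None) -> list[tuple[str, float]]:
        items = (
            (k, v)
            for k, v in self.scores.items()
            if kind is None or self.kinds.get(k) == kind
        )
        return sorted(items, key=lambda kv: (-kv[1], kv[0]))[:n]


def _node_index(hg: HeteroGraph) -> list[str]:
    return sorted(hg.g.nodes())


def column_normalized_operator(
    hg: HeteroGraph,
) -> tuple[sp.csr_matrix | np.ndarray, list[str]]:
    """Column-stochastic transition operator A and its node ordering.

    Each column j distributes unit mass equally over the neighbors of node j;
    isolated nodes have no valid column and are rejected.
    """
    nodes = _node_index(hg)
    index = {n: i for i, n in enumerate(nodes)}
    deg = dict(hg.g.degree())
    for n in nodes:
        if deg[n] == 0:
            raise ValueError(f"isolated node {n!r} has no transition column")
    rows, cols, vals = [], [], []
    for u, v in hg.g.edges():
        iu, iv = index[u], index[v]
        rows.append(iu), cols.append(iv), vals.append(1.0 / deg[v])
        rows.append(iv), cols.append(iu), vals.append(1.0 / deg[u])
    A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(nodes), len(nodes)), dtype=float
    )
    if len(nodes) <= _DENSE_LIMIT:
        return A.toarray(), nodes
    return A, nodes


def _restart_matrix(
    seeds_list: Sequence[SeedSet], index: Mapping[str, int]
) -> np.ndarray:
    E = np.zeros((len(index), len(seeds_list)))
    for j, seeds in enumerate(seeds_list):
        for ident, w in seeds.weights.items():
            if ident not in index:
                raise KeyError(f"seed node {ident!r} not in graph")
            E[index[ident], j] = w
    return E


def _iterate(A, E: np.ndarray, cfg: WalkConfig) -> tuple[np.ndarray, int, float]:
    """Batched power iteration; each column of E is an independent walk."""
    P = E.copy()
    r = cfg.r
    for it in range(1, cfg.max_iter + 1):
        P_next = (1.0 - r) * (A @ P) + r * E
        residual = float(np.abs(P_next - P).sum(axis=0).max())
        P = P_next
        if residual < cfg.tau:
            return P, it, residual
    raise RuntimeError(
        f"walk failed to converge in {cfg.max_iter} iterations "
        f"(residual {residual:.3e} >= tau {cfg.tau:.3e})"
    )


def random_walk(
    hg: HeteroGraph, seeds: SeedSet, cfg: Optional[WalkConfig] = None
) -> ProximityVector:
    """Run RWR from ``seeds`` and return steady-state proximity scores."""
    cfg = cfg or WalkConfig()
    A, nodes = column_normalized_operator(hg)
    index = {n: i for i, n in enumerate(nodes)}
    E = _restart_matrix([seeds], index)
    P, iters, residual = _iterate(A, E, cfg)
    p = P[:, 0]
    kinds = {n: hg.g.nodes[n]["kind"] for n in nodes}
    return ProximityVector(dict(zip(nodes, p.tolist())), iters, residual, kinds)


def batched_walks(
    hg: HeteroGraph, seed_sets: Sequence[SeedSet], cfg: Optional[WalkConfig] = None
) -> tuple[np.ndarray, list[str]]:
    """Run many walks at once; returns score matrix (node x walk) and node order."""
    cfg = cfg or WalkConfig()
    A, nodes = column_normalized_operator(hg)
    index = {n: i for i, n in enumerate(nodes)}
    E = _restart_matrix(seed_sets, index)
    P, _, _ = _iterate(A, E, cfg)
    return P, nodes


def rwr_gene_similarity(
    hg: HeteroGraph,
    genes: Sequence[NodeRef],
    cfg: Optional[WalkConfig] = None,
):
    """Gene-gene similarity from single-seed walks.

    Sim(g_i, g_j) = (p_{g_i}(g_j) + p_{g_j}(g_i)) / 2 — symmetric by
    construction; the diagonal is the walker's self-return probability.
    Genes absent from the graph yield NaN rows/columns (the "missing gene"
    case), which downstream set-similarity averages exclude.
    """
    from .semsim import SimilarityMatrix  # local import to avoid a cycle

    cfg = cfg or WalkConfig()
    present = [g for g in genes if hg.has_node(g.identifier)]
    missing = [g.identifier for g in genes if not hg.has_node(g.identifier)]
    if missing:
        import logging

        logging.getLogger(__name__).info(
            "rwr_gene_similarity: %d gene(s) absent from graph: %s",
            len(missing),
            ", ".join(missing[:5]),
        )
    ids = [g.identifier for g in genes]
    values = np.full((len(ids), len(ids)), np.nan)
    if present:
        P, nodes = batched_walks(hg, [SeedSet([g]) for g in present], cfg)
        index = {n: i for i, n in enumerate(nodes)}
        pos = {g.identifier: j for j, g in enumerate(present)}
        for a in present:
            ia = ids.index(a.identifier)
            for b in present:
                ib = ids.index(b.identifier)
                pab = P[index[b.identifier], pos[a.identifier]]
                pba = P[index[a.identifier], pos[b.identifier]]
                values[ia, ib] = 0.5 * (pab + pba)
    return SimilarityMatrix(genes=ids, values=values, measure="rwr")
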