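"""Permutation-based significance of walk scores and the two-fold filter.

The null model rearranges all node labels uniformly at random while keeping
the topology fixed, then repeats the walk from the same seed labels. A
node's empirical p-value is the add-one-smoothed fraction of permutations
whose score is at least the observed one. The two-fold filter then keeps
gene nodes that are both significant (p <= alpha) and in the upper tail of
walk scores (score >= the q-quantile of all node scores); seeds themselves
are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graph import HeteroGraph, NodeRef
from .rwr import ProximityVector, SeedSet, WalkConfig, _iterate, column_normalized_operator


def permute_graph(hg: HeteroGraph, seed: int) -> HeteroGraph:
    """Uniformly shuffle node labels over the fixed topology.

    Each label (with its kind/species attributes) moves to a new topological
    position; the degree sequence is unchanged. Deterministic given ``seed``.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    nodes = sorted(hg.g.nodes())
    perm = rng.permutation(len(nodes))
    mapping = {nodes[i]: nodes[perm[i]] for i in range(len(nodes))}
    g2 = nx.Graph()
    for n in nodes:
        d = hg.g.nodes[n]
        g2.add_node(n, kind=d["kind"], species=d.get("species"))
    for u, v, d in hg.g.edges(data=True):
        g2.add_edge(mapping[u], mapping[v], relation=d["relation"])
    return HeteroGraph(g2, dict(hg.provenance))


@dataclass
class PermutationResult:
    observed: ProximityVector
    pvalues: dict[str, float]
    n_perm: int
    seed_ids: frozenset[str]
    species: dict[str, Optional[str]]


def permutation_pvalues(
    hg: HeteroGraph,
    seeds: SeedSet,
    cfg: Optional[WalkConfig] = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
) -> PermutationResult:
    """Empirical p-values from ``n_perm`` label-permutation walks.

    A walk on the permuted graph with the original seed labels is equivalent
    to a walk on the original topology started from the permuted seed
    positions, reading each label's score at its permuted position; all
    permutations are therefore run as one batched iteration.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or WalkConfig()
    A, nodes = column_normalized_operator(hg)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    for s in seeds.identifiers:
        if s not in index:
            raise KeyError(f"seed node {s!r} not in graph")
    rng = np.random.default_rng(rng_seed)

    # column 0: observed walk; columns 1..n_perm: permuted walks.
    # sigma[j] maps each label position to its position in permutation j.
    sigmas = np.stack([rng.permutation(n) for _ in range(n_perm)])
    E = np.zeros((n, n_perm + 1))
    for ident, w in seeds.weights.items():
        i = index[ident]
        E[i, 0] = w
        E[sigmas[:, i], np.arange(1, n_perm + 1)] = w
    P, iters, residual = _iterate(A, E, cfg)

    obs = P[:, 0]
    # permuted score of label i in permutation j is P[sigma_j(i), j+1]
    perm_scores = P[sigmas.T, np.arange(1, n_perm + 1)]  # shape (n, n_perm)
    # "as high or higher": scores equal in exact arithmetic (symmetric
    # positions) differ by O(tau) across walks, so ties are counted with a
    # tolerance of 10*tau rather than left to convergence jitter
    exceed = (perm_scores >= obs[:, None] - 10.0 * cfg.tau).sum(axis=1)
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    kinds = {m: hg.g.nodes[m]["kind"] for m in nodes}
    species = {m: hg.g.nodes[m].get("species") for m in nodes}
    observed = ProximityVector(dict(zip(nodes, obs.tolist())), iters, residual, kinds)
    return PermutationResult(
        observed=observed,
        pvalues=dict(zip(nodes, pvals.tolist())),
        n_perm=n_perm,
        seed_ids=frozenset(seeds.identifiers),
        species=species,
    )


def twofold_filter(
    pr: PermutationResult, alpha: float = 0.01, q: float = 0.95
) -> set[NodeRef]:
    """Genes passing both thresholds: permutation p <= alpha and walk score
    >= the q-quantile of all node scores. Seed nodes are never returned."""
    scores = pr.observed.scores
    if not scores:
        raise ValueError("no observed scores")
    cutoff = float(np.quantile(np.array(list(scores.values())), q))
    out = set()
    for ident, score in scores.items():
        if ident in pr.seed_ids:
            continue
        if pr.observed.kinds.get(ident) != "gene":
            continue
        if pr.pvalues[ident] <= alpha and score >= cutoff:
            out.add(NodeRef(ident, "gene", pr.species.get(ident)))
    return out
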