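"""DIAMOnD-style disease-module growth by connectivity significance.

Starting from seed genes, candidate genes are ranked by the hypergeometric
tail probability of having at least their observed number of links into the
current module by chance; the most significant candidate is absorbed and
the process repeats. Used here as the modular-growth comparator to
walk-based prioritization: on a heterogeneous graph whose genes connect
mostly through gene sets and ontology terms, candidates often have no
direct gene-gene link to the seeds and growth stalls — the failure mode the
walk does not share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

from .graph import HeteroGraph, NodeRef

logger = logging.getLogger(__name__)


def connectivity_pvalue(N: int, s0: int, k: int, ks: int) -> float:
    """Hypergeometric tail: probability that a degree-k node has >= ks links
    into a module of s0 nodes inside a network of N nodes.

        p = sum_{i=ks}^{min(k, s0)} C(s0, i) C(N - s0, k - i) / C(N, k)

    Computed with exact integer binomials; rounding happens only in the
    final division.
    """
    if ks < 0 or ks > k or ks > s0:
        raise ValueError(f"impossible seed-link count ks={ks} (k={k}, s0={s0})")
    if k > N - 1:
        raise ValueError(f"degree k={k} exceeds N-1={N - 1}")
    numerator = sum(comb(s0, i) * comb(N - s0, k - i) for i in range(ks, min(k, s0) + 1))
    return numerator / comb(N, k)


@dataclass
class ModuleGrowth:
    seeds: frozenset[str]
    added: list[tuple[str, int, int, float]]  # (gene, degree k, seed links ks, p)
    n_requested: int

    def module_genes(self) -> set[str]:
        return {g for g, _, _, _ in self.added}


def grow_disease_module(
    hg: HeteroGraph, seeds: Sequence[NodeRef] | Sequence[str], n: int = 250
) -> ModuleGrowth:
    """Iteratively absorb the gene with the smallest connectivity p-value.

    ``N`` counts all nodes (the algorithm is run as-is on the heterogeneous
    graph); candidates are gene nodes only. Ties are broken by higher ks,
    then lower degree, then identifier, making growth deterministic. Growth
    stops early when no remaining gene touches the module.
    """
    seed_ids = {s.identifier if isinstance(s, NodeRef) else s for s in seeds}
    present = {s for s in seed_ids if hg.has_node(s)}
    if not present:
        raise ValueError("no seed gene is present in the graph")
    dropped = seed_ids - present
    if dropped:
        logger.info("%d seed(s) absent from graph", len(dropped))

    N = len(hg)
    module = set(present)
    gene_ids = {g.identifier for g in hg.nodes("gene")}
    candidates = gene_ids - module
    adj = hg.g.adj
    added: list[tuple[str, int, int, float]] = []
    # seed-link counts maintained incrementally as the module absorbs nodes
    ks_count = {c: sum(1 for nb in adj[c] if nb in module) for c in candidates}

    while len(added) < n:
        best = None
        s0 = len(module)
        for c in sorted(candidates):
            ks = ks_count[c]
            if ks < 1:
                continue
            k = len(adj[c])
            p = connectivity_pvalue(N, s0, k, ks)
            key = (p, -ks, k, c)
            if best is None or key < best[0]:
                best = (key, c, k, ks, p)
        if best is None:
            if not added:
                logger.warning("no candidate gene touches the seed module; empty growth")
            break
        _, c, k, ks, p = best
        added.append((c, k, ks, p))
        module.add(c)
        candidates.discard(c)
        for nb in adj[c]:
            if nb in candidates:
                ks_count[nb] += 1
    return ModuleGrowth(seeds=frozenset(present), added=added, n_requested=n)
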