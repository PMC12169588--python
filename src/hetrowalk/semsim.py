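"""Semantic similarity measures, gene functional similarity, and pathway
discriminative power.

Term-level similarity Sim_sem(t1, t2) is one of:

* ``resnik`` — IC of the most informative common ancestor (MICA),
* ``lin``    — 2 IC(MICA) / (IC(t1) + IC(t2)), in [0, 1],
* ``jaccard``— |Anc(t1) ∩ Anc(t2)| / |Anc(t1) ∪ Anc(t2)| over ancestor sets
  (a term is its own ancestor),
* ``cosine`` — the same intersection over sqrt(|Anc(t1)|·|Anc(t2)|), i.e.
  the cosine of binary ancestor-indicator vectors.

Gene functional similarity is the best-match average over the two genes'
annotation term sets T1, T2:

    Sim(g1, g2) = ( Σ_{t∈T1} max_{t'∈T2} Sim_sem(t,t')
                  + Σ_{t∈T2} max_{t'∈T1} Sim_sem(t,t') ) / (|T1| + |T2|)

Discriminative power (DP) of a pathway S_k within a collection of P pathways
compares within-pathway to between-pathway average similarity:

    DP(S_k) = (P - 1) · IntraSetSim(S_k) / Σ_{i≠k} InterSetSim(S_k, S_i)

A high DP means the measure separates the pathway from functionally
distinct ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .graph import NodeRef
from .ontology import AnnotationSet, OntologyDAG, TermClosure, all_closures

logger = logging.getLogger(__name__)

MEASURES = ("resnik", "lin", "jaccard", "cosine", "rwr")
NORMALIZED_MEASURES = ("lin", "jaccard", "cosine")


@dataclass
class SimilarityMatrix:
    """Symmetric gene x gene similarity; NaN marks missing genes."""

    genes: list[str]
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.genes)):
            raise ValueError("similarity matrix shape does not match gene list")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.genes.index(i) for i in ids]
        return self.values[np.ix_(idx, idx)]

    @property
    def missing_genes(self) -> list[str]:
        mask = np.all(np.isnan(self.values), axis=1)
        return [g for g, m in zip(self.genes, mask) if m]


@dataclass
class PathwayCollection:
    """Named gene sets (GMT-style) used for the DP benchmark."""

    pathways: list[tuple[str, list[str]]]

    def __post_init__(self) -> None:
        ids = [p for p, _ in self.pathways]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pathway ids")
        for pid, genes in self.pathways:
            if not genes:
                raise ValueError(f"pathway {pid!r} is empty")

    def __len__(self) -> int:
        return len(self.pathways)

    def ids(self) -> list[str]:
        return [p for p, _ in self.pathways]

    def genes_of(self, pathway_id: str) -> list[str]:
        for pid, genes in self.pathways:
            if pid == pathway_id:
                return list(genes)
        raise KeyError(f"unknown pathway {pathway_id!r}")

    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, genes in self.pathways:
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "PathwayCollection":
        pathways = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: GMT row needs id, description, >=1 gene")
            pathways.append((cols[0], cols[2:]))
        return cls(pathways)

    def to_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([pid, "na"] + list(genes)) for pid, genes in self.pathways
        ]
        Path(path).write_text("\n".join(lines) + "\n")


class SemanticContext:
    """Caches closures and ICs for one (DAG, annotation set) pair."""

    def __init__(self, dag: OntologyDAG, annotations: AnnotationSet):
        self.dag = dag
        self.annotations = annotations
        self.closures: dict[str, TermClosure] = all_closures(dag, annotations)
        corpus = self.closures[dag.root].size
        if corpus == 0:
            raise ValueError("annotation corpus is empty")
        self.ic: dict[str, float] = {}
        for t, cl in self.closures.items():
            if cl.size > 0:
                self.ic[t] = -math.log(cl.size / corpus)
        self._anc: dict[str, frozenset[str]] = {}

    def ancestors(self, term: str) -> frozenset[str]:
        if term not in self._anc:
            self._anc[term] = frozenset(self.dag.ancestors(term))
        return self._anc[term]


def term_similarity(
    t1: str,
    t2: str,
    measure: str,
    dag: OntologyDAG,
    a: AnnotationSet,
    ctx: Optional[SemanticContext] = None,
) -> float:
    """Pairwise term similarity under the chosen measure."""
    ctx = ctx or SemanticContext(dag, a)
    if t1 not in dag or t2 not in dag:
        raise KeyError(f"unknown term {t1!r} or {t2!r}")
    anc1, anc2 = ctx.ancestors(t1), ctx.ancestors(t2)
    if measure == "jaccard":
        return len(anc1 & anc2) / len(anc1 | anc2)
    if measure == "cosine":
        return len(anc1 & anc2) / math.sqrt(len(anc1) * len(anc2))
    if measure in ("resnik", "lin"):
        common = anc1 & anc2
        ic_common = [ctx.ic[t] for t in common if t in ctx.ic]
        if not ic_common:
            raise ValueError(
                f"no common ancestor of {t1!r}, {t2!r} has a nonempty closure"
            )
        mica = max(ic_common)
        if measure == "resnik":
            return mica
        ic1, ic2 = ctx.ic.get(t1), ctx.ic.get(t2)
        if ic1 is None or ic2 is None:
            raise ValueError(f"term {t1!r} or {t2!r} has an empty closure")
        if ic1 + ic2 == 0:
            # both terms carry no information: identical -> 1, else 0
            return 1.0 if t1 == t2 else 0.0
        return 2.0 * mica / (ic1 + ic2)
    raise ValueError(f"unknown term-level measure {measure!r}")


def simterms(
    t: str,
    terms: Sequence[str],
    measure: str,
    dag: OntologyDAG,
    a: AnnotationSet,
    ctx: Optional[SemanticContext] = None,
) -> float:
    """Best match of ``t`` against a term set: max_{t' in terms} Sim_sem."""
    if not terms:
        raise ValueError("term set is empty")
    ctx = ctx or SemanticContext(dag, a)
    return max(term_similarity(t, t2, measure, dag, a, ctx) for t2 in terms)


def gene_functional_similarity(
    g1: NodeRef | str,
    g2: NodeRef | str,
    measure: str,
    dag: OntologyDAG,
    a: AnnotationSet,
    ctx: Optional[SemanticContext] = None,
) -> float:
    """Best-match-average functional similarity of two genes.

    Returns NaN (the missing-value marker) when either gene has no
    annotation after evidence filtering.
    """
    ctx = ctx or SemanticContext(dag, a)
    id1 = g1.identifier if isinstance(g1, NodeRef) else g1
    id2 = g2.identifier if isinstance(g2, NodeRef) else g2
    T1 = sorted(a.terms_of(id1))
    T2 = sorted(a.terms_of(id2))
    if not T1 or not T2:
        return float("nan")
    total = sum(simterms(t, T2, measure, dag, a, ctx) for t in T1)
    total += sum(simterms(t, T1, measure, dag, a, ctx) for t in T2)
    return total / (len(T1) + len(T2))


def semantic_gene_similarity(
    genes: Sequence[str],
    measure: str,
    dag: OntologyDAG,
    a: AnnotationSet,
) -> SimilarityMatrix:
    """Gene x gene functional similarity matrix under one semantic measure."""
    ctx = SemanticContext(dag, a)
    n = len(genes)
    values = np.full((n, n), np.nan)
    for i, gi in enumerate(genes):
        for j in range(i, n):
            s = gene_functional_similarity(gi, genes[j], measure, dag, a, ctx)
            values[i, j] = values[j, i] = s
    n_missing = int(np.all(np.isnan(values), axis=1).sum())
    if n_missing:
        logger.info("%d gene(s) have no usable annotation (missing values)", n_missing)
    return SimilarityMatrix(genes=list(genes), values=values, measure=measure)


def _present(ids: Sequence[str], M: SimilarityMatrix) -> list[str]:
    """Pathway genes usable in M: present in the gene list and not all-NaN."""
    missing = set(M.missing_genes)
    out = [g for g in ids if g in M.genes and g not in missing]
    dropped = [g for g in ids if g not in out]
    if dropped:
        logger.info("excluding %d gene(s) without similarity values: %s",
                    len(dropped), ", ".join(dropped[:5]))
    return out


def intraset_sim(pathway_genes: Sequence[str], M: SimilarityMatrix) -> float:
    """Mean of the full b x b similarity block (diagonal included)."""
    ids = _present(pathway_genes, M)
    if not ids:
        raise ValueError("pathway has no genes with similarity values")
    block = M.submatrix(ids)
    return float(np.nanmean(block))


def interset_sim(
    genes_k: Sequence[str], genes_l: Sequence[str], M: SimilarityMatrix
) -> float:
    """Mean of the b x c cross block between two pathways."""
    ids_k, ids_l = _present(genes_k, M), _present(genes_l, M)
    if not ids_k or not ids_l:
        raise ValueError("pathway has no genes with similarity values")
    ik = [M.genes.index(g) for g in ids_k]
    il = [M.genes.index(g) for g in ids_l]
    block = M.values[np.ix_(ik, il)]
    return float(np.nanmean(block))


def discriminative_power(
    pathway_id: str, coll: PathwayCollection, M: SimilarityMatrix
) -> float:
    """DP(S_k) = (P-1) IntraSetSim(S_k) / sum of InterSetSim over the rest.

    Invariant under uniform positive scaling of M, which makes RWR-derived
    similarities comparable to [0, 1]-bounded semantic measures.
    """
    if len(coll) < 2:
        raise ValueError("discriminative power needs at least 2 pathways")
    genes_k = coll.genes_of(pathway_id)
    intra = intraset_sim(genes_k, M)
    inter_total = sum(
        interset_sim(genes_k, coll.genes_of(other), M)
        for other in coll.ids()
        if other != pathway_id
    )
    if inter_total == 0:
        raise ValueError(f"degenerate similarity: zero inter-set total for {pathway_id!r}")
    return (len(coll) - 1) * intra / inter_total


def dp_table(coll: PathwayCollection, M: SimilarityMatrix) -> dict[str, float]:
    """DP for every pathway in the collection."""
    return {pid: discriminative_power(pid, coll, M) for pid in coll.ids()}
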