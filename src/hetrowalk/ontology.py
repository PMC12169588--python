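"""Ontology DAG handling, annotation evidence filtering, closures, and
information content.

Only the biological-process hierarchy under a single root is modelled, with
the three relation types that propagate annotations: ``is_a``, ``part_of``
and ``regulates``. Gene annotations are filtered to experimentally verified
or curator-assigned evidence codes; electronically inferred annotations
(IEA) are excluded. The *closure* of a term is the set of genes annotated to
it or to any descendant; terms whose closure exceeds a cap (default 200
genes) are considered too general and contribute only their direct
annotation edges to the heterogeneous graph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import obonet

from .graph import EdgeRecord, NodeRef

logger = logging.getLogger(__name__)

#: experimentally verified / expertly curated GO evidence codes
DEFAULT_EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IEP", "IGI", "IMP", "IPI", "TAS", "IC"}
)
PROPAGATING_RELATIONS = ("is_a", "part_of", "regulates")


@dataclass(frozen=True)
class AnnotationRecord:
    gene: NodeRef
    term: str
    evidence: str


@dataclass
class AnnotationSet:
    """Set of (gene, term, evidence) records."""

    records: frozenset[AnnotationRecord]

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[NodeRef, str, str]]) -> "AnnotationSet":
        return cls(frozenset(AnnotationRecord(g, t, e) for g, t, e in tuples))

    def __len__(self) -> int:
        return len(self.records)

    def direct_genes(self, term: str) -> set[NodeRef]:
        return {r.gene for r in self.records if r.term == term}

    def terms_of(self, gene_identifier: str) -> set[str]:
        return {r.term for r in self.records if r.gene.identifier == gene_identifier}

    def genes(self) -> set[NodeRef]:
        return {r.gene for r in self.records}


@dataclass
class OntologyDAG:
    """Term hierarchy: child -> {(parent, relation)} links reaching one root."""

    parents: dict[str, set[tuple[str, str]]]
    root: str
    _children: Optional[dict[str, set[str]]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_node(self.root)
        for child, links in self.parents.items():
            for parent, rel in links:
                if rel not in PROPAGATING_RELATIONS:
                    raise ValueError(f"relation {rel!r} does not propagate")
                g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        for t in g.nodes:
            if t != self.root and not nx.has_path(g, t, self.root):
                raise ValueError(f"term {t!r} does not reach root {self.root!r}")
        self._dag = g

    @property
    def terms(self) -> set[str]:
        return set(self._dag.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._dag

    def children_map(self) -> dict[str, set[str]]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.terms}
            for child, links in self.parents.items():
                for parent, _rel in links:
                    ch[parent].add(child)
            self._children = ch
        return self._children

    def descendants(self, term: str) -> set[str]:
        """Terms reachable downward from ``term`` (excluding itself)."""
        if term not in self._dag:
            raise KeyError(f"unknown term {term!r}")
        return set(nx.ancestors(self._dag, term))  # edges point child->parent

    def ancestors(self, term: str) -> set[str]:
        """Ancestors of ``term`` including itself (self is its own ancestor
        for set-overlap similarity measures)."""
        if term not in self._dag:
            raise KeyError(f"unknown term {term!r}")
        return set(nx.descendants(self._dag, term)) | {term}


def load_obo(path: str | Path, root: Optional[str] = None) -> OntologyDAG:
    """Read an OBO file keeping only is_a / part_of / regulates links.

    Other relationship types are ignored with a logged count. ``root``
    defaults to the unique term without outgoing propagating links.
    """
    g = obonet.read_obo(str(path))
    parents: dict[str, set[tuple[str, str]]] = {}
    skipped = 0
    for child, parent, key in g.edges(keys=True):
        if key in PROPAGATING_RELATIONS:
            parents.setdefault(child, set()).add((parent, key))
        else:
            skipped += 1
    if skipped:
        logger.info("%s: ignored %d non-propagating relationship(s)", path, skipped)
    if root is None:
        all_terms = set(g.nodes)
        non_roots = set(parents)
        roots = sorted(all_terms - non_roots)
        if len(roots) != 1:
            raise ValueError(f"cannot infer a unique root (candidates: {roots})")
        root = roots[0]
    return OntologyDAG(parents=parents, root=root)


def load_gaf(
    path: str | Path,
    species: str,
    allowed: frozenset[str] = DEFAULT_EVIDENCE_CODES,
) -> AnnotationSet:
    """Read a GAF 2.x annotation file (columns 2, 5, 7: object id, term,
    evidence code), applying the evidence filter on load."""
    tuples = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 7:
            raise ValueError(f"{path}:{lineno}: GAF row has {len(cols)} columns, need >=7")
        gene_id, term, evidence = cols[1], cols[4], cols[6]
        if evidence in allowed:
            tuples.append((NodeRef(gene_id, "gene", species), term, evidence))
    return AnnotationSet.from_tuples(tuples)


def filter_annotations(
    a: AnnotationSet, allowed: frozenset[str] = DEFAULT_EVIDENCE_CODES
) -> AnnotationSet:
    """Keep only records whose evidence code is in ``allowed``."""
    if not allowed:
        raise ValueError("allowed evidence code set is empty")
    kept = frozenset(r for r in a.records if r.evidence in allowed)
    if not kept:
        logger.info("evidence filter removed every annotation record")
    return AnnotationSet(kept)


@dataclass(frozen=True)
class TermClosure:
    term: str
    genes: frozenset[NodeRef]

    @property
    def size(self) -> int:
        return len(self.genes)


def term_closure(dag: OntologyDAG, a: AnnotationSet, term: str) -> TermClosure:
    """Genes annotated to ``term`` or any descendant (each counted once)."""
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    genes = set(a.direct_genes(term))
    for d in dag.descendants(term):
        genes |= a.direct_genes(d)
    return TermClosure(term, frozenset(genes))


def all_closures(dag: OntologyDAG, a: AnnotationSet) -> dict[str, TermClosure]:
    """Closures for every term in one bottom-up pass over the DAG."""
    direct: dict[str, set[NodeRef]] = {t: set() for t in dag.terms}
    for r in a.records:
        if r.term in direct:
            direct[r.term].add(r.gene)
    closures: dict[str, frozenset[NodeRef]] = {}
    order = nx.topological_sort(dag._dag)  # children before parents
    children = dag.children_map()
    for t in order:
        acc = set(direct[t])
        for c in children[t]:
            acc |= closures[c]
        closures[t] = frozenset(acc)
    return {t: TermClosure(t, g) for t, g in closures.items()}


def annotation_edges(
    dag: OntologyDAG, a: AnnotationSet, max_closure: int = 200
) -> list[EdgeRecord]:
    """Gene-term and term-term edges for the heterogeneous graph.

    Terms whose closure holds at most ``max_closure`` genes contribute an
    annotation edge for every closure gene; larger (too-general) terms keep
    only their direct annotation edges so their genes stay connected without
    flooding the graph. Every parent link becomes a term-term ontology edge.
    Output is independent of term iteration order.
    """
    closures = all_closures(dag, a)
    edges: dict[tuple, EdgeRecord] = {}
    for t in sorted(dag.terms):
        cl = closures[t]
        genes = cl.genes if 0 < cl.size <= max_closure else a.direct_genes(t)
        for g in sorted(genes, key=lambda n: n.identifier):
            rec = EdgeRecord(g, NodeRef(t, "term"), "annotation")
            edges.setdefault(rec.key, rec)
    for child in sorted(dag.parents):
        for parent, _rel in sorted(dag.parents[child]):
            rec = EdgeRecord(NodeRef(child, "term"), NodeRef(parent, "term"), "ontology")
            edges.setdefault(rec.key, rec)
    return list(edges.values())


def information_content(
    a: AnnotationSet,
    dag: OntologyDAG,
    term: str,
    closures: Optional[dict[str, TermClosure]] = None,
) -> float:
    """IC(t) = -ln(|closure(t)| / |closure(root)|); 0 at the root.

    Natural log; the base only rescales Resnik values and cancels in Lin.
    """
    if closures is None:
        closures = all_closures(dag, a)
    if term not in closures:
        raise KeyError(f"unknown term {term!r}")
    corpus = closures[dag.root].size
    if corpus == 0:
        raise ValueError("annotation corpus is empty")
    size = closures[term].size
    if size == 0:
        raise ValueError(f"term {term!r} has an empty closure; IC undefined")
    return -math.log(size / corpus)
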