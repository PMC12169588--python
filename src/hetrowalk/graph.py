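"""Typed heterogeneous graph assembly and perturbation.

The knowledge graph mixes several node kinds — genes (per species), curated
gene sets, ontology terms — and several undirected, unweighted edge relations
(protein-protein interaction, pathway co-membership, gene-set membership,
term annotation, term-term ontology links, cross-species homology). A
single-species (ss) graph omits homology; adding other species' layers joined
by homology edges yields the multi-species (ms) variant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

NODE_KINDS = ("gene", "geneset", "term", "homolog_cluster")
SPECIES = ("human", "mouse", "rat")
RELATIONS = ("ppi", "pathway", "membership", "annotation", "ontology", "homology")


@dataclass(frozen=True, order=True)
class NodeRef:
    """A namespaced node: identifier, kind, and (for genes) species."""

    identifier: str
    kind: str = "gene"
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "gene" and self.species is None:
            raise ValueError(f"gene node {self.identifier!r} requires a species")
        if self.kind != "gene" and self.species is not None:
            raise ValueError(f"{self.kind} node {self.identifier!r} must not set species")
        if self.species is not None and self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")


@dataclass(frozen=True)
class EdgeRecord:
    """Undirected, unweighted edge between two nodes under one relation."""

    u: NodeRef
    v: NodeRef
    relation: str

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.u.identifier == self.v.identifier:
            raise ValueError("self-loop edge")

    @property
    def key(self) -> tuple:
        a, b = sorted((self.u.identifier, self.v.identifier))
        return (a, b, self.relation)


class HeteroGraph:
    """Undirected heterogeneous graph backed by :class:`networkx.Graph`.

    Node keys are identifiers; node attributes carry ``kind`` and ``species``,
    edge attributes carry ``relation``. ``provenance`` maps a source label to
    the number of edges it contributed.
    """

    def __init__(self, g: Optional[nx.Graph] = None, provenance: Optional[dict] = None):
        self.g = g if g is not None else nx.Graph()
        self.provenance: dict[str, int] = dict(provenance or {})

    # -- introspection -------------------------------------------------
    def __len__(self) -> int:
        return self.g.number_of_nodes()

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def node_ref(self, identifier: str) -> NodeRef:
        d = self.g.nodes[identifier]
        return NodeRef(identifier, d["kind"], d.get("species"))

    def nodes(self, kind: Optional[str] = None) -> list[NodeRef]:
        return [
            NodeRef(n, d["kind"], d.get("species"))
            for n, d in sorted(self.g.nodes(data=True))
            if kind is None or d["kind"] == kind
        ]

    def genes(self, species: Optional[str] = None) -> list[NodeRef]:
        return [
            n for n in self.nodes("gene") if species is None or n.species == species
        ]

    def has_node(self, identifier: str) -> bool:
        return identifier in self.g

    def edges(self) -> list[EdgeRecord]:
        out = []
        for u, v, d in self.g.edges(data=True):
            out.append(EdgeRecord(self.node_ref(u), self.node_ref(v), d["relation"]))
        return out

    def copy(self) -> "HeteroGraph":
        return HeteroGraph(self.g.copy(), dict(self.provenance))

    # -- construction --------------------------------------------------
    def _add_node(self, n: NodeRef) -> None:
        if n.identifier in self.g:
            d = self.g.nodes[n.identifier]
            if d["kind"] != n.kind:
                raise ValueError(
                    f"node {n.identifier!r} declared both {d['kind']} and {n.kind}"
                )
        else:
            self.g.add_node(n.identifier, kind=n.kind, species=n.species)

    def add_edges(self, records: Iterable[EdgeRecord], source: str) -> int:
        added = 0
        for r in records:
            self._add_node(r.u)
            self._add_node(r.v)
            if not self.g.has_edge(r.u.identifier, r.v.identifier):
                self.g.add_edge(r.u.identifier, r.v.identifier, relation=r.relation)
                added += 1
        self.provenance[source] = self.provenance.get(source, 0) + added
        return added

    # -- serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodes": [
                {"id": n, "kind": d["kind"], "species": d.get("species")}
                for n, d in sorted(self.g.nodes(data=True))
            ],
            "edges": [
                {"u": u, "v": v, "relation": d["relation"]}
                for u, v, d in sorted(self.g.edges(data=True), key=lambda e: (e[0], e[1]))
            ],
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "HeteroGraph":
        payload = json.loads(Path(path).read_text())
        g = nx.Graph()
        for n in payload["nodes"]:
            g.add_node(n["id"], kind=n["kind"], species=n.get("species"))
        for e in payload["edges"]:
            g.add_edge(e["u"], e["v"], relation=e["relation"])
        return cls(g, payload.get("provenance", {}))


def _parse_node(token: str, kind: str, species: Optional[str]) -> NodeRef:
    if kind == "gene":
        return NodeRef(token, "gene", species)
    return NodeRef(token, kind)


def load_edge_list(
    path: str | Path,
    relation: str,
    default_species: Optional[str] = None,
    *,
    u_kind: str = "gene",
    v_kind: str = "gene",
    min_count: Optional[int] = None,
) -> list[EdgeRecord]:
    """Read a whitespace/tab-delimited two(+)-column edge list.

    Lines starting with ``#`` are comments. An optional third numeric column
    is an orthology support count; when ``min_count`` is given, rows below it
    are dropped (used for homology edge lists that report how many orthology
    algorithms support each pair). Undirected duplicates are collapsed;
    self-loops are dropped with a logged count.
    """
    path = Path(path)
    records: dict[tuple, EdgeRecord] = {}
    self_loops = 0
    below_count = 0
    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n_lines += 1
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
        u, v = parts[0], parts[1]
        if min_count is not None and len(parts) >= 3:
            try:
                count = int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count column {parts[2]!r}") from exc
            if count < min_count:
                below_count += 1
                continue
        if u == v:
            self_loops += 1
            continue
        rec = EdgeRecord(
            _parse_node(u, u_kind, default_species),
            _parse_node(v, v_kind, default_species),
            relation,
        )
        records.setdefault(rec.key, rec)
    if n_lines == 0:
        raise ValueError(f"{path}: empty edge list")
    if self_loops:
        logger.info("%s: dropped %d self-loop(s)", path, self_loops)
    if below_count:
        logger.info("%s: dropped %d edge(s) below orthology count threshold", path, below_count)
    return list(records.values())


def expand_homology_clusters(
    path: str | Path, species_of: dict[str, str]
) -> list[EdgeRecord]:
    """Expand a cluster file (cluster id + member genes per line) to a clique
    of gene-gene homology edges between members of different species."""
    path = Path(path)
    records: dict[tuple, EdgeRecord] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: cluster needs an id and >=2 members")
        members = parts[1:]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a == b:
                    continue
                sa, sb = species_of.get(a), species_of.get(b)
                if sa is None or sb is None:
                    raise ValueError(f"{path}:{lineno}: unknown species for {a!r} or {b!r}")
                if sa == sb:
                    continue  # within-species paralogs carry no cross-species signal
                rec = EdgeRecord(NodeRef(a, "gene", sa), NodeRef(b, "gene", sb), "homology")
                records.setdefault(rec.key, rec)
    return list(records.values())


def assemble_heterograph(
    sources: Sequence[tuple[Sequence[EdgeRecord], str]],
    homology: Optional[Sequence[EdgeRecord]] = None,
) -> HeteroGraph:
    """Union the edge-record sources into one graph.

    ``sources`` is a list of ``(records, source_name)``. Supplying homology
    edges produces the multi-species (ms) variant; omitting them the
    single-species (ss) one. Isolated nodes are removed (a walk from or to an
    isolate is degenerate). Assembly is order-independent.
    """
    if not sources:
        raise ValueError("no sources given")
    hg = HeteroGraph()
    for records, name in sources:
        if not records:
            raise ValueError(f"source {name!r} is empty")
        hg.add_edges(records, name)
    if homology is not None:
        for r in homology:
            if r.relation != "homology":
                raise ValueError(f"non-homology edge {r.key} passed as homology")
            if r.u.kind != "gene" or r.v.kind != "gene" or r.u.species == r.v.species:
                raise ValueError(
                    f"homology edge must join genes of different species: "
                    f"{r.u.identifier}–{r.v.identifier}"
                )
        hg.add_edges(homology, "homology")
    isolates = list(nx.isolates(hg.g))
    if isolates:
        logger.info("dropping %d isolated node(s)", len(isolates))
        hg.g.remove_nodes_from(isolates)
    n_comp = nx.number_connected_components(hg.g)
    if n_comp > 1:
        logger.warning("assembled graph has %d connected components", n_comp)
    return hg


def perturb_edges(
    hg: HeteroGraph, fraction: float, mode: str, seed: int
) -> HeteroGraph:
    """Randomly add or remove ``round(fraction * |E|)`` edges.

    Models noise (add) and missing data (remove); the studied range is up to
    30% of edges. Added edges are sampled uniformly among unconnected node
    pairs and typed ``ppi``; removed edges are drawn uniformly from the
    existing edge set. Deterministic given ``seed``; input is not modified.
    """
    if not 0 < fraction <= 0.3:
        raise ValueError(f"fraction must be in (0, 0.3], got {fraction}")
    if mode not in ("add", "remove"):
        raise ValueError(f"mode must be 'add' or 'remove', got {mode!r}")
    m = hg.n_edges()
    k = round(fraction * m)
    if k < 1:
        raise ValueError("fraction too small: no edges to perturb after rounding")
    rng = np.random.default_rng(seed)
    out = hg.copy()
    if mode == "remove":
        edges = sorted(out.g.edges())
        idx = rng.choice(len(edges), size=k, replace=False)
        out.g.remove_edges_from(edges[i] for i in idx)
        isolates = list(nx.isolates(out.g))
        if isolates:
            logger.info("edge removal isolated %d node(s); dropping them", len(isolates))
            out.g.remove_nodes_from(isolates)
        out.provenance[f"perturb_remove_{fraction}"] = -k
    else:
        nodes = sorted(out.g.nodes())
        n = len(nodes)
        if n * (n - 1) // 2 - m < k:
            raise ValueError(f"graph too small to add {k} new edges")
        added = 0
        while added < k:
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            u, v = nodes[i], nodes[j]
            if out.g.has_edge(u, v):
                continue
            out.g.add_edge(u, v, relation="ppi")
            added += 1
        out.provenance[f"perturb_add_{fraction}"] = k
    return out
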