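import numpy as np
import pytest

from hetrowalk import (
    AnnotationSet,
    EdgeRecord,
    NodeRef,
    OntologyDAG,
    assemble_heterograph,
)


def gene(name, species="human"):
    return NodeRef(name, "gene", species)


def ppi_edge(a, b, species="human"):
    return EdgeRecord(gene(a, species), gene(b, species), "ppi")


def graph_from_pairs(pairs, species="human"):
    """Small single-species ppi graph from (u, v) pairs."""
    recs = [ppi_edge(a, b, species) for a, b in pairs]
    return assemble_heterograph([(recs, "ppi")])


@pytest.fixture
def path2():
    """Two nodes, one edge: A - B."""
    return graph_from_pairs([("A", "B")])


@pytest.fixture
def triangle():
    return graph_from_pairs([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star():
    """Center c with three leaves."""
    return graph_from_pairs([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def chain_dag():
    """root -> a -> b is_a chain."""
    return OntologyDAG(
        parents={"a": {("root", "is_a")}, "b": {("a", "is_a")}}, root="root"
    )


@pytest.fixture
def diamond_dag():
    """Two paths from d up to root: d -> {a, b} -> root."""
    return OntologyDAG(
        parents={
            "a": {("root", "is_a")},
            "b": {("root", "part_of")},
            "d": {("a", "is_a"), ("b", "is_a")},
        },
        root="root",
    )


@pytest.fixture
def chain_annotations():
    """Eight genes spread over the chain DAG: 4 at b, 2 at a, 2 at root."""
    return AnnotationSet.from_tuples(
        [(gene(f"g{i}"), "b", "IDA") for i in range(4)]
        + [(gene(f"g{i}"), "a", "IMP") for i in range(4, 6)]
        + [(gene(f"g{i}"), "root", "TAS") for i in range(6, 8)]
    )


def circulant_graph(n, chords):
    """Vertex-transitive circulant graph on gene nodes."""
    recs = []
    for i in range(n):
        for c in chords:
            recs.append(ppi_edge(f"g{i}", f"g{(i + c) % n}"))
    return assemble_heterograph([(recs, "circ")])
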