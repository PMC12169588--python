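"""Synthetic multi-species fixtures with the structure the method assumes.

The generator emulates the shape of the real inputs without any download:

* per species, a stochastic-block protein-interaction layer whose planted
  modules are dense gene communities on a sparse background; module
  membership is conserved across species, so 1:1:1 orthology edges carry
  the module signal between layers;
* the human layer is *thinned* inside modules (a tunable retention
  fraction), emulating the incompleteness of human interaction data that
  motivates borrowing signal from model organisms;
* gene-set nodes attached to the human disease module (curated gene-set
  emulation);
* a balanced ontology DAG with leaf annotations under experimental
  evidence codes;
* pathway collections drawn from the planted modules with controlled
  overlap, including one 4-gene and one 6-gene pathway to probe the
  small-pathway regime.

Everything is deterministic given the spec's ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .graph import EdgeRecord, HeteroGraph, NodeRef, assemble_heterograph
from .ontology import (
    DEFAULT_EVIDENCE_CODES,
    AnnotationSet,
    OntologyDAG,
)
from .semsim import PathwayCollection


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions."""

    n_genes_per_species: int = 80
    species: tuple[str, ...] = ("human", "mouse", "rat")
    p_within: float = 0.6
    p_between: float = 0.03
    n_disease_genes: int = 12
    homology_coverage: float = 0.9
    human_edge_retention: float = 0.5
    ontology_depth: int = 3
    ontology_branching: int = 3
    n_pathways: int = 6
    pathway_size: int = 8
    pathway_overlap: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_between < self.p_within <= 1:
            raise ValueError("need 0 <= p_between < p_within <= 1")
        if not 0 <= self.homology_coverage <= 1:
            raise ValueError("homology_coverage must be in [0,1]")
        if not 0 < self.human_edge_retention <= 1:
            raise ValueError("human_edge_retention must be in (0,1]")
        if self.n_disease_genes < 1:
            raise ValueError("empty disease module")
        if self.n_pathways * self.n_disease_genes > self.n_genes_per_species:
            raise ValueError(
                "planted modules do not fit: n_pathways * n_disease_genes "
                "exceeds n_genes_per_species"
            )
        if self.pathway_overlap > min(4, self.pathway_size):
            raise ValueError("pathway_overlap exceeds the smallest pathway size")


def _gene(species: str, i: int) -> NodeRef:
    return NodeRef(f"{species}:g{i}", "gene", species)


def _module_of(spec: FixtureSpec, i: int) -> Optional[int]:
    """Module index of gene index i, or None for background genes."""
    m = i // spec.n_disease_genes
    return m if m < spec.n_pathways else None


def _species_layer(
    spec: FixtureSpec, species: str, rng: np.random.Generator
) -> list[EdgeRecord]:
    """Stochastic-block ppi layer; human within-module edges are thinned."""
    n = spec.n_genes_per_species
    records = []
    for i in range(n):
        for j in range(i + 1, n):
            mi, mj = _module_of(spec, i), _module_of(spec, j)
            within = mi is not None and mi == mj
            p = spec.p_within if within else spec.p_between
            if within and species == "human":
                p *= spec.human_edge_retention
            if rng.random() < p:
                records.append(
                    EdgeRecord(_gene(species, i), _gene(species, j), "ppi")
                )
    return records


def _geneset_edges(spec: FixtureSpec, rng: np.random.Generator) -> list[EdgeRecord]:
    """Two curated gene-set nodes attached to the human disease module."""
    records = []
    disease = list(range(spec.n_disease_genes))
    for gs_i in (1, 2):
        gs = NodeRef(f"gsid:GS{gs_i}", "geneset")
        for i in disease:
            if rng.random() < 0.7:
                records.append(EdgeRecord(_gene("human", i), gs, "membership"))
    return records


def _homology_edges(spec: FixtureSpec, rng: np.random.Generator) -> list[EdgeRecord]:
    """1:1:1 ortholog cliques at the given coverage."""
    records = []
    for i in range(spec.n_genes_per_species):
        if rng.random() >= spec.homology_coverage:
            continue
        members = [_gene(sp, i) for sp in spec.species]
        for a_idx in range(len(members)):
            for b_idx in range(a_idx + 1, len(members)):
                records.append(
                    EdgeRecord(members[a_idx], members[b_idx], "homology")
                )
    return records


@dataclass
class FixtureBundle:
    """All raw edge sources of one synthetic study, pre-assembly."""

    spec: FixtureSpec
    ppi: dict[str, list[EdgeRecord]]
    genesets: list[EdgeRecord]
    homology: list[EdgeRecord]
    disease_genes: list[str] = field(default_factory=list)

    def single_species_graph(self) -> HeteroGraph:
        sources = [(self.ppi["human"], "ppi_human"), (self.genesets, "genesets")]
        return assemble_heterograph(sources)

    def multi_species_graph(self) -> HeteroGraph:
        sources = [(self.ppi[sp], f"ppi_{sp}") for sp in self.spec.species]
        sources.append((self.genesets, "genesets"))
        homology = self.homology if self.homology else None
        return assemble_heterograph(sources, homology=homology)


def synth_fixture_bundle(spec: FixtureSpec) -> FixtureBundle:
    rng = np.random.default_rng(spec.rng_seed)
    ppi = {sp: _species_layer(spec, sp, rng) for sp in spec.species}
    genesets = _geneset_edges(spec, rng)
    homology = _homology_edges(spec, rng) if len(spec.species) > 1 else []
    disease = [f"human:g{i}" for i in range(spec.n_disease_genes)]
    return FixtureBundle(spec, ppi, genesets, homology, disease)


def synth_multispecies_graph(spec: FixtureSpec) -> tuple[HeteroGraph, list[str]]:
    """Assembled multi-species graph plus the planted disease gene list."""
    bundle = synth_fixture_bundle(spec)
    return bundle.multi_species_graph(), bundle.disease_genes


def synth_ontology(
    depth: int,
    branching: int,
    genes: Sequence[NodeRef],
    seed: int = 0,
    p_crosslink: float = 0.1,
) -> tuple[OntologyDAG, AnnotationSet]:
    """Balanced is_a tree of the given depth/branching with sparse part_of
    cross-links; genes are annotated to leaves with experimental evidence
    codes, cycling over leaves so every leaf is used."""
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    n_leaves = branching**depth
    if genes and n_leaves < 1:
        raise ValueError("not enough leaves for annotation")
    rng = np.random.default_rng(seed)
    parents: dict[str, set[tuple[str, str]]] = {}
    levels: list[list[str]] = [["T0"]]
    counter = 1
    for d in range(1, depth + 1):
        level = []
        for parent in levels[d - 1]:
            for _ in range(branching):
                t = f"T{counter}"
                counter += 1
                parents[t] = {(parent, "is_a")}
                level.append(t)
        levels.append(level)
    # sparse part_of cross-links from leaves to non-ancestral internal terms
    internal = [t for lvl in levels[:-1] for t in lvl]
    for leaf in levels[-1]:
        if rng.random() < p_crosslink and len(internal) > 1:
            target = internal[int(rng.integers(len(internal)))]
            if target != "T0":
                parents[leaf].add((target, "part_of"))
    dag = OntologyDAG(parents=parents, root="T0")
    codes = sorted(DEFAULT_EVIDENCE_CODES)
    leaves = levels[-1]
    tuples = []
    for i, g in enumerate(genes):
        leaf = leaves[i % len(leaves)]
        code = codes[int(rng.integers(len(codes)))]
        tuples.append((g, leaf, code))
    return dag, AnnotationSet.from_tuples(tuples)


def synth_pathways(spec: FixtureSpec) -> PathwayCollection:
    """Pathways drawn from the planted human modules.

    Pathway k takes its genes from module k; consecutive pathways share
    ``pathway_overlap`` genes. The first two pathways have 4 and 6 genes
    (the small-pathway regime); the rest use ``pathway_size``.
    """
    sizes = [4, 6] + [spec.pathway_size] * (spec.n_pathways - 2)
    sizes = sizes[: spec.n_pathways]
    m = spec.n_disease_genes
    pathways = []
    for k, size in enumerate(sizes):
        if size > m:
            raise ValueError(f"pathway size {size} exceeds module size {m}")
        genes = [f"human:g{k * m + j}" for j in range(size)]
        if k > 0 and spec.pathway_overlap > 0:
            shared = [f"human:g{(k - 1) * m + j}" for j in range(spec.pathway_overlap)]
            genes = shared + genes[: size - len(shared)]
        pathways.append((f"path{k}", genes))
    return PathwayCollection(pathways)


# ------------------------------------------------------------ file output
def write_edge_tsv(records: Sequence[EdgeRecord], path: str | Path) -> None:
    lines = ["# u\tv"]
    for r in sorted(records, key=lambda r: r.key):
        lines.append(f"{r.u.identifier}\t{r.v.identifier}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_homology_clusters(
    spec: FixtureSpec, homology: Sequence[EdgeRecord], path: str | Path
) -> None:
    """One ortholog cluster per line: cluster id then member genes."""
    clusters: dict[int, set[str]] = {}
    for r in homology:
        i = int(r.u.identifier.rsplit("g", 1)[1])
        clusters.setdefault(i, set()).update({r.u.identifier, r.v.identifier})
    lines = [
        f"HC{i}\t" + "\t".join(sorted(members))
        for i, members in sorted(clusters.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    chunks = ["format-version: 1.2", ""]
    for term in sorted(dag.terms):
        chunks.append("[Term]")
        chunks.append(f"id: {term}")
        chunks.append(f"name: synthetic term {term}")
        for parent, rel in sorted(dag.parents.get(term, ())):
            if rel == "is_a":
                chunks.append(f"is_a: {parent} ! {parent}")
            else:
                chunks.append(f"relationship: {rel} {parent} ! {parent}")
        chunks.append("")
    Path(path).write_text("\n".join(chunks))


def write_gaf(annotations: AnnotationSet, path: str | Path) -> None:
    lines = ["!gaf-version: 2.2"]
    recs = sorted(
        annotations.records, key=lambda r: (r.gene.identifier, r.term, r.evidence)
    )
    for r in recs:
        cols = [""] * 17
        cols[0] = "synthdb"
        cols[1] = r.gene.identifier
        cols[2] = r.gene.identifier.split(":")[-1]
        cols[4] = r.term
        cols[5] = "SYNTH:0000001"
        cols[6] = r.evidence
        cols[8] = "P"
        cols[11] = "protein"
        cols[12] = f"taxon:{r.gene.species}"
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write every file format the pipeline consumes; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = synth_fixture_bundle(spec)
    paths: dict[str, Path] = {}
    for sp in spec.species:
        p = out / f"ppi_{sp}.tsv"
        write_edge_tsv(bundle.ppi[sp], p)
        paths[f"ppi_{sp}"] = p
    paths["genesets"] = out / "genesets.tsv"
    write_edge_tsv(bundle.genesets, paths["genesets"])
    if bundle.homology:
        paths["homology"] = out / "homology_clusters.tsv"
        write_homology_clusters(spec, bundle.homology, paths["homology"])
    human_genes = [_gene("human", i) for i in range(spec.n_genes_per_species)]
    dag, ann = synth_ontology(
        spec.ontology_depth, spec.ontology_branching, human_genes, spec.rng_seed
    )
    paths["obo"] = out / "ontology.obo"
    write_obo(dag, paths["obo"])
    paths["gaf"] = out / "annotations.gaf"
    write_gaf(ann, paths["gaf"])
    paths["gmt"] = out / "pathways.gmt"
    synth_pathways(spec).to_gmt(paths["gmt"])
    paths["disease"] = out / "disease_genes.txt"
    paths["disease"].write_text("\n".join(bundle.disease_genes) + "\n")
    return paths
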