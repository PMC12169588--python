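import math

import numpy as np
import pytest

from hetrowalk import (
    AnnotationSet,
    PathwayCollection,
    SimilarityMatrix,
    discriminative_power,
    gene_functional_similarity,
    information_content,
    interset_sim,
    intraset_sim,
    simterms,
    term_similarity,
)
from hetrowalk.semsim import SemanticContext
from conftest import gene


@pytest.fixture
def chain_ann(chain_dag):
    """root->a->b chain with genes at every level (corpus of 8)."""
    return AnnotationSet.from_tuples(
        [(gene(f"g{i}"), "b", "IDA") for i in range(4)]
        + [(gene(f"g{i}"), "a", "IMP") for i in range(4, 6)]
        + [(gene(f"g{i}"), "root", "TAS") for i in range(6, 8)]
    )


class TestTermSimilarity:
    def test_root_self_similarity(self, chain_dag, chain_ann):
        assert term_similarity("root", "root", "resnik", chain_dag, chain_ann) == 0.0
        assert term_similarity("root", "root", "jaccard", chain_dag, chain_ann) == 1.0
        assert term_similarity("root", "root", "cosine", chain_dag, chain_ann) == 1.0

    def test_lin_self_similarity_is_one(self, chain_dag, chain_ann):
        assert term_similarity("b", "b", "lin", chain_dag, chain_ann) == pytest.approx(1.0)

    def test_chain_jaccard(self, chain_dag, chain_ann):
        # Anc(a) = {root, a}; Anc(b) = {root, a, b}
        assert term_similarity("a", "b", "jaccard", chain_dag, chain_ann) == pytest.approx(2 / 3)

    def test_chain_cosine(self, chain_dag, chain_ann):
        assert term_similarity("a", "b", "cosine", chain_dag, chain_ann) == pytest.approx(
            2 / math.sqrt(2 * 3)
        )

    def test_resnik_is_mica_ic(self, chain_dag, chain_ann):
        # MICA of (a, b) is a itself
        expected = information_content(chain_ann, chain_dag, "a")
        assert term_similarity("a", "b", "resnik", chain_dag, chain_ann) == pytest.approx(expected)

    def test_lin_closed_form(self, chain_dag, chain_ann):
        ica = information_content(chain_ann, chain_dag, "a")
        icb = information_content(chain_ann, chain_dag, "b")
        assert term_similarity("a", "b", "lin", chain_dag, chain_ann) == pytest.approx(
            2 * ica / (ica + icb)
        )

    def test_unknown_term_rejected(self, chain_dag, chain_ann):
        with pytest.raises(KeyError):
            term_similarity("a", "nope", "lin", chain_dag, chain_ann)


class TestSimterms:
    def test_self_in_set_maxes_normalized_measure(self, chain_dag, chain_ann):
        assert simterms("b", ["a", "b"], "lin", chain_dag, chain_ann) == pytest.approx(1.0)

    def test_singleton_set(self, chain_dag, chain_ann):
        direct = term_similarity("a", "b", "lin", chain_dag, chain_ann)
        assert simterms("a", ["b"], "lin", chain_dag, chain_ann) == pytest.approx(direct)

    def test_is_max_over_pairs(self, chain_dag, chain_ann):
        vals = [
            term_similarity("b", t, "jaccard", chain_dag, chain_ann) for t in ("root", "a")
        ]
        assert simterms("b", ["root", "a"], "jaccard", chain_dag, chain_ann) == max(vals)

    def test_empty_set_rejected(self, chain_dag, chain_ann):
        with pytest.raises(ValueError):
            simterms("a", [], "lin", chain_dag, chain_ann)


class TestGeneFunctionalSimilarity:
    def test_identical_singleton_annotations(self, chain_dag, chain_ann):
        # both genes annotated only to b
        assert gene_functional_similarity("g0", "g1", "lin", chain_dag, chain_ann) == pytest.approx(1.0)

    def test_resnik_identical_terms_gives_ic(self, chain_dag, chain_ann):
        icb = information_content(chain_ann, chain_dag, "b")
        assert gene_functional_similarity("g0", "g1", "resnik", chain_dag, chain_ann) == pytest.approx(icb)

    def test_hand_best_match_average(self, chain_dag):
        # T1 = {a}, T2 = {a, b}: (max(a,T2) + max(a,T1) + max(b,T1)) / 3
        ann = AnnotationSet.from_tuples(
            [(gene("x"), "a", "IDA"), (gene("y"), "a", "IDA"), (gene("y"), "b", "IDA"),
             (gene("z"), "b", "IDA")]
        )
        lin_ab = term_similarity("a", "b", "lin", chain_dag, ann)
        expected = (1.0 + 1.0 + lin_ab) / 3
        got = gene_functional_similarity("x", "y", "lin", chain_dag, ann)
        assert got == pytest.approx(expected)

    def test_unannotated_gene_is_missing(self, chain_dag, chain_ann):
        v = gene_functional_similarity("g0", "ghost", "lin", chain_dag, chain_ann)
        assert math.isnan(v)

    def test_symmetric(self, chain_dag, chain_ann):
        a = gene_functional_similarity("g0", "g5", "jaccard", chain_dag, chain_ann)
        b = gene_functional_similarity("g5", "g0", "jaccard", chain_dag, chain_ann)
        assert a == pytest.approx(b)

    @pytest.mark.parametrize("measure", ["lin", "jaccard", "cosine"])
    def test_normalized_measures_bounded(self, chain_dag, chain_ann, measure):
        for g1 in ("g0", "g4", "g6"):
            for g2 in ("g1", "g5", "g7"):
                v = gene_functional_similarity(g1, g2, measure, chain_dag, chain_ann)
                assert 0.0 <= v <= 1.0 + 1e-12


class TestOracleEquivalence:
    """Best-match-average agrees with an exhaustive double loop."""

    def bma_oracle(self, g1, g2, measure, dag, ann):
        T1 = sorted(ann.terms_of(g1))
        T2 = sorted(ann.terms_of(g2))
        total = 0.0
        for t in T1:
            total += max(term_similarity(t, t2, measure, dag, ann) for t2 in T2)
        for t in T2:
            total += max(term_similarity(t, t1, measure, dag, ann) for t1 in T1)
        return total / (len(T1) + len(T2))

    @pytest.mark.parametrize("measure", ["resnik", "lin", "jaccard", "cosine"])
    def test_toy_dag_all_measures(self, measure):
        from hetrowalk import synth_ontology

        genes = [gene(f"G{i}") for i in range(10)]
        dag, ann = synth_ontology(depth=2, branching=3, genes=genes, seed=5)
        # give some genes multiple annotations
        extra = [(gene("G0"), "T1", "IDA"), (gene("G1"), "T2", "IMP")]
        ann = AnnotationSet(ann.records | AnnotationSet.from_tuples(extra).records)
        ids = [g.identifier for g in genes]
        for i in range(len(ids)):
            for j in range(i, len(ids)):
                got = gene_functional_similarity(ids[i], ids[j], measure, dag, ann)
                want = self.bma_oracle(ids[i], ids[j], measure, dag, ann)
                assert got == pytest.approx(want, abs=1e-12)


def matrix(genes, values, measure="lin"):
    return SimilarityMatrix(genes=genes, values=np.array(values, dtype=float), measure=measure)


class TestSetSimilarity:
    def test_intraset_all_ones(self):
        M = matrix(["a", "b"], [[1, 1], [1, 1]])
        assert intraset_sim(["a", "b"], M) == pytest.approx(1.0)

    def test_intraset_includes_diagonal(self):
        M = matrix(["a", "b"], [[1, 0.8], [0.8, 1]])
        assert intraset_sim(["a", "b"], M) == pytest.approx(0.9)

    def test_single_gene_pathway_is_diagonal(self):
        M = matrix(["a", "b"], [[0.7, 0.1], [0.1, 1.0]])
        assert intraset_sim(["a"], M) == pytest.approx(0.7)

    def test_interset_of_identical_pathways_is_intraset(self):
        M = matrix(["a", "b"], [[1, 0.5], [0.5, 1]])
        assert interset_sim(["a", "b"], ["a", "b"], M) == pytest.approx(
            intraset_sim(["a", "b"], M)
        )

    def test_interset_constant_cross_block(self):
        M = matrix(
            ["a", "b", "c", "d"],
            [
                [1, 0.9, 0.2, 0.2],
                [0.9, 1, 0.2, 0.2],
                [0.2, 0.2, 1, 0.9],
                [0.2, 0.2, 0.9, 1],
            ],
        )
        assert interset_sim(["a", "b"], ["c", "d"], M) == pytest.approx(0.2)

    def test_missing_gene_excluded_with_log(self):
        M = matrix(["a", "b", "c"], [[1, 0.5, np.nan], [0.5, 1, np.nan], [np.nan] * 3])
        assert intraset_sim(["a", "b", "c"], M) == pytest.approx((1 + 0.5 + 0.5 + 1) / 4)

    def test_empty_after_exclusion_rejected(self):
        M = matrix(["a"], [[np.nan]])
        with pytest.raises(ValueError):
            intraset_sim(["a"], M)


class TestDiscriminativePower:
    def two_block(self):
        M = matrix(
            ["g1", "g2", "g3", "g4"],
            [
                [0.9, 0.9, 0.2, 0.2],
                [0.9, 0.9, 0.2, 0.2],
                [0.2, 0.2, 0.9, 0.9],
                [0.2, 0.2, 0.9, 0.9],
            ],
        )
        coll = PathwayCollection([("S1", ["g1", "g2"]), ("S2", ["g3", "g4"])])
        return M, coll

    def test_hand_example(self):
        M, coll = self.two_block()
        assert discriminative_power("S1", coll, M) == pytest.approx(4.5)

    def test_identical_pathways_give_one(self):
        M = matrix(["a", "b"], [[1, 0.4], [0.4, 1]])
        coll = PathwayCollection([("S1", ["a", "b"]), ("S2", ["a", "b"])])
        assert discriminative_power("S1", coll, M) == pytest.approx(1.0)

    def test_uniform_scaling_invariance(self):
        M, coll = self.two_block()
        scaled = SimilarityMatrix(M.genes, 2.0 * M.values, M.measure)
        assert discriminative_power("S1", coll, scaled) == pytest.approx(
            discriminative_power("S1", coll, M)
        )

    def test_gene_order_invariance(self):
        M, _ = self.two_block()
        c1 = PathwayCollection([("S1", ["g1", "g2"]), ("S2", ["g3", "g4"])])
        c2 = PathwayCollection([("S1", ["g2", "g1"]), ("S2", ["g4", "g3"])])
        assert discriminative_power("S1", c1, M) == pytest.approx(
            discriminative_power("S1", c2, M)
        )

    def test_exhaustive_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(12)]
        raw = rng.random((12, 12))
        vals = (raw + raw.T) / 2
        M = matrix(genes, vals)
        coll = PathwayCollection(
            [
                ("P0", genes[0:4]),
                ("P1", genes[3:8]),
                ("P2", genes[8:10]),
                ("P3", genes[9:12]),
            ]
        )
        gi = {g: i for i, g in enumerate(genes)}
        for pid in coll.ids():
            b = coll.genes_of(pid)
            intra = sum(vals[gi[x], gi[y]] for x in b for y in b) / len(b) ** 2
            inter_total = 0.0
            for other in coll.ids():
                if other == pid:
                    continue
                c = coll.genes_of(other)
                inter_total += sum(vals[gi[x], gi[y]] for x in b for y in c) / (
                    len(b) * len(c)
                )
            want = (len(coll) - 1) * intra / inter_total
            assert discriminative_power(pid, coll, M) == pytest.approx(want)

    def test_single_pathway_collection_rejected(self):
        M = matrix(["a"], [[1.0]])
        with pytest.raises(ValueError):
            discriminative_power("S1", PathwayCollection([("S1", ["a"])]), M)


class TestGmtRoundtrip:
    def test_roundtrip(self, tmp_path):
        coll = PathwayCollection([("p1", ["a", "b"]), ("p2", ["c"])])
        coll.to_gmt(tmp_path / "p.gmt")
        back = PathwayCollection.from_gmt(tmp_path / "p.gmt")
        assert back.pathways == coll.pathways
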