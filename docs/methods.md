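# Methods

## Graph model

The knowledge graph is undirected, unweighted, and typed: nodes are genes
(with a species), gene sets, or ontology terms; edges carry one relation
out of {ppi, pathway, membership, annotation, ontology, homology}. All
sources are unioned; duplicate undirected edges collapse; self-loops are
dropped at load time; isolated nodes are removed (a restart walk from or
to an isolate is degenerate). Provenance counts per source are kept so a
graph's composition is reconstructible. Homology is represented as direct
gene-gene edges between different species; a cluster file (one ortholog
cluster per line) is expanded to the clique of its cross-species pairs,
and within-species pairs in a cluster are skipped because they carry no
cross-species signal. When a homology edge list has a numeric support
column, a minimum count (supporting orthology algorithms, typically ≥ 9)
can be applied at load time; without the column all edges are accepted.

## Ontology handling

Only the biological-process hierarchy under one root is used, with the
three relations that propagate annotations (`is_a`, `part_of`,
`regulates`); other OBO relationship types are ignored with a logged
count. Annotations are filtered to the experimentally verified or
curator-assigned evidence codes {EXP, IDA, IEP, IGI, IMP, IPI, TAS, IC};
electronically inferred (IEA) annotations are excluded. The *closure* of a
term is the union of genes annotated to it or any descendant, computed in
one bottom-up topological pass. When emitting gene-term edges for the
graph, a term whose closure holds ≤ 200 genes contributes an edge for
every closure gene; a larger term is considered too general and keeps only
its direct annotation edges — dropping those too would disconnect genes
whose only annotations are general, so direct edges are retained. The cap
counts genes pooled across species. Information content is
`IC(t) = −ln(|closure(t)| / |closure(root)|)` with natural log: the base
only rescales Resnik and cancels in Lin.

## Random walk with restart

`p(t+1) = (1−r) A p(t) + r e` with column-stochastic `A`
(`A[i,j] = 1/deg(j)` for `i ~ j`), `r = 0.25`, stopping when the L1 change
is below `τ = 1e−8` (at most 10 000 iterations; non-convergence is an
error reporting the residual). Probability mass is conserved exactly, so
scores are a distribution over nodes. With several seeds the restart
vector is **uniform over the seeds** and sums to one — the only
normalization that keeps `p` a probability distribution. The operator is
dense below 2 000 nodes and sparse above, with identical results within τ;
many walks (gene-gene similarity, permutation nulls) run as one batched
matrix iteration. Walk-derived gene similarity is the symmetrized
cross-proximity `Sim(g_i, g_j) = (p_{g_i}(g_j) + p_{g_j}(g_i)) / 2`; genes
absent from the graph get NaN rows and are excluded pairwise downstream.

## Permutation significance and the two-fold filter

The null model permutes node labels uniformly over the fixed topology and
repeats the walk from the same seed labels. This is implemented without
materializing permuted graphs: a walk on the permuted graph equals a walk
on the original topology from the permuted seed positions, reading each
label's score at its permuted position, so all permutations share one
batched iteration. The empirical p-value uses add-one smoothing,
`p = (1 + #{perm ≥ obs}) / (n_perm + 1)`, which avoids p = 0. Scores that
are equal in exact arithmetic (symmetric positions) differ across walks by
convergence jitter of order τ, so "as high or higher" is counted with a
tolerance of 10·τ instead of being left to floating-point noise. The
two-fold filter returns gene nodes with p ≤ 0.01 **and** walk score at or
above the 95th linear-interpolation quantile of *all* node scores
(boundary inclusive); seed nodes are never returned. Degree-preserving
edge rewiring would be a stricter null; the label permutation is the
literal "rearranging all nodes" reading and is what is implemented.

## Semantic similarity and discriminative power

Term-level measures: Resnik = IC of the most informative common ancestor;
Lin = 2·IC(MICA)/(IC(t1)+IC(t2)) with the convention 1 for identical
zero-IC terms and 0 otherwise; Jaccard and cosine operate on ancestor sets
(a term is its own ancestor) — Jaccard as intersection over union, cosine
as intersection over the geometric mean of set sizes, i.e. the cosine of
binary ancestor-indicator vectors (an IC-weighted vector space would be a
plausible alternative; the binary one keeps the measure purely
topological). Gene similarity is the best-match average over the genes'
term sets. A gene with no surviving annotation yields a missing value
(NaN), counted and excluded pairwise, never zero-filled.

Discriminative power of pathway S_k in a collection of P pathways is
`DP = (P−1) · IntraSetSim / Σ_{i≠k} InterSetSim`, where IntraSetSim is the
mean of the full b×b similarity block — the b² denominator includes the
diagonal — and InterSetSim the mean of the b×c cross block. The prefactor
uses the total collection size P so that it equals the number of inter-set
terms, matching the DP literature. DP is invariant under uniform positive
scaling of the similarity matrix, which is what makes unbounded walk
scores comparable with [0,1] semantic measures.

## DIAMOnD comparator

Connectivity significance is the hypergeometric tail
`p = Σ_{i=ks}^{min(k,s0)} C(s0,i) C(N−s0, k−i) / C(N,k)`, computed with
exact integer binomials. Growth absorbs the lowest-p gene each round,
counting links into seeds plus previously added genes; ties break by
higher seed-link count, then lower degree, then identifier, making growth
fully deterministic. `N` counts all nodes and candidates are gene nodes
only — i.e. the algorithm is run as-is on the heterogeneous graph, which
is exactly the regime where it stalls: a candidate gene whose only paths
to the seeds run through gene-set or ontology nodes has zero direct seed
links and is never absorbed. Seed weighting extensions are out of scope.

## Benchmarks and statistics

Cross-validation shuffles the disease gene list once per seed and splits
it into k = 5 near-equal test folds; training genes present in the graph
seed the method, and the recapitulation proportion is
`|output ∩ test| / |test|`. For the walk, "output" is the set of genes
passing the two-fold filter. Mann-Whitney U counts pairs with ties at one
half; the p-value uses the normal approximation with tie and continuity
corrections (matching how complete-separation comparisons at n = m = 5
yield p ≈ 0.01 rather than the exact permutation value). Kruskal-Wallis H
is tie-corrected; Dunn's post-hoc z-tests use pooled tie-corrected ranks
with Benjamini-Hochberg adjustment over all pairs. Cliff's delta uses the
consistent row/column-dominance variance estimator, a Student-t quantile
(df = n+m−2) and the asymmetric confidence transform that keeps the
interval inside [−1, 1]; magnitude bands are 0.147 / 0.330 / 0.474
(negligible / small / moderate / large). At |δ| = 1 the variance estimate
degenerates and the interval collapses to the point estimate.

## Synthetic study conditions

`FixtureSpec` defaults define the study conditions and are not tuned per
experiment: three species (human, mouse, rat) with 80 genes each;
six planted modules of 12 genes (module 0 is the disease module);
within-module edge probability 0.6 against background 0.03; 1:1:1
ortholog triples at 90% coverage; two gene-set nodes attached to the
human disease module at 70% membership. The human layer keeps only 50% of
its within-module edges (`human_edge_retention`) — this models the
incompleteness of human interaction data that motivates borrowing
model-organism signal, and it is what gives the multi-species graph its
measurable advantage: with a fully wired human module the single-species
walk would already saturate. Pathways are drawn from the planted modules
(sizes 4, 6, then 8; consecutive pathways share 2 genes) so the
small-pathway regime is represented. Ontologies are balanced is_a trees
(depth 3, branching 3) with sparse part_of cross-links and leaf
annotations under the allowed evidence codes.

What the fixtures do **not** emulate: scale-free degree distributions,
annotation co-occurrence bias in real GO, paralog fan-out in orthology,
and the size of real interactomes. Passing benchmarks here shows the
machinery behaves as designed under the assumed structure; effect sizes
measured on full-scale public databases are a separate question and out
of scope here.

Experiment sizes were chosen so the whole suite runs in well under a
minute: cross-validation uses 200 permutations per fold (the CLI default
for a single analysis remains 1000), benefit and robustness experiments
use 20 generator seeds, and the permutation-null uniformity check uses a
61-node circulant (vertex-transitive) graph with 200 permutations and 100
replicates.

## Known limitations

* The label-permutation null preserves topology but not degree-score
  coupling; hub nodes are significant less often than under a
  degree-preserving rewiring null.
* Empirical p-values are lower-bounded by 1/(n_perm+1); with 1000
  permutations the filter threshold 0.01 is ten times the floor, which is
  adequate, but smaller thresholds would need more permutations.
* Walk similarity depends on degree: high-degree genes have diffuse
  proximity vectors, deflating their pairwise similarities. DP's scaling
  invariance removes global effects only.
* The CLI assumes identifiers are namespaced (`species:gene`); no live
  identifier mapping is performed — a static mapping file must be applied
  upstream.
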