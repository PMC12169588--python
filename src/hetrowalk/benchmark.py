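"""Cross-validated recapitulation experiments, robustness suite, and the
nonparametric statistical comparisons.

The central benchmark is 5-fold cross-validation over a list of known
disease genes: each training fold seeds a method (walk + two-fold filter,
or module growth) and the *recapitulation proportion* is the fraction of
held-out test genes the method returns. Methods are compared with
Mann-Whitney U tests on the per-fold proportions; groups of discriminative
power values are compared with a Kruskal-Wallis test, Dunn's post-hoc
z-tests under Benjamini-Hochberg correction, and Cliff's delta effect
sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from .graph import HeteroGraph, NodeRef, perturb_edges
from .rwr import SeedSet, WalkConfig, rwr_gene_similarity
from .semsim import PathwayCollection, dp_table
from .significance import permutation_pvalues, twofold_filter
from .diamond import grow_disease_module

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- CV core
def kfold_split(
    genes: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Random disjoint near-equal test folds covering every gene."""
    genes = list(genes)
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    folds = np.array_split(order, k)
    out = []
    for f in folds:
        test = [genes[i] for i in f]
        train = [g for g in genes if g not in set(test)]
        out.append((train, test))
    return out


def recapitulation_proportion(output: set[str], test: Sequence[str]) -> float:
    """|output ∩ test| / |test|."""
    test = list(test)
    if not test:
        raise ValueError("empty test set")
    return len(output & set(test)) / len(test)


@dataclass
class CVResult:
    method: str
    disorder: str
    folds: list[tuple[list[str], list[str], float]]

    def proportions(self) -> list[float]:
        return [p for _, _, p in self.folds]


def cv_experiment(
    hg: HeteroGraph,
    disease_genes: Sequence[str],
    method: str,
    cfg: Optional[WalkConfig] = None,
    seed: int = 0,
    k: int = 5,
    n_perm: int = 200,
    alpha: float = 0.01,
    quantile: float = 0.95,
    diamond_n: int = 250,
    disorder: str = "synthetic",
) -> CVResult:
    """k-fold recapitulation of known disease genes.

    ``method`` is ``rwr_twofold`` (walk from the training genes, keep genes
    passing the two-fold filter) or ``diamond`` (module growth from the
    training genes). Folds are split over the full disease gene list; train
    genes absent from the graph are dropped from the seed set.
    """
    if method not in ("rwr_twofold", "diamond"):
        raise ValueError(f"unknown method {method!r}")
    cfg = cfg or WalkConfig()
    folds_out = []
    for fold_i, (train, test) in enumerate(kfold_split(disease_genes, k, seed)):
        seeds = [g for g in train if hg.has_node(g)]
        if not seeds:
            logger.warning("fold %d: no training gene in graph; proportion 0", fold_i)
            folds_out.append((train, test, 0.0))
            continue
        if method == "rwr_twofold":
            seed_refs = [hg.node_ref(g) for g in seeds]
            pr = permutation_pvalues(
                hg, SeedSet(seed_refs), cfg, n_perm=n_perm,
                rng_seed=seed * 1000 + fold_i,
            )
            output = {r.identifier for r in twofold_filter(pr, alpha, quantile)}
        else:
            growth = grow_disease_module(hg, seeds, n=diamond_n)
            output = growth.module_genes()
        folds_out.append((train, test, recapitulation_proportion(output, test)))
    return CVResult(method=method, disorder=disorder, folds=folds_out)


# ------------------------------------------------------- rank statistics
def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U with normal approximation (tie and continuity
    corrected). U counts pairs where x exceeds y, ties count one half."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    diff = x[:, None] - y[None, :]
    U = float((diff > 0).sum() + 0.5 * (diff == 0).sum())
    mu = n * m / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    Nt = n + m
    var = n * m / 12.0 * ((Nt + 1) - tie_term / (Nt * (Nt - 1)))
    if var == 0:
        return U, 1.0
    sd = np.sqrt(var)
    if alternative == "two-sided":
        z = (abs(U - mu) - 0.5) / sd
        p = 2.0 * st.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (U - mu - 0.5) / sd
        p = float(st.norm.sf(z))
    elif alternative == "less":
        z = (U - mu + 0.5) / sd
        p = float(st.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return U, float(min(p, 1.0))


def kw_dunn(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> tuple[float, float, dict[tuple[str, str], float]]:
    """Kruskal-Wallis H (tie corrected) plus Dunn's pairwise z-tests with
    Benjamini-Hochberg adjustment across all pairs."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 1:
            raise ValueError("every group needs at least one observation")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if all(np.array_equal(arrays[0], g) for g in arrays[1:]):
        # identical groups: H = 0 by definition, kruskal rejects this input
        H, p_kw = 0.0, 1.0
    else:
        H, p_kw = st.kruskal(*arrays)
    pooled = np.concatenate(arrays)
    ranks = st.rankdata(pooled)
    N = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = ((counts**3 - counts).sum()) / (12.0 * (N - 1)) if N > 1 else 0.0
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    raw, pairs = [], []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(
                (N * (N + 1) / 12.0 - tie_corr) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            raw.append(2.0 * st.norm.sf(abs(z)))
            pairs.append((labels[i], labels[j]))
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    return float(H), float(p_kw), {pr: float(p) for pr, p in zip(pairs, adjusted)}


_DELTA_BANDS = ((0.147, "negligible"), (0.330, "small"), (0.474, "moderate"))


@dataclass
class EffectSize:
    delta: float
    ci_low: float
    ci_high: float
    label: str


def cliffs_delta(
    x: Sequence[float], y: Sequence[float], conf: float = 0.95
) -> EffectSize:
    """Cliff's delta with a Student-t confidence interval.

    delta = (#(x > y) - #(x < y)) / (n m); the variance uses Cliff's
    consistent estimator from the row/column dominance means and the CI the
    asymmetric transform that keeps the bounds inside [-1, 1]. Magnitude
    bands follow Hess & Kromrey: negligible < 0.147, small < 0.330,
    moderate < 0.474, large otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    dom = np.sign(x[:, None] - y[None, :])
    d = float(dom.mean())
    label = "large"
    for bound, name in _DELTA_BANDS:
        if abs(d) < bound:
            label = name
            break
    if n < 2 or m < 2 or abs(d) == 1.0:
        return EffectSize(d, d, d, label)
    di = dom.mean(axis=1)
    dj = dom.mean(axis=0)
    ss_i = ((di - d) ** 2).sum()
    ss_j = ((dj - d) ** 2).sum()
    ss_ij = ((dom - d) ** 2).sum()
    s2 = max(m**2 * ss_i + n**2 * ss_j - ss_ij, 0.0) / (n * m * (n - 1) * (m - 1))
    t = st.t.ppf(1 - (1 - conf) / 2, df=n + m - 2)
    denom = 1 - d**2 + t**2 * s2
    half = t * np.sqrt(s2) * np.sqrt(max(1 - 2 * d**2 + d**4 + t**2 * s2, 0.0))
    lo = (d - d**3 - half) / denom
    hi = (d - d**3 + half) / denom
    lo, hi = max(min(lo, d), -1.0), min(max(hi, d), 1.0)
    return EffectSize(d, float(lo), float(hi), label)


# -------------------------------------------------------- robustness suite
def robustness_suite(
    hg: HeteroGraph,
    coll: PathwayCollection,
    fractions: Sequence[float] = (0.1, 0.2, 0.3),
    modes: Sequence[str] = ("add", "remove"),
    seed: int = 0,
    cfg: Optional[WalkConfig] = None,
) -> tuple[list[dict], tuple[float, float]]:
    """Discriminative power of walk-derived similarity under edge noise.

    Recomputes the gene-gene walk similarity and per-pathway DP on the
    baseline graph and on each perturbed variant (added or removed edges at
    each fraction), then tests the DP distributions across conditions with
    a Kruskal-Wallis ANOVA. Returns the long-format table of records
    ``{pathway, condition, dp}`` and ``(H, p)``.
    """
    cfg = cfg or WalkConfig()
    gene_refs = []
    for gid in coll.all_genes():
        if hg.has_node(gid):
            gene_refs.append(hg.node_ref(gid))
    conditions: list[tuple[str, HeteroGraph]] = [("baseline", hg)]
    for mode in modes:
        for frac in fractions:
            tag = f"{'+' if mode == 'add' else '-'}{int(round(frac * 100))}%"
            conditions.append((tag, perturb_edges(hg, frac, mode, seed)))
    table: list[dict] = []
    groups: list[list[float]] = []
    labels: list[str] = []
    for tag, graph in conditions:
        M = rwr_gene_similarity(graph, gene_refs, cfg)
        dps = dp_table(coll, M)
        groups.append(list(dps.values()))
        labels.append(tag)
        for pid, dp in dps.items():
            table.append({"pathway": pid, "condition": tag, "dp": dp})
    H, p, _ = kw_dunn(groups, labels)
    return table, (H, p)
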