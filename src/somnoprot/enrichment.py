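"""Hypergeometric term enrichment with kappa-score term clustering.

Significant proteins (the query) are tested against each gene set using
the accumulative (upper-tail) hypergeometric distribution, with the
distinct proteins measured on the panels as the background universe
(355 in the study design). A term passes when p < 0.01, the overlap
count is at least 3 and the enrichment factor (k/n)/(K/N) exceeds 1.5.
Passed terms are then clustered: pairwise similarity is Cohen's kappa on
their membership indicator vectors over the query genes, average-linkage
hierarchical clustering is cut where similarity drops to 0.3, and the
most significant term represents each cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import GeneSet

__all__ = [
    "EnrichmentInput",
    "TermResult",
    "hypergeom_tail",
    "score_terms",
    "kappa_similarity",
    "cluster_terms",
    "run_enrichment",
]

P_MAX = 0.01
MIN_COUNT = 3
MIN_ENRICHMENT_FACTOR = 1.5
KAPPA_THRESHOLD = 0.3


@dataclass(frozen=True)
class EnrichmentInput:
    query: frozenset[str]
    background: frozenset[str]
    genesets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        if not self.background:
            raise ValueError("background universe is empty")
        if not self.query:
            raise ValueError("query set is empty")
        stray = self.query - self.background
        if stray:
            raise ValueError(
                f"query proteins outside the background universe: {sorted(stray)[:5]}"
            )


@dataclass
class TermResult:
    term_id: str
    term_name: str
    k: int  # overlap with the query
    n: int  # query size
    K: int  # term size within the background
    N: int  # background size
    p: float
    enrichment_factor: float
    overlap_genes: tuple[str, ...]
    passed: bool
    cluster_id: int | None = None
    representative: bool = False


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n): the accumulative tail.

    N population size, K marked items, n draws without replacement,
    k observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid counts N={N}, K={K}, n={n}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def score_terms(
    inp: EnrichmentInput,
    *,
    p_max: float = P_MAX,
    min_count: int = MIN_COUNT,
    min_ef: float = MIN_ENRICHMENT_FACTOR,
) -> list[TermResult]:
    """Score every gene set against the query over the background.

    Gene sets are intersected with the background before testing; terms
    with fewer than ``min_count`` background genes cannot pass the count
    filter and are skipped. ``passed`` applies the three filters:
    p < p_max, overlap >= min_count, enrichment factor > min_ef.
    """
    N = len(inp.background)
    n = len(inp.query)
    out: list[TermResult] = []
    for gs in inp.genesets:
        members = gs.genes & inp.background
        K = len(members)
        if K < min_count:
            continue
        overlap = members & inp.query
        k = len(overlap)
        p = hypergeom_tail(N, K, n, k)
        ef = (k / n) / (K / N)
        out.append(
            TermResult(
                term_id=gs.term_id,
                term_name=gs.term_name,
                k=k,
                n=n,
                K=K,
                N=N,
                p=p,
                enrichment_factor=ef,
                overlap_genes=tuple(sorted(overlap)),
                passed=(p < p_max) and (k >= min_count) and (ef > min_ef),
            )
        )
    return out


def kappa_similarity(
    term_a: frozenset[str] | set[str],
    term_b: frozenset[str] | set[str],
    universe: Sequence[str] | frozenset[str],
) -> float:
    """Cohen's kappa between two terms' membership vectors over a universe.

    kappa = (p_o - p_e) / (1 - p_e) on the 2x2 contingency of universe
    genes belonging to A vs B; when both marginals are degenerate and the
    memberships agree everywhere, kappa is 1 by convention.
    """
    genes = list(universe)
    if not genes:
        raise ValueError("kappa universe is empty")
    a = np.fromiter((g in term_a for g in genes), dtype=bool, count=len(genes))
    b = np.fromiter((g in term_b for g in genes), dtype=bool, count=len(genes))
    m = len(genes)
    p_o = float(np.mean(a == b))
    p_e = float(a.mean() * b.mean() + (1 - a.mean()) * (1 - b.mean()))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def cluster_terms(
    terms: Sequence[TermResult],
    genesets: Sequence[GeneSet],
    universe: Sequence[str] | frozenset[str],
    *,
    threshold: float = KAPPA_THRESHOLD,
    linkage: Literal["average", "single", "complete"] = "average",
) -> list[TermResult]:
    """Cluster passed terms by kappa similarity; flag representatives.

    Average-linkage hierarchical clustering on distance 1 - kappa, cut at
    distance 1 - threshold so subtrees with similarity above the
    threshold stay together. Within each cluster the minimum-p term is
    the representative (ties: larger overlap k, then lexicographic
    term_id).
    """
    if not terms:
        raise ValueError("no passed terms to cluster")
    members = {gs.term_id: gs.genes for gs in genesets}
    sets = [frozenset(members[t.term_id]) for t in terms]
    m = len(terms)
    out = [replace(t) for t in terms]
    if m == 1:
        out[0].cluster_id = 1
        out[0].representative = True
        return out

    sim = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = kappa_similarity(sets[i], sets[j], universe)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)  # kappa may exceed... stay in [0, 2]
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    labels = hierarchy.fcluster(Z, t=1.0 - threshold, criterion="distance")

    for t, lab in zip(out, labels):
        t.cluster_id = int(lab)
    for lab in sorted(set(labels)):
        idx = [i for i in range(m) if labels[i] == lab]
        best = min(idx, key=lambda i: (out[i].p, -out[i].k, out[i].term_id))
        out[best].representative = True
    return out


def run_enrichment(
    query: Sequence[str] | frozenset[str],
    background: Sequence[str] | frozenset[str],
    genesets: Sequence[GeneSet],
    *,
    p_max: float = P_MAX,
    min_count: int = MIN_COUNT,
    min_ef: float = MIN_ENRICHMENT_FACTOR,
    kappa_threshold: float = KAPPA_THRESHOLD,
    linkage: Literal["average", "single", "complete"] = "average",
) -> list[TermResult]:
    """Score all terms, cluster the passed ones, return all scored terms.

    Passed terms carry cluster ids and representative flags; results are
    ordered by ascending p with representatives resolvable per cluster.
    """
    inp = EnrichmentInput(
        query=frozenset(query), background=frozenset(background), genesets=tuple(genesets)
    )
    scored = score_terms(inp, p_max=p_max, min_count=min_count, min_ef=min_ef)
    passed = [t for t in scored if t.passed]
    if passed:
        clustered = cluster_terms(
            passed, genesets, sorted(inp.query), threshold=kappa_threshold, linkage=linkage
        )
        by_id = {t.term_id: t for t in clustered}
        scored = [by_id.get(t.term_id, t) for t in scored]
    scored.sort(key=lambda t: (t.p, t.term_id))
    return scored
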