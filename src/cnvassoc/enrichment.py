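"""Gene overlap and gene-set overrepresentation for reported regions.

A gene overlaps a region if they are on the same chromosome and share at
least one base pair. For the gene list G overlapping the selected regions
and a candidate gene set C within a universe of N genes, significance is
the upper-tail hypergeometric probability

    P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n)

with K = |C|, n = |G|, k = |G intersect C| (all restricted to the
universe). P-values over the tested sets are adjusted with
Benjamini-Hochberg and with Storey's q-value method (single-lambda
estimator at lambda = 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy.stats import false_discovery_control, hypergeom

from .types import GeneRecord, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One gene set's hypergeometric test outcome."""

    set_name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_N: int
    p_value: float
    p_adjusted: float | None = None
    q_value: float | None = None
    overlap_genes: frozenset[str] = frozenset()


def genes_overlapping_regions(regions, annotation: list[GeneRecord]) -> set[str]:
    """Gene ids sharing >= 1 bp with any of the given regions.

    ``regions`` is any iterable of objects with chromosome/start/end
    attributes (CNVRegion or RegionResult).
    """
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        # half-open tree interval [start, end+1) covers the inclusive span
        trees.setdefault(gene.chromosome, IntervalTree()).addi(
            gene.start, gene.end + 1, gene.gene_id
        )
    hits: set[str] = set()
    for region in regions:
        tree = trees.get(region.chromosome)
        if tree is None:
            continue
        hits.update(iv.data for iv in tree.overlap(region.start, region.end + 1))
    return hits


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    k successes drawn, K successes in the population of N, n draws.
    Computed via the survival function for numerical stability.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return false_discovery_control(p, method="bh")


def storey_qvalues(p_values, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda pi0 estimator.

    pi0 = min(1, #{p > lambda} / (m (1 - lambda))); q-values are the BH
    step-up cascade scaled by pi0. With fewer than two p-values pi0 cannot
    be estimated, so the function falls back to BH with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m < 2:
        logger.warning("fewer than 2 p-values; falling back to BH adjustment")
        return bh_adjust(p)
    pi0 = min(1.0, (p > lambda_).sum() / (m * (1.0 - lambda_)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def run_enrichment(
    query_genes: set[str],
    gene_sets: GeneSetCollection,
    annotation: list[GeneRecord] | None = None,
    *,
    min_set_size: int = 2,
) -> list[EnrichmentResult]:
    """Test every gene set for overrepresentation in ``query_genes``.

    The universe defaults to all genes in the annotation; an explicit
    universe on the GeneSetCollection overrides it. Query genes outside the
    universe are dropped (logged); sets smaller than ``min_set_size`` after
    universe restriction are skipped (logged). Results are sorted by
    p-value.
    """
    if gene_sets.universe is not None:
        universe = set(gene_sets.universe)
    elif annotation is not None:
        universe = {g.gene_id for g in annotation}
    else:
        raise ValueError("need an annotation or an explicit universe to define N")

    G = query_genes & universe
    dropped = len(query_genes) - len(G)
    if dropped:
        logger.info("dropped %d query genes absent from the universe", dropped)
    N, n = len(universe), len(G)

    results = []
    for name in sorted(gene_sets.sets):
        C = gene_sets.sets[name] & universe
        if len(C) < min_set_size:
            logger.info("skipping set %r: only %d genes in universe", name, len(C))
            continue
        overlap = G & C
        p = hypergeometric_pvalue(len(overlap), len(C), n, N)
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_k=len(overlap),
                set_size_K=len(C),
                query_size_n=n,
                universe_N=N,
                p_value=p,
                overlap_genes=frozenset(overlap),
            )
        )
    if results:
        ps = [r.p_value for r in results]
        adj = bh_adjust(ps)
        qs = storey_qvalues(ps)
        for r, a, q in zip(results, adj, qs):
            r.p_adjusted = float(a)
            r.q_value = float(q)
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
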