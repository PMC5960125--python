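"""Empirical genome-wide q-values by label permutation.

The null hypothesis is that CNV occurrence is independent of the phenotype.
Sample-to-group assignment is permuted repeatedly, preserving the two group
sizes and every call's position, length and type; the model (and merging,
when enabled) is re-run on each permuted labelling, and a reported region's
q-value is the fraction of permutations producing an equally or more
significant region — one spanning at least as many base pairs ("equally or
more" means ties count). For the statistical model only regions of the same
event type compete; query-model results are typeless and compete pooled.
Each permutation contributes only its single longest reported region per
family (a genome-wide, family-wise exceedance), and optionally the longest
per chromosome when q-values are scoped to single chromosomes.

Segmentation depends only on call coordinates, never on group labels, so
the observed segmentation is reused across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .association import (
    ContingencyTable,
    Query,
    RegionResult,
    fisher_exact_two_sided,
)
from .segmentation import CNVRegion
from .types import CohortDataset, VARIANT_STATES


@dataclass(frozen=True)
class PermutationConfig:
    """Settings for the permutation test.

    n_permutations: number of label permutations (resolution of q is 1/n).
    seed: master seed; permutation r draws from a deterministic sub-stream.
    scope: 'genome' pools competitor lengths across all chromosomes;
        'per-chromosome' restricts each result's competitors to its own
        chromosome (q-values generally become much smaller).
    estimator: 'plain' = count/n (can be 0); 'add-one' = (count+1)/(n+1).
    """

    n_permutations: int = 1000
    seed: int = 0
    scope: str = "genome"
    estimator: str = "plain"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.scope not in ("genome", "per-chromosome"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.estimator not in ("plain", "add-one"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def permute_assignment(
    samples: tuple[str, ...], size1: int, rng: np.random.Generator
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Uniformly random partition of ``samples`` into sizes (size1, rest)."""
    if not 0 < size1 < len(samples):
        raise ValueError("size1 must leave both groups non-empty")
    idx = rng.permutation(len(samples))
    g1 = np.sort(idx[:size1])
    g2 = np.sort(idx[size1:])
    return tuple(samples[i] for i in g1), tuple(samples[i] for i in g2)


class _RegionMatrices:
    """Label-independent per-region arrays reused across permutations."""

    def __init__(self, regions: list[CNVRegion], samples: tuple[str, ...]):
        self.n_regions = len(regions)
        self.samples = samples
        sample_pos = {s: j for j, s in enumerate(samples)}
        self.chrom_labels = sorted({r.chromosome for r in regions})
        chrom_pos = {c: i for i, c in enumerate(self.chrom_labels)}
        self.chrom_id = np.array([chrom_pos[r.chromosome] for r in regions], dtype=np.int64)
        self.start = np.array([r.start for r in regions], dtype=np.int64)
        self.end = np.array([r.end for r in regions], dtype=np.int64)
        self.carrier = {}  # state -> (n_regions, n_samples) bool
        for state in VARIANT_STATES:
            m = np.zeros((self.n_regions, len(samples)), dtype=bool)
            for i, r in enumerate(regions):
                for s, states in r.state_sets.items():
                    if state in states:
                        m[i, sample_pos[s]] = True
            self.carrier[state] = m
        self.normal = ~(
            self.carrier["Gain"] | self.carrier["Loss"] | self.carrier["LOH"]
        )

    def max_merged_lengths(
        self, reported: np.ndarray, merge_distance_bp: int | None
    ) -> np.ndarray:
        """Longest (optionally chain-merged) reported span per chromosome.

        ``reported`` is a boolean mask over regions (which are sorted by
        chromosome then start). Returns an array of length n_chromosomes;
        chromosomes with no reported region get 0.
        """
        out = np.zeros(len(self.chrom_labels), dtype=np.int64)
        idx = np.flatnonzero(reported)
        if idx.size == 0:
            return out
        cid, st, en = self.chrom_id[idx], self.start[idx], self.end[idx]
        if merge_distance_bp is None:
            lengths = en - st + 1
            np.maximum.at(out, cid, lengths)
            return out
        run_c, run_s, run_e = cid[0], st[0], en[0]
        for i in range(1, idx.size):
            if cid[i] == run_c and st[i] - run_e - 1 <= merge_distance_bp:
                run_e = max(run_e, en[i])
            else:
                out[run_c] = max(out[run_c], run_e - run_s + 1)
                run_c, run_s, run_e = cid[i], st[i], en[i]
        out[run_c] = max(out[run_c], run_e - run_s + 1)
        return out


_FISHER_TABLE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _fisher_table(n1: int, n2: int) -> np.ndarray:
    """p[a, c] for all carrier counts a <= n1, c <= n2 (cached per sizes)."""
    cached = _FISHER_TABLE_CACHE.get((n1, n2))
    if cached is None:
        p = np.empty((n1 + 1, n2 + 1))
        for a in range(n1 + 1):
            for c in range(n2 + 1):
                p[a, c] = fisher_exact_two_sided(ContingencyTable(a, n1 - a, c, n2 - c))
        p.setflags(write=False)
        _FISHER_TABLE_CACHE[(n1, n2)] = cached = p
    return cached


def _predicate_mask(
    mats: _RegionMatrices, pred, g_idx: np.ndarray
) -> np.ndarray:
    """Vectorized predicate evaluation over all regions for one group."""
    m = len(g_idx)
    if pred.state == "Normal":
        counts = mats.normal[:, g_idx].sum(axis=1)
    else:
        counts = mats.carrier[pred.state][:, g_idx].sum(axis=1)
    if pred.match == "ne":
        counts = m - counts
    if pred.cmp == "ge":
        return counts >= pred.threshold * m - 1e-9
    return counts <= pred.threshold * m + 1e-9


def compute_qvalues(
    dataset: CohortDataset,
    regions: list[CNVRegion],
    observed_results: list[RegionResult],
    *,
    model: str,
    p_threshold: float = 0.05,
    query: Query | None = None,
    merge_distance_bp: int | None = None,
    config: PermutationConfig = PermutationConfig(),
) -> list[RegionResult]:
    """Fill q-values on observed (already merged) results by permutation.

    The model run and merging inside each permutation use exactly the same
    settings that produced ``observed_results``: ``p_threshold`` for the
    statistical model, ``query`` for the query model, and
    ``merge_distance_bp`` (None = merging off).

    Returns new RegionResult objects in the same order, q_value filled.
    """
    if model == "query" and query is None:
        raise ValueError("query model needs a query")
    if not observed_results:
        return []

    mats = _RegionMatrices(regions, dataset.samples)
    n1 = len(dataset.group1_samples)
    n = len(dataset.samples)
    families = list(VARIANT_STATES) if model == "statistical" else [None]
    fam_pos = {f: i for i, f in enumerate(families)}
    n_chrom = len(mats.chrom_labels)

    if model == "statistical":
        ptable = _fisher_table(n1, n - n1)
        rowtot = {s: mats.carrier[s].sum(axis=1) for s in VARIANT_STATES}

    # maxlen[r, fam, chrom]: longest reported (merged) span
    R = config.n_permutations
    maxlen = np.zeros((R, len(families), n_chrom), dtype=np.int64)
    children = np.random.SeedSequence(config.seed).spawn(R)
    for r in range(R):
        rng = np.random.default_rng(children[r])
        g1_idx = np.sort(rng.permutation(n)[:n1])
        if model == "statistical":
            for f, state in enumerate(families):
                a = mats.carrier[state][:, g1_idx].sum(axis=1)
                c = rowtot[state] - a
                reported = ptable[a, c] <= p_threshold
                maxlen[r, f] = mats.max_merged_lengths(reported, merge_distance_bp)
        else:
            g2_idx = np.setdiff1d(np.arange(n), g1_idx, assume_unique=True)
            reported = _predicate_mask(mats, query.p1, g1_idx) & _predicate_mask(
                mats, query.p2, g2_idx
            )
            maxlen[r, 0] = mats.max_merged_lengths(reported, merge_distance_bp)

    genome_max = maxlen.max(axis=2)
    chrom_pos = {c: i for i, c in enumerate(mats.chrom_labels)}
    out = []
    for res in observed_results:
        fam = fam_pos[res.event_type if model == "statistical" else None]
        if config.scope == "genome":
            count = int((genome_max[:, fam] >= res.length).sum())
        else:
            count = int((maxlen[:, fam, chrom_pos[res.chromosome]] >= res.length).sum())
        if config.estimator == "plain":
            q = count / R
        else:
            q = (count + 1) / (R + 1)
        out.append(replace(res, q_value=q))
    return out
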