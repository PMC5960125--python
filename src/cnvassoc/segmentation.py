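"""Breakpoint segmentation of chromosomes into CNV regions (CNVRs).

A CNVR is a maximal genomic interval within a single chromosome in which no
sample changes state. Each chromosome is cut at every call start and at every
position just past a call end, so region boundaries coincide exactly with
call boundaries and no call starts or ends strictly inside a region.

Candidate intervals covered by zero calls (all-Normal gaps) are dropped:
they can never reach a significant Fisher p-value and a query matching them
is degenerate. Adjacent regions with identical state distributions are kept
separate here; collapsing nearby reported regions is the merging stage's job.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from collections import defaultdict

from .types import CNVCall, CohortDataset, VARIANT_STATES


@dataclass(frozen=True)
class CNVRegion:
    """A segmentation interval with every sample's state set.

    ``state_sets`` maps sample_id -> frozenset of states held across the
    whole interval; samples absent from the mapping (or mapped to the empty
    set) are Normal here. A sample overlapped by calls of several types in
    the same interval holds all of them.
    """

    chromosome: str
    start: int
    end: int
    state_sets: dict[str, frozenset[str]]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def states_of(self, sample_id: str) -> frozenset[str]:
        return self.state_sets.get(sample_id, frozenset())


# frozen dataclass with a dict field: hash on coordinates only
CNVRegion.__hash__ = lambda self: hash((self.chromosome, self.start, self.end))  # type: ignore[method-assign]


def segment_regions(dataset: CohortDataset) -> list[CNVRegion]:
    """Segment each chromosome at every call breakpoint.

    Returns regions ordered by (chromosome, start). Breakpoints on a
    chromosome are the sorted distinct values of {call.start} and
    {call.end + 1}; candidate regions span consecutive breakpoints and are
    emitted only if at least one call overlaps them.
    """
    by_chrom: dict[str, list[CNVCall]] = defaultdict(list)
    for call in dataset.calls:
        by_chrom[call.chromosome].append(call)

    regions: list[CNVRegion] = []
    for chrom in sorted(by_chrom):
        calls = by_chrom[chrom]
        breaks = sorted({c.start for c in calls} | {c.end + 1 for c in calls})
        # per-interval accumulation of (sample, state); call boundaries are
        # breakpoints, so each call covers a whole run of intervals
        n_iv = len(breaks) - 1
        acc: list[dict[str, set[str]]] = [defaultdict(set) for _ in range(n_iv)]
        for c in calls:
            i0 = bisect.bisect_left(breaks, c.start)
            i1 = bisect.bisect_left(breaks, c.end + 1)
            for i in range(i0, i1):
                acc[i][c.sample_id].add(c.state)
        chrom_regions: list[CNVRegion] = []
        for i in range(n_iv):
            if not acc[i]:
                continue  # uncovered gap
            state_sets = {s: frozenset(v) for s, v in acc[i].items()}
            prev = chrom_regions[-1] if chrom_regions else None
            # regions are maximal: a breakpoint where no sample actually
            # changes state (overlapping same-state calls of one sample)
            # does not start a new region
            if prev is not None and prev.end + 1 == breaks[i] and prev.state_sets == state_sets:
                chrom_regions[-1] = CNVRegion(chrom, prev.start, breaks[i + 1] - 1, state_sets)
            else:
                chrom_regions.append(CNVRegion(chrom, breaks[i], breaks[i + 1] - 1, state_sets))
        regions.extend(chrom_regions)
    return regions


@dataclass(frozen=True)
class GroupFrequencies:
    """Per-group fraction of samples in each state for one region.

    For a variant state T the fraction counts samples whose state set
    contains T (a sample with {Gain, LOH} counts toward both); the Normal
    fraction counts samples with an empty state set, so
    freq(Normal) = 1 - freq(any variant).
    """

    group1: dict[str, float]
    group2: dict[str, float]


def _group_freqs(region: CNVRegion, samples: tuple[str, ...]) -> dict[str, float]:
    n = len(samples)
    out = {}
    for state in VARIANT_STATES:
        out[state] = sum(state in region.states_of(s) for s in samples) / n
    out["Normal"] = sum(not region.states_of(s) for s in samples) / n
    return out


def region_frequencies(region: CNVRegion, dataset: CohortDataset) -> GroupFrequencies:
    """Fractions of each group's samples in each state within ``region``."""
    return GroupFrequencies(
        group1=_group_freqs(region, dataset.group1_samples),
        group2=_group_freqs(region, dataset.group2_samples),
    )
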