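"""Shared fixtures and independent oracles.

The per-base segmentation oracle deliberately ignores the breakpoint
algorithm under test: it records every sample's state set at every single
base and cuts wherever any set changes. It is only usable on small
coordinate ranges, which is exactly the point.
"""

from __future__ import annotations

import random
from collections import defaultdict

import pytest

from cnvassoc import CNVCall, CohortDataset
from cnvassoc.types import VARIANT_STATES


def make_dataset(calls, group1, group2):
    """Build a CohortDataset from (sample, chrom, start, end, state) tuples."""
    return CohortDataset([CNVCall(*c) for c in calls], tuple(group1), tuple(group2))


def perbase_segment(calls):
    """Per-base oracle: list of (chrom, start, end, {sample: frozenset}).

    Scans every base between the first and last covered position on each
    chromosome, records each sample's state set, and cuts wherever any
    sample's set changes; stretches where every set is empty are dropped.
    """
    by_chrom = defaultdict(list)
    for c in calls:
        by_chrom[c.chromosome].append(c)
    regions = []
    for chrom in sorted(by_chrom):
        cs = by_chrom[chrom]
        lo = min(c.start for c in cs)
        hi = max(c.end for c in cs)
        prev_sets = None
        run_start = None
        for pos in range(lo, hi + 2):  # hi+1 acts as a sentinel flush
            sets = {}
            if pos <= hi:
                for c in cs:
                    if c.start <= pos <= c.end:
                        sets.setdefault(c.sample_id, set()).add(c.state)
            sets = {s: frozenset(v) for s, v in sets.items()}
            if sets != prev_sets:
                if prev_sets:  # non-empty mapping = covered stretch ends
                    regions.append((chrom, run_start, pos - 1, prev_sets))
                prev_sets = sets
                run_start = pos
        # loop's sentinel pass flushed the final run
    return regions


def random_cohort(rng: random.Random, max_samples=5, max_chroms=3, max_pos=2000,
                  max_calls=12):
    """A small random cohort for oracle-equivalence checks."""
    n_samples = rng.randint(2, max_samples)
    samples = [f"S{i}" for i in range(n_samples)]
    n1 = rng.randint(1, n_samples - 1)
    chroms = [f"chr{i + 1}" for i in range(rng.randint(1, max_chroms))]
    calls = []
    for _ in range(rng.randint(1, max_calls)):
        start = rng.randint(1, max_pos - 1)
        end = rng.randint(start, min(max_pos, start + rng.randint(0, 400)))
        calls.append(CNVCall(
            rng.choice(samples), rng.choice(chroms), start, end,
            rng.choice(VARIANT_STATES),
        ))
    return CohortDataset(calls, tuple(samples[:n1]), tuple(samples[n1:]))


@pytest.fixture
def two_sample_dataset():
    """The canonical overlap example: S1 gains [100,200], S2 loses [150,250]."""
    return make_dataset(
        [("S1", "chr1", 100, 200, "Gain"), ("S2", "chr1", 150, 250, "Loss")],
        ["S1"], ["S2"],
    )
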