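"""Significance models over segmented CNV regions.

Two models are provided. The statistical model builds, per region and per
variant state (Gain, Loss, LOH separately), a 2x2 table of carriers vs
non-carriers in the two groups and tests it with a two-sided Fisher exact
test; regions at or below a p-value threshold are reported. The query model
reports regions matching a user-defined pair of predicates, one per group,
with no hypothesis test attached.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import hypergeom

from .segmentation import CNVRegion, region_frequencies
from .types import CohortDataset, PREDICATE_STATES, VARIANT_STATES

#: Relative tolerance for the "no more probable than observed" comparison in
#: the two-sided sum; guards against float tie misclassification on
#: symmetric margins.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """Carrier counts: a/b = group1 with/without the event, c/d = group2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by the minimum-likelihood rule.

    With both margins fixed, sums the hypergeometric point probabilities of
    every table whose probability is no greater than the observed table's
    (within relative tolerance 1e-7).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n1 = a + b          # group 1 size
    col = a + c         # event-column total
    n = n1 + c + d      # grand total
    support = np.arange(max(0, col - (c + d)), min(col, n1) + 1)
    probs = hypergeom.pmf(support, n, col, n1)
    p_obs = hypergeom.pmf(a, n, col, n1)
    p = probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum()
    return float(min(1.0, p))


@dataclass(frozen=True)
class Predicate:
    """One group's matching condition: fraction-of-samples I R under (E, T).

    The fraction f of the group's samples whose state set matches state T
    (``match='eq'``: contains T, or is empty when T is Normal; ``match='ne'``:
    the negation) is compared to the threshold: f >= R for ``cmp='ge'``,
    f <= R for ``cmp='le'``.
    """

    cmp: str        # 'ge' | 'le'
    threshold: float
    match: str      # 'eq' | 'ne'
    state: str      # Normal | Gain | Loss | LOH

    def __post_init__(self) -> None:
        if self.cmp not in ("ge", "le"):
            raise ValueError(f"cmp must be 'ge' or 'le', got {self.cmp!r}")
        if self.match not in ("eq", "ne"):
            raise ValueError(f"match must be 'eq' or 'ne', got {self.match!r}")
        if self.state not in PREDICATE_STATES:
            raise ValueError(f"state must be one of {PREDICATE_STATES}, got {self.state!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


@dataclass(frozen=True)
class Query:
    """A pair of predicates; P1 applies to group 1, P2 to group 2."""

    p1: Predicate
    p2: Predicate


@dataclass
class RegionResult:
    """One reported region with model-dependent annotations.

    Statistical results carry an event type and a p-value; query results
    carry neither. Frequencies are closed intervals [lo, hi] per group and
    state, degenerate (lo == hi) until regions are merged. The q-value is
    filled by the permutation stage.
    """

    chromosome: str
    start: int
    end: int
    model: str                                   # 'statistical' | 'query'
    event_type: str | None = None
    p_value: float | None = None
    q_value: float | None = None
    group1_freq: dict[str, tuple[float, float]] = field(default_factory=dict)
    group2_freq: dict[str, tuple[float, float]] = field(default_factory=dict)
    merged: bool = False

    def __post_init__(self) -> None:
        if self.model == "statistical":
            if self.event_type is None or self.p_value is None:
                raise ValueError("statistical results need event_type and p_value")
        elif self.model == "query":
            if self.event_type is not None or self.p_value is not None:
                raise ValueError("query results carry no event_type or p_value")
        else:
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _freq_intervals(freqs: dict[str, float]) -> dict[str, tuple[float, float]]:
    return {state: (f, f) for state, f in freqs.items()}


def run_statistical_model(
    regions: list[CNVRegion],
    dataset: CohortDataset,
    p_threshold: float = 0.05,
) -> list[RegionResult]:
    """Fisher-test every (region, event type) pair; keep p <= threshold.

    Each of Gain, Loss and LOH is tested separately, so one region may
    produce up to three result rows.
    """
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    n1, n2 = len(dataset.group1_samples), len(dataset.group2_samples)
    results = []
    for region in regions:
        freqs = region_frequencies(region, dataset)
        for state in VARIANT_STATES:
            a = sum(state in region.states_of(s) for s in dataset.group1_samples)
            c = sum(state in region.states_of(s) for s in dataset.group2_samples)
            p = fisher_exact_two_sided(ContingencyTable(a, n1 - a, c, n2 - c))
            if p <= p_threshold:
                results.append(
                    RegionResult(
                        chromosome=region.chromosome,
                        start=region.start,
                        end=region.end,
                        model="statistical",
                        event_type=state,
                        p_value=p,
                        group1_freq=_freq_intervals(freqs.group1),
                        group2_freq=_freq_intervals(freqs.group2),
                    )
                )
    return results


def evaluate_predicate(
    predicate: Predicate, group_state_sets: list[frozenset[str]]
) -> bool:
    """Evaluate a predicate against one group's per-sample state sets."""
    if not group_state_sets:
        raise ValueError("group must be non-empty")
    if predicate.state == "Normal":
        matches = [not s for s in group_state_sets]
    else:
        matches = [predicate.state in s for s in group_state_sets]
    if predicate.match == "ne":
        matches = [not m for m in matches]
    # compare in count space to dodge float artefacts at the boundary
    count, m = sum(matches), len(group_state_sets)
    if predicate.cmp == "ge":
        return count >= predicate.threshold * m - 1e-9
    return count <= predicate.threshold * m + 1e-9


def run_query_model(
    regions: list[CNVRegion],
    dataset: CohortDataset,
    query: Query,
) -> list[RegionResult]:
    """Report every region where group 1 matches P1 and group 2 matches P2."""
    results = []
    for region in regions:
        sets1 = [region.states_of(s) for s in dataset.group1_samples]
        sets2 = [region.states_of(s) for s in dataset.group2_samples]
        if evaluate_predicate(query.p1, sets1) and evaluate_predicate(query.p2, sets2):
            freqs = region_frequencies(region, dataset)
            results.append(
                RegionResult(
                    chromosome=region.chromosome,
                    start=region.start,
                    end=region.end,
                    model="query",
                    group1_freq=_freq_intervals(freqs.group1),
                    group2_freq=_freq_intervals(freqs.group2),
                )
            )
    return results


_CLAUSE_RE = re.compile(
    r"^\s*(group1|group2)\s+(ge|le)\s+(\S+)\s+(eq|ne)\s+(normal|gain|loss|loh)\s*$",
    re.IGNORECASE,
)

_STATE_CANON = {s.lower(): s for s in PREDICATE_STATES}


def parse_query(text: str) -> Query:
    """Parse the textual query form.

    Grammar, two clauses separated by ';'::

        <group1|group2> <ge|le> <fraction> <eq|ne> <normal|gain|loss|loh>

    e.g. ``group1 ge 0.2 eq gain; group2 le 0.1 ne normal``.
    """
    clauses = text.split(";")
    if len(clauses) != 2:
        raise ValueError(f"query needs exactly two ';'-separated clauses, got {len(clauses)}")
    preds: dict[str, Predicate] = {}
    for clause in clauses:
        m = _CLAUSE_RE.match(clause)
        if m is None:
            raise ValueError(
                f"cannot parse clause {clause.strip()!r}; expected "
                "'<group1|group2> <ge|le> <fraction> <eq|ne> <normal|gain|loss|loh>'"
            )
        group, cmp_, frac_text, match, state = (g.lower() for g in m.groups())
        try:
            frac = float(frac_text)
        except ValueError:
            raise ValueError(f"not a number: {frac_text!r}") from None
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"fraction {frac} out of range [0, 1]")
        if group in preds:
            raise ValueError(f"two clauses for {group}; need one per group")
        preds[group] = Predicate(cmp_, frac, match, _STATE_CANON[state])
    if set(preds) != {"group1", "group2"}:
        raise ValueError("query needs one clause for group1 and one for group2")
    return Query(preds["group1"], preds["group2"])
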