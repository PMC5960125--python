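"""Core domain types shared across the package.

Coordinates are 1-based and inclusive on both ends throughout; BED input is
converted on read. Chromosome labels are opaque strings ("chr1" and "1" are
distinct). A sample's state in a region is a *set* of variant states
(Gain/Loss/LOH); the empty set means Normal, which is never an input state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The three discrete variant states a CNV call can carry.
VARIANT_STATES = ("Gain", "Loss", "LOH")

#: States a query predicate may name (Normal = absence of any call).
PREDICATE_STATES = ("Normal",) + VARIANT_STATES

_STATE_ALIASES = {s.lower(): s for s in VARIANT_STATES}


def normalize_state(text: str) -> str:
    """Map a case-insensitive state label to canonical capitalization.

    Raises ValueError for anything outside {gain, loss, loh}.
    """
    try:
        return _STATE_ALIASES[text.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown CNV state {text!r}; expected one of gain, loss, loh") from None


@dataclass(frozen=True)
class CNVCall:
    """One sample's CNV segment with a discrete state."""

    sample_id: str
    chromosome: str
    start: int  # bp, 1-based inclusive
    end: int    # bp, 1-based inclusive
    state: str  # Gain | Loss | LOH

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.state not in VARIANT_STATES:
            raise ValueError(f"state must be one of {VARIANT_STATES}, got {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CohortDataset:
    """Two labelled groups of samples and their pooled CNV calls.

    Every call's sample must belong to exactly one group; the groups are
    disjoint and non-empty. Samples without calls are legal (they are Normal
    everywhere) and still contribute to group denominators.
    """

    calls: list[CNVCall]
    group1_samples: tuple[str, ...]
    group2_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        self.group1_samples = tuple(self.group1_samples)
        self.group2_samples = tuple(self.group2_samples)
        g1, g2 = set(self.group1_samples), set(self.group2_samples)
        if not g1 or not g2:
            raise ValueError("both groups must be non-empty")
        if len(g1) != len(self.group1_samples) or len(g2) != len(self.group2_samples):
            raise ValueError("duplicate sample id within a group")
        overlap = g1 & g2
        if overlap:
            raise ValueError(f"samples in both groups: {sorted(overlap)}")
        known = g1 | g2
        stray = {c.sample_id for c in self.calls} - known
        if stray:
            raise ValueError(f"calls for samples not in either group: {sorted(stray)}")

    @property
    def samples(self) -> tuple[str, ...]:
        return self.group1_samples + self.group2_samples

    def with_groups(self, group1: tuple[str, ...], group2: tuple[str, ...]) -> "CohortDataset":
        """Same calls under a different sample-to-group assignment."""
        return CohortDataset(self.calls, tuple(group1), tuple(group2))


@dataclass(frozen=True)
class GeneRecord:
    """A gene's genomic span, 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if self.universe is not None:
                missing = members - self.universe
                if missing:
                    raise ValueError(
                        f"gene set {name!r} has members outside the declared universe: "
                        f"{sorted(missing)[:5]}"
                    )
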