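"""Synthetic two-group CNV cohorts with known ground truth.

The generator emulates the shape of a small case-control tumour cohort
(default 14 vs 27 samples, mirroring an HPV-positive / HPV-negative penile
cancer study): a handful of chromosomes, sparse background CNVs per sample,
and optional planted regions carried with group-specific penetrance. Planted
calls share exact breakpoints across carriers by default (the cleanest
possible region signal); an optional jitter perturbs breakpoints per carrier
for stress-testing segmentation.

Background CNVs are placed uniformly at random with uniform lengths and a
uniform state among Gain/Loss/LOH; counts per sample per chromosome are
Poisson. No correlation structure between states and no realistic length
distribution is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import CNVCall, CohortDataset, VARIANT_STATES


def _default_chromosomes() -> dict[str, int]:
    return {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}


@dataclass(frozen=True)
class PlantedRegion:
    """A ground-truth CNV carried with group-specific penetrance."""

    chromosome: str
    start: int
    end: int
    state: str
    penetrance_group1: float
    penetrance_group2: float

    def __post_init__(self) -> None:
        if self.state not in VARIANT_STATES:
            raise ValueError(f"state must be one of {VARIANT_STATES}")
        for p in (self.penetrance_group1, self.penetrance_group2):
            if not 0.0 <= p <= 1.0:
                raise ValueError("penetrance must be in [0, 1]")
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid planted coordinates")


@dataclass
class SyntheticConfig:
    """Cohort-generation settings.

    background_rate is the Poisson mean number of background CNVs per sample
    per chromosome; background_length the inclusive (min, max) bp length
    range they draw from uniformly. jitter_bp, when positive, shifts each
    planted carrier's breakpoints independently by a uniform offset in
    [-jitter_bp, +jitter_bp] (clipped to the chromosome).
    """

    n_group1: int = 14
    n_group2: int = 27
    chromosome_lengths: dict[str, int] = field(default_factory=_default_chromosomes)
    background_rate: float = 0.5
    background_length: tuple[int, int] = (10_000, 200_000)
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    jitter_bp: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups need at least one sample")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        lo, hi = self.background_length
        if not 1 <= lo <= hi:
            raise ValueError("background_length must satisfy 1 <= min <= max")
        for region in self.planted_regions:
            limit = self.chromosome_lengths.get(region.chromosome)
            if limit is None:
                raise ValueError(f"planted region on unknown chromosome {region.chromosome!r}")
            if region.end > limit:
                raise ValueError("planted region exceeds chromosome length")


@dataclass
class GroundTruth:
    """Realized carrier counts for each planted region."""

    planted: list[PlantedRegion]
    carriers_group1: list[list[str]]
    carriers_group2: list[list[str]]


def generate_cohort(config: SyntheticConfig) -> tuple[CohortDataset, GroundTruth]:
    """Draw one cohort; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    group1 = tuple(f"S{i + 1:03d}" for i in range(config.n_group1))
    group2 = tuple(f"S{i + 1:03d}" for i in range(config.n_group1, config.n_group1 + config.n_group2))
    calls: list[CNVCall] = []

    carriers1: list[list[str]] = []
    carriers2: list[list[str]] = []
    for region in config.planted_regions:
        chrom_len = config.chromosome_lengths[region.chromosome]
        realized = ([], [])
        for gi, (group, pen) in enumerate(
            [(group1, region.penetrance_group1), (group2, region.penetrance_group2)]
        ):
            for sample in group:
                if rng.random() >= pen:
                    continue
                start, end = region.start, region.end
                if config.jitter_bp:
                    start += int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
                    end += int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
                    start = max(1, min(start, chrom_len))
                    end = max(start, min(end, chrom_len))
                calls.append(CNVCall(sample, region.chromosome, start, end, region.state))
                realized[gi].append(sample)
        carriers1.append(realized[0])
        carriers2.append(realized[1])

    lo, hi = config.background_length
    for sample in group1 + group2:
        for chrom, chrom_len in config.chromosome_lengths.items():
            for _ in range(rng.poisson(config.background_rate)):
                length = int(rng.integers(lo, hi + 1))
                length = min(length, chrom_len)
                start = int(rng.integers(1, chrom_len - length + 2))
                state = VARIANT_STATES[rng.integers(0, 3)]
                calls.append(CNVCall(sample, chrom, start, start + length - 1, state))

    dataset = CohortDataset(calls, group1, group2)
    truth = GroundTruth(list(config.planted_regions), carriers1, carriers2)
    return dataset, truth


def null_cohort(config: SyntheticConfig) -> CohortDataset:
    """A cohort whose labels carry no information about the calls."""
    if config.planted_regions:
        raise ValueError("null cohort must not have planted regions")
    dataset, _ = generate_cohort(config)
    return dataset
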