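"""Query-based region matching.

Instead of a hypothesis test, the query model reports regions matching a
pair of predicates, one per group. Here: at least 20% of group 1 carry a
loss, while at most 10% of group 2 show any variation at all.
"""

from cnvassoc import (
    PlantedRegion,
    SyntheticConfig,
    generate_cohort,
    parse_query,
    run_query_model,
    segment_regions,
)

config = SyntheticConfig(
    planted_regions=[PlantedRegion("chr2", 5_000_000, 6_200_000, "Loss", 0.4, 0.0)],
    seed=7,
)
dataset, _ = generate_cohort(config)
regions = segment_regions(dataset)

query = parse_query("group1 ge 0.2 eq loss; group2 le 0.1 ne normal")
print(f"query: {query.p1} AND {query.p2}")

matches = run_query_model(regions, dataset, query)
print(f"{len(matches)} of {len(regions)} regions match both predicates")
for r in matches[:8]:
    loss1 = r.group1_freq["Loss"][0]
    varied2 = 1.0 - r.group2_freq["Normal"][0]
    print(f"  {r.chromosome}:{r.start}-{r.end}  "
          f"group1 loss {loss1:.0%}, group2 varied {varied2:.0%}")

# A region is reported only when BOTH groups satisfy their predicate; no
# p-value is attached — significance comes from permutation q-values
# (see merging_and_qvalues.py).
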