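"""Merging nearby regions and genome-wide permutation q-values.

Runs the statistical model, merges directly adjacent same-type regions
(distance threshold 0), then computes empirical q-values by permuting the
sample-to-group labels 500 times: a region's q is the share of permutations
producing an equally long or longer reported region of the same type
anywhere in the genome.
"""

from cnvassoc import (
    PermutationConfig,
    PlantedRegion,
    SyntheticConfig,
    compute_qvalues,
    generate_cohort,
    merge_adjacent_results,
    run_statistical_model,
    segment_regions,
)

config = SyntheticConfig(
    planted_regions=[PlantedRegion("chr1", 2_000_000, 3_500_000, "Loss", 0.5, 0.0)],
    background_rate=0.8,
    seed=11,
)
dataset, _ = generate_cohort(config)
regions = segment_regions(dataset)
results = run_statistical_model(regions, dataset, p_threshold=0.05)
print(f"{len(results)} (region, type) pairs at p <= 0.05")

merged = merge_adjacent_results(results, distance_threshold_bp=0, model="statistical")
print(f"{len(merged)} after merging directly adjacent same-type regions")

final = compute_qvalues(
    dataset, regions, merged,
    model="statistical", p_threshold=0.05, merge_distance_bp=0,
    config=PermutationConfig(n_permutations=500, seed=1),
)
print("\ntop regions by q-value:")
for r in sorted(final, key=lambda r: (r.q_value, r.p_value))[:5]:
    lo, hi = r.group1_freq[r.event_type]
    freq = f"{lo:.0%}" if lo == hi else f"{lo:.0%}-{hi:.0%}"
    print(f"  {r.chromosome}:{r.start}-{r.end}  {r.event_type:<4}  "
          f"p={r.p_value:.4f}  q={r.q_value:.3f}  group1 {freq}")

# p is per-region evidence; q is genome-wide: how often random labels
# produce an equally large same-type region anywhere. Merged regions report
# frequency ranges (lo-hi) over their constituents and the largest (least
# significant) constituent p-value.
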