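"""Gene-set enrichment for genes overlapping reported regions.

Builds a toy annotation of 30 genes on one chromosome and two gene sets,
selects a pair of regions, collects every gene sharing at least one base
pair with them, and tests each set with the upper-tail hypergeometric test
(with Benjamini-Hochberg and Storey adjustments across sets).
"""

from cnvassoc import (
    GeneRecord,
    GeneSetCollection,
    genes_overlapping_regions,
    run_enrichment,
)


class Region:
    def __init__(self, chromosome, start, end):
        self.chromosome, self.start, self.end = chromosome, start, end


# 30 genes tiled every 10 kb, each 6 kb long
annotation = [
    GeneRecord(f"G{i}", "chr1", 10_000 * i + 1, 10_000 * i + 6_000)
    for i in range(1, 31)
]
gene_sets = GeneSetCollection({
    "PATHWAY_A": frozenset({"G1", "G2", "G3", "G4"}),      # inside the regions
    "PATHWAY_B": frozenset({"G20", "G21", "G22", "G23"}),  # elsewhere
})

regions = [Region("chr1", 5_000, 48_000), Region("chr1", 55_000, 66_000)]
genes = genes_overlapping_regions(regions, annotation)
print(f"genes overlapping the {len(regions)} regions: {sorted(genes)}")

for r in run_enrichment(genes, gene_sets, annotation):
    print(f"  {r.set_name}: k={r.overlap_k} of K={r.set_size_K} "
          f"(n={r.query_size_n}, N={r.universe_N})  "
          f"p={r.p_value:.4g}  BH={r.p_adjusted:.4g}  q={r.q_value:.4g}")

# k genes of the set fall in the region gene list of size n, drawn from a
# universe of N annotated genes; p is P(X >= k) under the hypergeometric
# null of no association between set membership and region overlap.
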