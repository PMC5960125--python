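# Methods

## Model and assumptions

`cnvassoc` works on *segmented, discrete* CNV calls: each call is an
interval on one chromosome with a state in {Gain, Loss, LOH}. Normal is
never an input state; it is the absence of a call. Coordinates are 1-based
and inclusive everywhere internally; BED input (0-based, half-open) is
converted on read, and chromosome labels are opaque strings — "chr1" and
"1" are deliberately not unified, since silent normalisation can corrupt
user data.

### CNV regions

A CNV region (CNVR) is a maximal interval on one chromosome in which no
sample changes state. Construction cuts the chromosome at every call start
and at every position just past a call end, assigns each interval the
per-sample union of covering call states, and drops intervals covered by
no call at all: an all-Normal stretch can never reach a significant
Fisher p-value, and a query matching it (both predicates about Normal) is
degenerate. Because regions are defined as *maximal*, adjacent candidate
intervals with identical per-sample state sets are coalesced; this matters
only for degenerate inputs where one sample carries overlapping or
directly adjacent calls of the same state, where the interior breakpoint
changes nobody's state. A per-base reference scan (record every sample's
state set at every base, cut where any set changes) is the test oracle for
this stage and agrees exactly.

A sample overlapped by calls of several types within one region holds a
state *set*, not a single state. The statistical model treats each event
type separately, which the set representation serves directly; such a
sample counts as a carrier of each of its states, and the per-group Normal
frequency is one minus the varied frequency.

### Statistical model

For each region and each type T separately, a 2×2 table (carriers vs
non-carriers of T, group 1 vs group 2) is tested with the two-sided Fisher
exact test under the minimum-likelihood rule: with margins fixed, the
p-value sums the hypergeometric probabilities of every table no more
probable than the observed one. Point-probability comparisons use a
relative tolerance of 1e-7 so that exact ties on symmetric margins are not
misclassified by floating point. One region can therefore yield up to
three result rows, one per type. The default reporting threshold is
p ≤ 0.05.

### Query model

A predicate (I, R, E, T) asks whether the fraction f of a group's samples
whose state set matches (E = "=") or mismatches (E = "≠") state T
satisfies f ≥ R or f ≤ R. T = Normal with "=" means the state set is
empty. A query pairs one predicate per group; a region is reported when
both hold. Threshold comparisons are done in carrier-count space with a
1e-9 guard (`count ≥ R·m − ε`), so boundary thresholds like R = 0.2 on
m = 5 samples behave exactly. Query results carry no event type and no
p-value.

### Merging

Reported regions in close proximity often describe one biological event.
Two results merge when the gap between them (`next.start − current.end − 1`,
so adjacent regions have gap 0) is within the user threshold and — for the
statistical model — they share an event type; query results merge freely.
Chains merge transitively; the scan is greedy left-to-right but the
outcome is order-independent because mergeability depends only on pairwise
gaps. The merged region spans gap included, takes the *largest* (least
significant) constituent p-value, and turns each group/state frequency
into the [min, max] interval over constituents, rendered as `lo-hi`
percentages. Merged regions no longer satisfy the CNVR no-state-change
invariant and are flagged `merged`. Nothing is re-tested after merging.

### Permutation q-values

The null hypothesis is that CNV occurrence is independent of the group
label. Labels are permuted uniformly with group sizes preserved; calls
keep their positions, lengths and types. The same model settings and the
same merging are applied inside every permutation (segmentation is
label-invariant and is reused). A region's q-value is the fraction of
permutations whose *longest* reported region — of the same event type for
the statistical model, pooled for the typeless query model — is at least
as long as the observed region ("at least" means ties count). Length is
the significance ordering because under the null, long stretches of
coincident CNVs are less likely than short ones when most of the genome is
quiet. Using only each permutation's maximum makes q a genome-wide,
family-wise error measure; counting all permuted regions would estimate a
different, per-region expected-count statistic.

Options: `scope="per-chromosome"` restricts each region's competitors to
its own chromosome (q-values become much smaller; genome-wide is the
default and the recommended measure), and `estimator="add-one"` returns
(count+1)/(n+1) instead of the plain fraction, which cannot be 0. The
default 1000 permutations give q a resolution of 0.001; the count is
configurable and unrelated to any fixed analysis. All permutation streams
derive from a single seed via per-permutation sub-seeds, so results are
bit-reproducible and independent of evaluation order.

Implementation note: the permutation loop runs on precomputed
region × sample carrier matrices with a cached Fisher p lookup table over
all (a, c) carrier-count pairs, so re-running the model 1000 times costs
milliseconds; tests assert this fast path agrees with running the plain
model on a relabelled dataset.

### Enrichment

Genes overlap a region if they share at least one base pair on the same
chromosome (interval-tree lookup). For gene list G and set C in universe
N, p = P(X ≥ k) is the upper-tail hypergeometric probability computed via
the survival function (log-space stable); exact rational enumeration is
the test oracle. The universe defaults to all genes in the supplied
annotation; an explicit GMT universe overrides it, query genes outside the
universe are dropped with a logged count, and sets with fewer than two
genes after restriction are skipped (logged). Across tested sets,
Benjamini–Hochberg adjusted p-values and Storey q-values are reported.
Storey's π₀ uses the single-λ estimator at λ = 0.5 — the method's simplest
published form, fully testable by hand — rather than a smoothed λ grid;
q-values equal BH when π₀ = 1 and are uniformly smaller otherwise.

## Synthetic cohorts

The generator emulates a small two-group tumour cohort: defaults are 14
vs 27 samples (a realistic case/control imbalance for a rare cancer
cohort), three 10 Mb chromosomes, background CNVs at Poisson rate 0.5 per
sample per chromosome with lengths uniform in 10–200 kb and states uniform
over the three variant types, and no planted regions. Planted regions are
carried with group-specific penetrance and exact shared breakpoints — the
cleanest possible region signal; `jitter_bp` optionally perturbs each
carrier's breakpoints for stress-testing segmentation and is off by
default.

What the generator does *not* model: realistic CNV length distributions,
correlation between events, recurrent breakpoint hotspots, LOH/gain
interaction, or whole-chromosome aneuploidy. Passing tests therefore
demonstrate correctness of the machinery and calibration under an idealised
null — not power or error rates on any particular real platform.

## Numerical and design choices

- Fisher two-sided rule: minimum-likelihood with 1e-7 relative tie
  tolerance (reproduces reference p-values 0.0341 and 0.0387 for 3/14 vs
  0/27 and 4/14 vs 1/27 carriers).
- Ties everywhere favour conservatism: "equally long" permuted regions
  count against the observed region; equal point probabilities are
  included in the two-sided Fisher sum.
- Output ordering: q ascending, then p, then (chromosome, start); equal-q
  rows are thus stable and reproducible.
- Degenerate inputs: empty datasets segment to nothing; a group with no
  calls in a region is 100% Normal; an empty result list writes a
  header-only TSV; merging an empty list returns an empty list.
- Problem sizes in the validation suite: oracle-equivalence checks run on
  500 random mini-cohorts (≤ 5 samples, positions ≤ 2000); null
  calibration uses 200 synthetic null cohorts × 200 permutations;
  planted-region recovery uses 100 seeds × 200 permutations. These sizes
  give binomial standard errors comfortably inside the asserted margins
  while keeping the whole suite fast.

## Known limitations

- Only discrete states are supported; numerical copy-number values (and
  regression-based tests on them) are out of scope.
- No covariate adjustment and no alternative association models
  (chi-squared, logistic regression).
- The q-value resolution is 1/n_permutations; with the plain estimator a
  q of 0 means "never seen in n permutations", not impossibility — use
  the add-one estimator for strictly positive estimates.
- Enrichment treats gene sets as flat sets: no ontology topology,
  ancestor propagation, or set-size bias correction.
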