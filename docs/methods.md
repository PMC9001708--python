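# Methods

This note records the model behind each pipeline stage, the estimators
used, the synthetic-data generator's scope, and the numerical
conventions. It makes no empirical claims beyond what the test suite
and `scripts/acceptance.py` compute.

## Coordinate conventions

All intervals are 0-based, half-open `[start, end)` (BED convention).
Two intervals overlap iff they share at least one base; an interval
ending at position `p` does not overlap one starting at `p`. Interval
equality ignores the optional name and score fields. Signal tracks are
bedGraph-style non-overlapping runs; bases not covered by any run have
value 0 in every consumer.

## Interval core

The set operations are implemented directly (sorted sweeps and
searchsorted indexes) rather than through an external bedtools binding,
because they are the tested primitive of the package. Their contracts:

- `intersect(a, b, mode="report-a", min_overlap_bp=m)`: each record of
  `a` whose maximal overlap with a **single** record of `b` is ≥ m
  bases, returned unmodified. `mode="segments"` returns the overlap
  segment of every overlapping (a, b) record pair.
- `subtract(a, b)`: whole-record exclusion — one shared base removes
  the entire `a` record, no trimming (the `-v` convention).
- `merge_intervals`: maximal union runs; touching-but-not-overlapping
  runs (`end == start`) merge because the result is a coverage union.
- `coverage_support(sets)`: per-base count of how many input *sets*
  cover the base (a set covering a base via two of its own records
  counts once), emitted as maximal constant runs.

All four are tested for exact equality against an independent per-base
boolean-mask oracle on ≥ 200 randomized toy genomes.

`shuffle_intervals` re-places each interval independently: a chromosome
is drawn with probability proportional to its number of placeable start
positions (`length − L + 1` for an interval of length L), then the
start is uniform among those positions. This makes every legal
placement of the interval equally likely genome-wide.

Track summaries: the per-interval `mean` is the width-weighted mean
with uncovered bases counted as 0; the `median` is the exact per-base
median computed from cumulative run weights (no sampling). The window
signal matrix splits a `2·half_window` window centered on each
reference midpoint into equal bins of the width-weighted mean;
out-of-genome bases count as 0.

## Enhancer catalog

1. **Reproducible peaks**: replicate-1 records overlapping any
   replicate-2 record by ≥ 1 bp (records reported unmodified).
2. **TSS exclusion**: whole-record subtraction of peaks overlapping any
   TSS point (optionally extended by ± halfwidth).
3. **Blacklist**: maximal runs where ≥ `min_support` (default 5) of the
   unrelated tissue peak sets cover the base; catalog records
   overlapping such a run are flagged (and optionally removed — the
   default is annotate-only).
4. **Specificity**: a catalog peak overlapping no developmental-stage
   peak set is tissue-specific (PsE); otherwise developmentally shared
   (DevE). The split is exhaustive and exclusive.
5. **Temporal clustering**: DevE elements are clustered on their
   windowed stage-track signal matrix. Rows are `log1p`-scaled and
   max-normalized, then k-means (k = 4, k-means++ init, fixed seed,
   `n_init` = 10). Cluster names C1..Ck are assigned by descending mean
   normalized signal over the earliest stage, so labels are stable
   across reruns.
6. **Genomic location**: each peak midpoint gets exactly one category
   with priority promoter-proximal (within −1000/+100 bp of a TSS,
   strand-aware) > exonic > intronic (inside a gene span without exon
   overlap) > intergenic.

## Enhancer–gene linking

Contacts are pairs of fixed-width chunks (default 5 kb) with a read
count. Filtering keeps cis contacts with count ≥ 2 and bin-start
distance ≤ 100 kb (both inclusive). An active promoter is a gene whose
TSS lies inside a replicate-reproducible promoter-mark peak. A link
(e, g) exists iff some filtered contact has one chunk overlapping
enhancer e by ≥ 1 bp and the other chunk containing g's TSS; counts sum
over supporting contacts; contacts whose two chunks coincide are
skipped.

## Expression statistics

The HC/AllG ratio is `mean(set × group samples) / mean(all genes ×
group samples)` — arithmetic means over the full rectangle, not
per-gene medians. The accompanying test is a one-sided Mann–Whitney
rank-sum on per-gene means, set versus the full universe (the universe
includes the set, mirroring the ratio's definition; testing against the
complement is available). The normal approximation with tie correction
is used; because the "all" group is a superset of the set, the test is
slightly conservative under the null, which the calibration test
tolerates (rejection rate ≤ α + 3·SE).

## Cross-species enrichment

Mapping uses single-block liftover: an element maps iff ≥ 95% of its
length lies within one alignment block, and the image is the affine
(strand-aware) image of the covered part. The enrichment statistic is
the number of mapped elements overlapping any target mark. The null
re-places every mapped target interval uniformly (length-preserving, as
in `shuffle_intervals`) N times (default 1000) and recounts. Fold
change = observed / mean(null). The empirical p uses the add-one
(permutation-inclusive) estimator `(1 + #{null ≥ observed}) / (1 + N)`,
whose floor is `1/(N+1)`; this is the standard bias-avoiding form for
permutation p-values. Conservation is summarized per element
(width-weighted mean, per-base median of the conservation track over
the target interval) and aggregated per sharing group as the mean of
means and the median of medians.

## Disease and motif enrichment

Gene–disease associations are filtered to score strictly > 0.1,
translated to the target species through a many-to-many homology map
(union of homologs, each gene counted once), and diseases with < 15
translated genes are dropped. Enrichment of a disease set in the
linked-gene set is the exact hypergeometric upper tail
`P(X ≥ x) = hypergeom.sf(x−1, universe, M, K)` with ratio
`(x/K)/(M/universe)`. Multiple testing uses Benjamini–Hochberg
q-values; a disease is significant iff q ≤ 0.05 **and** ratio ≥ 1.5.
(BH is used rather than Storey's q-value: with a handful of tests the
π₀ estimate of the Storey procedure is unstable, and BH is the
conservative, parameter-free choice.)

Motif analysis takes the top-k (default 140) motifs of each ranked
list and reports the full exclusive-overlap (Venn) structure plus, per
pair, the observed overlap, a hypergeometric upper-tail p (both top-k
sets modeled as random draws from the universe), and
`E = observed / (k²/universe)`.

## Report invariants

Every percentage in the summary report equals
`100·numerator/denominator` rounded **half-up** to one decimal
(`Decimal` arithmetic, so 7115/14753 renders 48.2 and exact .x5 cases
round up, unlike banker's rounding). The report stores numerator and
denominator next to each percentage and re-verifies the identity on
every run. The pipeline config (every threshold and the seed) is
hashed into each artifact.

## Synthetic-data generator

The generator plants known structure at a desk-scale default size
(3 × 5 Mb genome, 600 enhancers, 800 genes — the package's own choice,
small enough for laptop runtimes but large enough for stable
statistics):

- One regulatory feature per 5-kb chunk (enhancer or promoter), so
  chunk-level linking admits a unique correct answer and planted links
  are recoverable with precision = recall = 1.0.
- Peak lengths are lognormal (median 600 bp); replicate 2 reproduces
  every true peak (noise-free default) plus per-replicate noise peaks
  that the reproducibility filter must remove.
- Four temporal archetypes (flat-high, early, late, flat-low) drive
  both stage peak membership and stage signal tracks over a nonzero
  background level; the background makes flat-high and flat-low
  separable after max-normalization.
- Decoy contacts each violate exactly one linking rule (low count, too
  far, non-regulatory chunk, inactive-gene TSS).
- Linked genes get a 2-fold expression boost in the focal group, so the
  expected HC/AllG ratio has the closed form
  `fold·n / (n_linked·fold + n − n_linked)` (≈ 1.4545 at defaults).
- Cross-species: a Bernoulli subset of enhancers falls inside lift
  blocks; mark-sharing is planted deterministically at
  `round(ρ · Σ qᵢ)` shared elements, where qᵢ is the exact analytic
  null probability that element i overlaps a mark after uniform
  re-placement (computed by mark dilation), so the planted fold ρ = 3
  is recovered by the shuffle test.
- The disease table contains one planted disease drawing half its
  genes from the linked set, uniform decoy diseases, and two
  filter-exercising decoys (low scores; too few genes). Motif lists
  are built by exact set construction to hit configured pairwise and
  triple overlaps (98/63/61, triple 40 at k = 140).

Child RNG streams are spawned per generator stage via
`SeedSequence(entropy=seed, spawn_key=(stage,))`; a single integer seed
fixes every byte of the output, and `write_dataset` is
byte-deterministic.

### Generator scope and limitations

The generator is a test instrument, not a biological simulator: peaks
are placed on a chunk grid rather than with realistic clustering;
expression is gamma noise around group means with no count/dispersion
model; contacts have no distance-decay; conservation is a two-level
step function with Gaussian noise; the homology map is 1:1. Statistical
conclusions about the pipeline's behavior on real data are out of
scope; what the synthetic results establish is that each stage
implements its stated contract and recovers planted structure under
that contract.

## Numerical choices

- Percentages: decimal half-up rounding (see above).
- Empirical p-values: add-one estimator, never 0.
- Rank-sum: asymptotic normal with tie correction; p clamped to (0, 1].
- k-means: fixed `random_state`, 10 restarts; determinism is asserted.
- bedGraph serialization uses 12 significant digits; reports computed
  from written files match in-memory reports to counts/keys exactly
  and to ~1e-9 relative tolerance for floating statistics.
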