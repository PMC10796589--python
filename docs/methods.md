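# Methods

## Network model

Interaction calls are condition- and replicate-resolved records linking an
anchor (a captured promoter or variant probe) to a distal restriction
fragment. Per cell line and condition we build one simple undirected graph:
an edge exists iff at least one replicate carries a call with
`supporting_pairs >= min_supporting_pairs` (default 4) and Bonferroni-
adjusted `p < adj_p_network` (default 0.001; the looser 0.01 default
`adj_p_general` applies outside network construction).

**PIR node identity.** Distal fragments that overlap by at least one base
are merged into a single PIR node (the union interval). Merging runs over
the union of passing calls from *both* compared conditions, so a fragment
boundary jittered by a few base pairs is the same node in both networks;
without this, Jaccard similarity is systematically deflated by coordinate
noise rather than biology. Touching-but-not-overlapping fragments stay
separate (half-open interval arithmetic, 0-based internally; 1-based
inclusive spans are converted at the I/O boundary).

**Anchors.** Promoter anchors become `gene:<symbol>` nodes, variant probes
`probe:<id>`, background controls `ctrl:<id>`. The TSV dialect carries only
the distal interval, so a call whose distal end happens to be another
promoter's fragment is represented as promoter–PIR; all calls are retained
as edges either way.

## Rewiring statistics and the DI rule

For node *x* with neighbor sets *A*, *B* in the two networks:
`JI = |A∩B|/|A∪B|`, `OCE = |A∩B|/min(|A|,|B|)`. OCE is undefined
(reported NaN) when the node is absent from one network — the formula
would divide by zero, and such genes are already excluded by the JI > 0
requirement. A gene is DI iff `OCE < 1`, `0 < JI <= ji_max` (default 0.5)
and `mean_tpm > tpm_min` (default 0.2 TPM), where `mean_tpm` averages the
gene's TPM over the samples of the two compared conditions (the expression
filter's averaging window is a package choice; only the cutoff is given by
the analysis being implemented). Genes failing a criterion are reported
with a reason code rather than dropped.

**Replicate handling.** The default compares one union-over-replicates
network per condition, matching the edge definition ("significant in at
least one replicate"). A per-replicate mode (`per_replicate: true`) builds
one network per replicate and averages JI/OCE over all replicate pairings;
it is provided because building per-replicate networks is an equally
defensible reading of the same edge rule, and union is the default because
the statistics are then a deterministic function of the published edge
definition.

Promoter–promoter edges count toward a promoter's neighbor set by default;
`pir_neighbors_only: true` restricts neighborhoods to PIR nodes.

## Cohort statistics

k-means (k = 2, 10 seeded restarts, features standardized to zero mean and
unit variance) splits patients on the three blood-count phenotypes. The
cluster with the lower mean standardized count is labeled HT: these are
nadir counts, and lower counts mean more severe myelosuppression. The
labeling rule and the k-means settings are package choices — only the use
of unsupervised k-means on the three phenotypes is prescribed.

Per cohort, `AC = sum of alt-allele dosages` over non-missing genotypes and
`AF = AC / (2 x non-missing patients)` (diploid denominator; missing
genotypes are excluded from numerator and denominator alike — the source
analysis does not state the denominator). `ACdiff` and `AFdiff` are
normalized absolute differences, defined as 0 when both cohorts have zero
counts (a variant absent everywhere is maximally uninteresting; this keeps
both statistics total and in [0, 1]). Candidates require
`AFdiff > ace_thr`, `ACdiff > ace_thr` (default 0.25) and
`|AC.LT − AC.HT| > 1` as printed; the textual "present in at least two
individuals" variant of the last criterion is available as
`require_two_carriers` (off by default — the two disagree for a variant
carried twice within one cohort, and the formula is the operative
definition).

Note a structural property of the ratio statistics: with unequal cohort
sizes, ACdiff has a nonzero expectation even under equal AFs (E[ACdiff] ≈
(n_LT − n_HT)/(n_LT + n_HT) for common variants), and both diffs are noisy
for rare variants, where a handful of carriers swings the ratio past any
fixed threshold. The filter is therefore most reliable for common variants.

## Motif disruption score

For a PWM with probability columns p_i, position weights are
`w_i = IC_i / Σ IC` with `IC_i = 2 + Σ_b p'_i(b) log2 p'_i(b)` and
`p' = (p + 1e-3)/(1 + 4e-3)` (pseudocount to keep zero probabilities
finite). A window scores `Σ w_i p_i(base_i)`, min–max-normalized over all
possible sequences to a relative score in [0, 1]; a PWM with no
information (max = min) scores every window 1 by convention. The effect
size of a variant is `score(alt) − score(ref)` at the window/strand
maximizing `max(score_ref, score_alt)` among all windows covering the
variant (so both gain and loss of binding are captured); ties break to the
leftmost window, then the plus strand. `|ES| >= strong_es_min` (default
0.4) is "strong"; the threshold is configurable because the underlying
analysis never quantifies "strong", and 0.4 on the relative-score scale
requires the variant position to carry a large share of the motif's
information. Exact zero effect classifies as neutral.

## Enrichment tests

All 2x2 tests use the exact hypergeometric (Fisher) test from scipy; the
test suite cross-checks it against a brute-force enumeration of all tables
with fixed margins for every table with total ≤ 40.

*DI enrichment.* Genes are partitioned into candidate-connected (≥ 1
linked candidate variant; a gene linked to both kinds counts here —
dominance rule) and rest-connected; genes with no variant-bearing PIR are
excluded. Two-sided Fisher by default (`fisher_sided`), since the
direction is the hypothesis under test; a one-sided option exists. A
pair-level mode treats (gene, variant) pairs as the unit of analysis.
Benjamini–Hochberg adjustment is available for multi-comparison reports.

*Gene-set enrichment* is one-sided (enrichment) with
`fold = (overlap/|query|) / (|trait ∩ universe|/|universe|)`; the default
universe in pipeline use is the set of interacting genes.

*Interval enrichment* follows the bedtools-fisher table construction:
after merging each set, a/b count query intervals by annotation overlap, c
counts unhit annotation intervals, and d fills a genome partitioned into
slots of the mean merged-interval length. That d cell is an acknowledged
approximation of the tool it mirrors, so the coverage-based fold
enrichment is the headline statistic and the p-value secondary.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions: cohort sizes (54, 42);
candidate cohort AFs (0.05, 0.35); mean absolute promoter–PIR distance
calibrated to 156 kb via a log-normal (σ = 1, μ solved from the mean);
PIR length ~860 bp; one 10 Mb chromosome; Poisson degree with mean 4
(clipped ≥ 1, and ≥ 2 for DI genes so rewiring can leave a shared
neighbor); 10% DI genes; 20% candidate variants; rewire fraction 0.6;
per-replicate edge detection probability 0.95; 0.1 noise edges per gene
per condition-replicate, each confined to a single replicate; 2% missing
genotypes; rest-variant AFs uniform on (0.25, 0.5), equal across cohorts
(common variants — see the rare-variant caveat above, which is a property
of the statistic, not something the generator should hide). Each stage
draws from its own RNG stream spawned from the master seed, so identical
seeds give byte-identical files and stages can be regenerated
independently.

Planted candidate variants sit inside baseline PIRs of DI genes (this is
the enrichment the pipeline must detect; a `plant_enrichment=False` switch
places them uniformly for null calibration) and inside a planted PWM
consensus site: the reference allele is the consensus base and the
alternate the lowest-probability base at that position. The planted PWMs
concentrate information at the variant position (one sharply peaked
column, weakly informative flanks); with evenly informative columns a
single substitution could only move the relative score by roughly 1/length
and no single variant would ever be "strong" — concentrating IC mirrors
the situation the strong-ES filter selects for. A uniform control PWM is
included and must never produce a non-neutral call.

Features of real data the generator does **not** emulate: linkage
disequilibrium between variants, population structure in the cohorts,
distance-dependent interaction-calling power, batch effects between
replicates, multi-variant PIRs (each synthetic PIR hosts at most one
variant, vs ~94% in real data), and sequence composition biases. Passing
tests therefore demonstrate the statistics and filters behave as specified
under controlled noise — not that the pipeline's power estimates transfer
to real cohorts.

## Problem sizes and seeds

The default synthetic dataset uses 200 genes / 100 variants / 96 patients,
enough for ~20 planted DI genes and ~20 candidate variants so recovery
metrics are stable across seeds; the null-calibration runs use 80 genes /
50 variants over 200 seeds, where the Fisher rejection rate at α = 0.05
stays inside the central 99% binomial band despite the test's conservatism
on small discrete tables. All randomness flows through
`numpy.random.Generator` seeded explicitly; k-means uses seeded restarts.

## Known limitations

* The headline statistic pair (JI, OCE) ignores edge weights (supporting
  pairs) and treats all neighbors equally.
* The bedtools-style d cell makes the interval-enrichment p-value scale
  with an arbitrary slot count; compare fold enrichments, not p-values,
  across annotation sets.
* The motif score is not calibrated to a p-value; "strong" is a
  relative-scale convention.
* No liftover or genome-build validation: coordinates are taken at face
  value within one namespace.
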