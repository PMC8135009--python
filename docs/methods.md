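# Methods

## Coordinates and data model

All genomic intervals are 1-based and fully closed, so
`length = end − start + 1`; this is the convention of the reference
summary tables (a region printed as 633735..634300 has length 566), and
every bundled table row satisfies it.  BED input/output converts to and
from 0-based half-open coordinates at the boundary only.  Distances
between a peak and a gene are gap sizes in bp: 0 when the intervals
overlap or abut, otherwise the number of bases strictly between them.
Chromosome names are opaque strings; no "chr"-prefix normalization is
attempted.  Strand is ignored in peak work (the fragment tables are
unstranded).

## Peak calling against a uniform null

**Null model.**  If the N reads of a library were placed uniformly on a
genome of G bp, the count in any fixed window of width w would be
Binomial(N, w/G).  A candidate window containing k reads is scored with
the exact upper tail P(X ≥ k) (`scipy.stats.binom.sf`); a Poisson
approximation is available as an option but the exact tail is the default
in every code path, because it is cheap at all the sizes this pipeline
meets and agrees with brute-force summation to ≤ 1e-6 relative error
(oracle-tested for N ≤ 1000).  The E-value multiplies the tail by the
number of candidate windows tested.

**Candidate windows.**  Peaks in this material are read-defined with
variable widths (DNA pile-ups 579 ± 34 bp), so windows are not tiled.
When mean coverage is below 0.5x, candidate windows are maximal clusters
of overlapping reads (gap tolerance 0).  Cluster merging degenerates as
coverage grows — at ≥ 1x the whole genome fuses into one cluster — so
above 0.5x mean coverage candidate windows are instead maximal runs of
coverage exceeding the 0.99 Poisson quantile of the genome-wide mean.
The 0.5x switch point and 0.99 quantile are segmentation choices, not
significance thresholds; retention is always decided by the window score.

**Calibration.**  The analytic cluster p-value is a *ranking score*, not
a calibrated tail probability: under the null every singleton cluster has
the same deterministic score, so the score distribution over windows is
far from uniform.  `peaks.calibrate_null` therefore simulates the same
read regime (N, G, width distribution) under uniform placement and maps
observed scores to rank-based empirical p-values, which are uniform under
the null by construction; the test suite verifies type-I rates at
α ∈ {0.05, 0.01, 1e-3} within 3 Monte-Carlo SDs.  Retention of strong
peaks uses the analytic score against the default threshold p < 1e-5
(strict), where planted 10–20-fold enrichments sit many orders of
magnitude below threshold; table-census operations use the p-values
carried by the tables themselves, since the workbench that produced them
does not publish its exact null computation.

**Nearest genes.**  The 5' gene of a peak is the nearest whose interval
lies at or before the peak start; the 3' gene the nearest at or after the
peak end; an overlapping gene is reported on the side of its midpoint
with distance 0.  A peak is "gene-mapped" iff either distance is 0.  A
side with no gene on the chromosome is blank, never distance ∞.

## Differential counts

Counts come from libraries prepared from equal nucleic-acid input, so
group totals are directly comparable and no library-size scaling is
applied by default.  One locus's (a, b) counts are completed into a 2×2
table with the remainders of each library and tested with the Yates
continuity-corrected chi-square (1 df); whenever any expected cell is
below 5 the two-tailed Fisher exact test is substituted (the sum of
hypergeometric probabilities of all margin-fixed tables no more probable
than the observed one, oracle-tested against full enumeration).  The
printed-table mode treats the table's p column as a ceiling and compares
with ≤, so an entry of "0.001" qualifies at α = 0.001 — required for the
published 39/30/9 census to reconcile — and "NS" never qualifies.  A row
representing two genes in one peak is a single record.  The 5-vs-59
Y-chromosome comparison is framed as goodness-of-fit of two counts
against equal expectation, completing the margins with complementary
counts out of 100; the table has no second printed margin, and this is
the minimal completion consistent with the reported significance.
Welch's t (Satterthwaite df) serves continuous two-sample comparisons.
No multiple-testing correction is applied (none is applied in the tables
being emulated).

## Viral screening

Coverage depth is averaged over covered positions only, which is the
natural reading of "≥5x coverage" for a partially covered genome; the
longest run counts consecutive positions with depth ≥ 1.  Thresholds are
inclusive and two-staged: retrieval (5x / 75 nt / 50 reads) is the loose
screen used to form group read ratios, positive identification
(5x / 100 nt / 400 reads) the strict screen.  Both are configurable.
The table-level census `count_positive_viruses` calls a virus positive
when some group/molecule sample meets the positive-ID read count; on the
bundled 10-virus table this yields 7, and per-sample depth/contiguity
verdicts are available wherever coverage detail exists.  Host-read
removal is accepted as an upstream mask, not re-implemented.

## G-quadruplex detection

The QGRS-style search finds four equal-length G-runs (≥ 2 G each, equal
run length across the four groups) separated by loops of 0–36 nt within a
motif of ≤ 30 nt.  The G-score is defined here explicitly as

    gscore = 20·g − (l1 + l2 + l3) − (max loop − min loop)

which rewards longer G-groups first, then total loop brevity, then loop
equality; overlapping candidates are resolved by keeping the
highest-scoring non-overlapping set (ties: leftmost, then shortest, then
smallest loop tuple — a total order, so results are reproducible).  The
scan equals exhaustive enumeration on all tested sequences ≤ 60 nt.
Both-strand scans run in a canonical orientation (the lexicographically
smaller of sequence and reverse complement) so the motif set is exactly
invariant under reverse complementation, including tie cases.

G4Hunter-style scoring assigns each base +min(run, 4) in a G-run,
−min(run, 4) in a C-run, 0 otherwise, and averages over sliding windows
(default 25 nt); |score| ≥ 1.3 flags quadruplex propensity.

"Random expectation" for fold-enrichment is the mean motif count over
mononucleotide shuffles preserving base composition (default 100,
seeded).  Fold = (observed + 0.5)/(expected + 0.5); the pseudocount
prevents division by zero and means a zero-expectation locus needs ≥ 50
observed motifs to clear the >100-fold "G4-rich" cut.  Cutpoints are
strict (>100 rich, <20 poor, else intermediate).

## Contactome

Nodes are retained when ≥ `min_hits` spectral hits appear in
≥ `min_replicates` replicates (defaults 10 and 2 of 3); the filter is
idempotent and edges touching dropped nodes are discarded.  Central hubs
have degree > 4 on the filtered graph.  A hub connector is a node of
degree ≤ 4 whose removal places at least two central hubs of its
component into different components — the minimal formalization of
"joining hubs not otherwise connected" — and is verified in tests against
a brute-force remove-and-test oracle.  Clusters are connected components,
indexed by smallest protein id; components are the only parameter-free
reading of "clusters" here.  Degree per residue (degree / protein length
in aa) compensates for the tendency of very large proteins to accumulate
contacts by size alone; both raw and normalized degree are emitted so a
census can be formed on either.  Edge weights (crosslink counts) are
carried for reporting but do not affect topology-based roles.
Annotation enrichment is the upper-tail hypergeometric probability.

## Synthetic data

The generator produces every input class with planted, machine-readable
truth: uniform-background fragment reads with fold-enriched peaks (widths
DNA N(579, 34), RNA N(291, 31), truncated at 50 bp to avoid degenerate
intervals), Poisson two-group counts (count_a ~ Poisson(m),
count_b ~ Poisson(m/ratio), equal library depth 1e7 by default — the
minimal count-sampling model consistent with chi-square/Fisher testing),
viral read layouts realizing requested (reads, depth, run) triples
exactly up to integer rounding, genomes with embedded canonical G3
quadruplex motifs (loops 1–7 nt, non-G flanks) at a stated density, and
contact graphs built from ≥5-spoke hub stars chained into a requested
number of clusters with degree-2 connectors.  Default background read
density is deliberately scenario-level (stated in the shipped example
configurations and tests, not hard-coded into the analysis), since no
single value is canonical.  All outputs are deterministic given the
scenario seed; truth tables are TSV.

What the generator does *not* emulate: sequencing error, base-quality
structure, paired ends, mappability variation, GC bias, or correlated
(overdispersed) counts.  Passing recovery tests therefore demonstrates
correctness of the inference machinery under its stated model, not
robustness to real-library artifacts.

## Problem sizes and numerical choices

Simulation-based tests use genomes of 60–200 kb, null-calibration runs of
~12–15k reads on 40–50 Mb with 8–10 calibration replicates (~1e5 null
windows), 50–100 seeded replicates for recovery rates, and 1e4 loci for
null count calibration; these sizes put Monte-Carlo error well inside the
asserted 3-SD bands while keeping the whole suite under a minute of
statistical work.  Ratios are reported rounded to 2 decimals (full
precision retained internally); undefined ratios (zero denominator) are
flagged missing, never ±inf.  "No peak" table entries are missing values,
never p = 1.

## Known limitations

* Peak-table p-values are consumed as given; the commercial workbench's
  exact null is unpublished, so those values are inputs, not outputs.
* The per-locus G4 fold-ratio census of the original study depends on
  human-genome sequence not shipped here; the G4 stage is validated on
  synthetic loci and oracle suites instead.
* The hypergeometric enrichment p of the contactome depends on the chosen
  annotation universe; the kernel is exact, the universe is the caller's.
* Which specific threshold each screened-out virus failed is not
  recoverable from count data alone; per-threshold verdicts require
  coverage-level input.
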