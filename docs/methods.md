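# Methods notes

This note records the statistical model behind `factorscan`, the defaults and
why they are what they are, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would otherwise have to
reverse-engineer from the code.

## The screen, end to end

The unit of analysis is a gene × factor matrix of ChIP signals. Peak-to-gene
assignment uses BED semantics throughout: narrowPeak and gene-domain intervals
are 0-based half-open, and any intersection of ≥ 1 bp counts as overlap. Gene
domains are the gene body ± 5 kb (`flank`, default 5000 bp), clamped at
coordinate 0 only — no chromosome-size file is consumed, so there is no
right-edge clamp. Records sharing a symbol are merged to their union span
before flanking, which is the conservative superset of any per-transcript
choice. Per gene and factor the matrix stores the *maximum* signalValue over
all peaks of all cell types; the maximum (rather than a sum or mean) makes the
value robust to differing numbers of cell types per factor. Each factor column
is rescaled to sum to 100,000 so tail means are comparable across factors;
all-zero columns have no defined rescaling and are dropped with a warning.

The enrichment statistic is a one-sided CDF-gap screen followed by a rank
test. With Q ⊆ B, D_S = sup(B−Q) and D_I = inf(B−Q) are computed exactly on
the grid of observed values (the difference of two step functions is constant
between observed values, so the grid is sufficient). Triage keeps a factor iff
|D_S| > |D_I|; exact ties — including the degenerate flat case — are
discarded, since a factor indistinguishable from background has nothing to
score. When D_S is attained at several thresholds the smallest is taken as
c*, which makes the leading-edge target set (signals strictly > c*) the
largest of the tied candidates and keeps it deterministic.

The Mann–Whitney test treats the query as drawn from within the background
(that is how the lists are constructed), so the small-sample exact null
enumerates all C(N, X) query-sized subsets of the background and counts those
whose midrank U statistic meets or exceeds the observed one. Enumeration is
used when C(N, X) ≤ 20,000 and the query really is a sub-multiset of the
background; otherwise the normal approximation with midranks, tie correction
and continuity correction applies. If every value is tied the test is
undefined and p = 0.5 is returned with a log message. BH correction runs over
the surviving (non-triaged) factors only — the triage step is a filter, not a
test, and correcting over filtered-out factors would double-count it.

The tail ratio uses n = max(1, round(0.05·X)) so short query lists still have
a defined tail; both means are over exactly n values. The score is
S = −log(P_corr)·r with **log base 10** (`log_base`, exposed as a parameter).
The base is a genuine convention choice: published scores of this statistic
are not always consistent with any single base and probability column, so the
implementation keeps the formula literal and the base explicit.

## Differential expression

The multi-model design is collapsed to one column per (model, condition,
timepoint) by the per-gene median, so each laboratory/model contributes one
vote. "Fold change" is the difference of group means of these model medians
on the log2 scale. The DEG rule is FDR < 0.05 (BH over all genes, Student
t-test, equal-variance, two-sided) *and* a fold change more than `sd_mult`
(default 2) standard deviations from the day's mean fold change in the
matching tail; the envelope is computed per day, not pooled across days.
Genes with zero variance in both groups get p = 1 (logged) rather than NaN.

Overlap tests report both the sample odds ratio ad/bc and the conditional
maximum-likelihood estimate from the noncentral hypergeometric likelihood;
the conditional MLE is the headline value (it is what standard exact-test
implementations print, and it reproduces the published persistence odds
ratios 139/283/133/341 within 1.5%, where the sample OR overshoots slightly).
Sample clustering uses 1 − uncentered Pearson correlation with complete
linkage — the uncentered variant treats the origin as meaningful, which is
appropriate for log-intensity profiles.

## Targets and factor groups

Pairwise Fisher tests of leading-edge target lists use the query list as the
universe. Cells with OR ≤ 1 or p ≥ 0.05 are masked to 0; the clustered matrix
is the masked one (the displayed map and the clustered map are the same
object — clustering the unmasked p-values would let sub-significant structure
drive the dendrogram). Grouping cuts the complete-linkage tree strictly below
the Pearson-distance threshold (default 0.7, i.e. correlation > 0.3); a cut
of 0 therefore yields all singletons, and zero-variance rows — factors with
no significant overlaps at all — are assigned maximal distance and come out
as singletons rather than propagating undefined correlations.

## Cohort modules

Probe filtering keeps probes with detection p < 0.05 in ≥ 20% of samples
(boundary inclusive). After median collapse to symbols and per-sample median
normalization, the variability filter keeps genes whose coefficient of
variation exceeds the cohort median CV. The criterion is stated ambiguously
in common pipelines (variance vs median CV mixes units); CV-vs-median-CV is
the default because both sides are dimensionless, and
`variability="variance"` switches to variance-vs-median-variance.

k-medians is the textbook L1 variant: assignment to the nearest center in L1,
centers updated to per-dimension medians, k-means++-style seeding under L1,
best of 20 restarts by total cost, empty clusters re-seeded from the worst-fit
gene. Cost is non-increasing within a run, and restarts can only improve the
returned solution; both properties are tested. The partition is deterministic
for a fixed seed but, like any k-medians, not guaranteed stable across seeds.

The cross-cohort module test compares per-gene means between cohorts with a
two-sided Mann–Whitney test on the two mean vectors (only symbols shared by
both platforms are used, and the count is logged). Direction is the sign of
the median paired difference, reported independently of the p-value.

## The synthetic generator

The generator's defaults are the study conditions used throughout the tests
and the acceptance script: 2,000 genes, 20 factors, 100 target genes, planted
ChIP signal scale 10×, expression effect −2 log2 units, and a rodent design of
5 models × (6 control + 6 case) per timepoint.

ChIP signals are log-normal (meanlog 1, sdlog 0.75) — right-skewed like real
peak signalValues, with zeros where a domain carries no peak (each cell type
covers a gene with probability 0.5–0.6; the planted factor always has 3 cell
types so ~94% of its targets carry at least one peak). Crucially, the planted
factor differs from the null factors *only* through the ×scale multiplier on
target-gene signals: at scale 1 it is exactly exchangeable with the nulls,
which is what makes the null-calibration rate a clean false-positive
estimate. Expression is N(8, 1) log2 baselines with within-group noise of
SD 0.5, and the cohort design adds a shared latent factor across target genes
(so k-medians has a module to find) plus probe-level structure: ~10% of genes
carry a second probe, half of which fail detection, exercising the filter.

What the generator does **not** emulate: real genomic geometry (domains never
overlap, every gene is the same length), correlated binding between factors,
batch or laboratory effects, platform-specific probe behavior, and
heavy-tailed expression noise. Passing tests therefore demonstrate that the
algorithms recover a planted signal under clean, well-separated conditions —
they do not establish sensitivity or calibration on real compendia, where
factor co-binding and annotation noise will lower both.

## Problem sizes and numerical details

The recovery and calibration runs use 20 seeds (signal scale 10) and 50 seeds
(scale 1) at the default 2,000 × 20 size with a single timepoint — enough to
resolve the ≥95% / ≤10% rates being checked while each run stays around a
second. Normalization asserts column sums to a relative 1e−9. MWW exact
enumeration caps at 20,000 subsets. Fisher's p uses the exact two-sided test;
its conditional-MLE odds ratio is 0 when the overlap is empty and infinite
when a off-diagonal margin is empty. All randomness flows from
`numpy.random.default_rng(seed)`; file outputs use fixed float formatting so
fixed-seed reruns are byte-identical, which the tests check with literal file
comparison.

## Known limitations

- The screen conditions on the query being a subset of the background; query
  genes are *not* removed from the background sample in the rank test, so p
  values are slightly conservative for large query fractions.
- Factors screened are limited to whatever the compendium contains; absence
  of evidence for unprofiled factors is not evidence of absence.
- The leading-edge rule with a strict `>` at c* can return an empty target
  set for weakly shifted factors; downstream overlap maps skip such factors
  naturally but report nothing about them.
- k-medians module counts (k, default 10) are a modeling choice, not
  estimated from the data.
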