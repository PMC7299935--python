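# Methods

## Problem and model

Structural variants can deregulate genes without touching them: a
breakpoint falling between a promoter and a distal regulatory element
severs their chromatin contact on the rearranged allele. The pipeline
detects such events in a cancer cohort by requiring three independent
signals to coincide in the same donor and gene: (i) a breakpoint disrupting
a promoter interaction of the gene, (ii) an outlying expression value for
that donor, and (iii) recurrence of the same disrupted contact with a
concordant expression change in at least one more donor. A survival screen
then asks which candidates carry prognostic information, and a concordance
statistic checks whether externally derived gene sets (e.g. genes
responsive to pharmacological inhibition of a candidate) shift coherently
between donors with extreme expression of that candidate.

## Coordinate conventions

Internal coordinates are 0-based half-open throughout; all external files
(breakpoint tables, interaction tables, `chr:start-end` strings) are
1-based fully closed and converted at the I/O boundary. This removes
off-by-one ambiguity from overlap tests: touching half-open intervals do
not overlap. Breakpoint windows are clamped at position 0 near contig
starts rather than erroring. Two-ended SV records are decomposed into two
independent breakpoints sharing a donor ID — recurrence is counted per
breakpoint, matching how cohort breakpoint counts are usually reported —
and exact duplicates (donor, chromosome, position) are removed on read,
since the two ends of an intra-chromosomal SV can repeat coordinates.

## Disruption mapping

Each breakpoint is extended by ±`flank_bp` (default 50 bp, giving a
2·flank+1 window) and intersected with the interactome via an interval
tree. Two hit definitions are first-class because the biology does not
decide between them: *span* mode (default) scores any overlap between the
window and the full bait-to-PIR stretch — a break anywhere in between
separates the elements — while *anchor* mode requires overlap with the PIR
fragment itself. Anchor-mode events are a subset of span-mode events for
cis contacts; trans contacts have no span and are skipped with a logged
count in span mode. The anchor reported for an event is always the PIR
fragment of the hit interaction, whatever the breakpoint's position within
the span.

## Expression stage

Normalization is median-of-ratios: reference genes are those with strictly
positive counts in every donor; donor *d*'s size factor is the median over
reference genes of count(g,d) divided by the gene's geometric-mean count
across donors. Only this normalization step of the negative-binomial
differential-expression framework is reproduced; dispersion estimation and
Wald tests are out of scope. The implementation is cross-checked in the
test suite against an independent reference implementation of the same
estimator.

Per-gene statistics (median, IQR = Q3 − Q1) are computed over the donors
that have SV data (`stats_donor_scope = sv_donors`; an `all_donors` mode
exists for benchmarking), with quantiles by linear interpolation between
closest order statistics — the common default of mainstream numerical
stacks; the convention matters at small n and is therefore fixed and
tested. Deviations are two-sided (absolute value, sign retained): the
filter concerns "expression changes", and a directional
(upregulation-only) flag is available but off by default. With a zero IQR
the deviation is ±∞ for values off the median and 0 at it. The expression
floor (> 10 normalized) applies to the donor's own value, not the gene
median, at both the primary (> 2 IQR) and recurrence (> 1 IQR) levels; all
comparisons are strict.

## Candidate calling

"Similar disrupted interaction" for recurrence defaults to sharing the PIR
anchor fragment with a primary donor's event for the same gene (candidates
are typically attributed to one disrupted anchor shared across donors); a
relaxed mode accepts any disruption of the same gene. The primary donor
counts toward `min_recurrent_donors` (default 2: one primary plus one
additional). Since a primary outlier is by construction also a recurrence
outlier (k_primary ≥ k_recurrence, same floor), primary donors are always
a subset of the recurrent set. The reported gene locus is the min–max span
of the gene's bait fragments — the pipeline carries no external gene model,
so the promoter fragments stand in for the locus; a gene with baits on
several chromosomes gets no locus.

## Survival screen

Donors are split at the median of the candidate's normalized expression,
ties to the low group (affects small cohorts only). Because different
cohorts may use different expression platforms, the split is computed
within each cohort separately and the groups are pooled for the test
(`split_by_cohort = True`; a pooled-split option exists). The two-group
log-rank test uses the standard O/E/V form, χ² with 1 df and no continuity
correction; Kaplan–Meier estimation and the test itself are delegated to
lifelines, and the test suite validates both against hand-computed
product-limit and O/E/V tables and against a permutation null. BH
adjustment runs over exactly the candidates tested in the run. Donors
present in only one of the expression matrix and survival table are
dropped with logged counts; genes with degenerate splits or zero events
are skipped with warnings rather than failing the screen.

Note on validation: the log-rank p is asymptotic. At the 20-donor scale
used in the permutation cross-check the exact permutation p differs from
the χ² p by up to a few hundredths even with no Monte-Carlo noise, so the
cross-check allows Monte-Carlo error plus an explicit 0.05 approximation
margin; the statistic itself matches the first-principles oracle to 1e-9.

## Concordance stage

Extreme groups are the floor(fraction·n) highest and lowest donors
(default fraction 0.10), ordered by (value, donor ID) so ties break
deterministically and the groups are disjoint. Fold changes are
log2((median_high + 1)/(median_low + 1)): the downstream test is
rank-based, so only the ordering of fold changes matters and a full count
model would change nothing; genes at zero in both groups get fold change
0. The gene-set shift test is a two-sided Mann–Whitney U of the set's fold
changes against all other genes in the table (the set is excluded from the
background, the standard two-sample framing), with exact enumeration when
both sides have ≤ 20 tie-free values and the tie-corrected normal
approximation otherwise; direction (sign of the median difference) is
reported separately.

## Synthetic cohorts

The generator emulates the study conditions: 92 donors and ~750
breakpoints by default (20 planted + 730 background), 2,000 genes, 300
interactions. Geometry is deterministic — 5 kb baits and 20 kb PIRs with a
15 kb gap, tiled in non-overlapping 80 kb slots — and each interaction can
carry several gene IDs to model multi-gene loci sharing an anchor. Planted
(gene, donor) pairs get a breakpoint uniform inside the gene's PIR anchor;
background breakpoints fall uniformly outside every interaction span (a
background breakpoint within flank distance of a span edge can still
register a disruption, which is intended — such donors lack expression
outliers and are removed by the filter). Counts are negative binomial with
var = μ + αμ² (α = 0.1, a typical bulk RNA-seq dispersion), means
μ = sf_d · q_g with log-uniform size factors in [0.5, 2] and baselines in
[20, 200], and a multiplicative cis-effect (default 8×) on planted cells.
Survival is exponential — chosen over Weibull for analytic transparency —
with baseline hazard 5·10⁻⁴ per day (median ≈ 3.8 years) and the hazard
ratio applied to the median-split high group of a designated gene, so the
planted effect matches exactly what the screen tests; censoring is
independent uniform with the horizon solved numerically so the expected
censored fraction hits the target (default 0.3). Each stage draws from its
own seed stream, making stages reproducible in isolation.

What the generator does not emulate: linked copy-number changes, SV class
structure, cohort batch effects beyond size factors, gene–gene expression
correlation, and non-proportional hazards. Passing recovery tests
therefore show the pipeline's filters behave as specified under the
declared noise model, not that real cohorts are free of confounders.

## Calibration and problem sizes

The self-validation benchmarks (shared by the tests, the acceptance
script, and `analysis/06_calibration.py`) use: 20 replicate cohorts of 100
donors / 1,000 genes / 10 planted genes for recovery (recall ≥ 90%
expected, ≈ 0 false candidates under the default geometry, since
background breakpoints rarely coincide with expression outliers); 500 null
replicates of 100 donors for log-rank type-I error, judged against the
exact binomial 99% band around 0.05; 100 replicates of 200 donors at
hazard ratio 3 for power; 1,000 random 50-gene sets from a 1,000-gene null
table for shift-test uniformity (KS test); and a +2 shift on 200 of 5,200
genes for the headline effect-size class (p < 10⁻¹²). These sizes keep the
whole validation in the order of seconds to a minute on one CPU while
leaving the binomial and KS checks well-powered.

## Known limitations

Candidate anchors, not breakpoint phase or derivative chromosomes, define
recurrence: two donors breaking the same contact from opposite sides are
treated alike. The survival screen is univariate (no Cox model, no
covariates such as IGHV or TP53 status). The published candidate table is
used only as a filter input and worked example; its BH family size is not
recoverable from the six printed p-values, so the printed adjusted values
are taken as given rather than recomputed.
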