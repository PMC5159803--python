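# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `polarmir`.

## Study design assumed throughout

Two polarization conditions (M1, M2) sampled at 1, 2, 4 and 8 h in
duplicate (16 polarized samples) plus duplicate unstimulated M0 controls
collected at 1 h.  M1 and M2 must share the same time points: the
differential-expression model and the per-timepoint fold changes are
time-paired contrasts.  M0 samples are used only for the optional
M0-relative clustering profiles; they are excluded from the two-factor
model and, by default, from the correlation filter (an
`include_m0_in_scc` switch adds them, since it is ambiguous whether "all
samples" should include controls).

## Normalization and detection

Size factors are the median, over features with a positive geometric mean,
of the ratio of each sample's count to that feature's geometric mean.  The
median is taken on the linear ratio scale (with an even number of usable
features this differs microscopically from taking it in log space; the
linear form is the documented contract and the one the oracle tests pin).
Detection keeps genes with a nonzero count in at least one sample and
miRNAs whose maximum normalized count strictly exceeds 10.

## Moderated two-factor differential expression

Expression is `log2(normalized count + 1)`; the pseudocount of 1 is logged
and configurable.  Per feature, ordinary least squares fits
`condition + time` with time categorical; with 16 samples and 4 time
points the residual degrees of freedom are 11.  Residual variances are
shrunk by empirical Bayes: writing `e_g = log s_g² − ψ(d/2) + log(d/2)`,
the moments of a scaled inverse-chi-square prior give
`trigamma(d₀/2) = Var(e) − trigamma(d/2)` (solved by Newton iteration on
the trigamma function) and `s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`.
When the observed spread of `e` does not exceed pure sampling noise the
moment equation has no finite solution; the fit then keeps the
per-feature variances unmoderated (equivalently d₀ = 0) and logs a
warning — in the genuinely degenerate case where all variances coincide,
this matches the no-op the model implies.  Zero residual variances are
floored at 1e-8 before taking logs.

The moderated t is the condition coefficient over `s̃ · c`, with `c` the
design-based standard-error factor, referred to a t distribution with
`d + d₀` degrees of freedom.  Fold changes are per-timepoint ratios of
pseudocounted mean normalized counts; the average absolute fold change is
the mean over time points of `max(FC, 1/FC)` on the linear scale (a log
scale average is available via `fc_average_scale`).  "Adjusted combined
p-values" for miRNAs are read as the BH-adjusted p of the single condition
contrast; no combination rule across time points is applied.  All calling
inequalities are strict, uniformly: average fold change exactly at the
threshold, adjusted p exactly at 0.05, membership exactly 0.5, SCC exactly
−0.5 and a maximum normalized count of exactly 10 all fail their filters.

Calibration: on a no-effect simulation the raw p-values are uniform within
binomial 99% bounds at the 1% and 5% levels (tested).

## Time-trend clustering

Profiles are 8-dimensional: log2 mean normalized expression at each time
point, M1 block then M2 block, standardized per gene.  Both conditions
enter because the cluster semantics contrast M1-high against M2-high
trends; an M0-relative variant (subtracting the log2 M0 mean before
standardization) is behind the `relative_to_m0` flag, since published
descriptions of this step are ambiguous between absolute and
control-relative profiles.  Constant genes are excluded with a logged
reason.

Fuzzy c-means uses Euclidean distance, fuzzifier m = 2.0, c = 4, seeded
initialization by sampling c distinct profiles as centers, and alternating
membership/center updates until the maximum center shift falls below 1e-6
(cap 500 iterations; non-convergence warns, never raises).  The objective
Σ uᵐ d² is non-increasing across iterations (asserted in tests).  Because
the objective has local optima, `n_init = 10` seeded restarts are run and
the lowest final objective kept, mirroring k-means practice.  A profile
coinciding exactly with a center receives full membership there.  Hard
assignment requires the maximum membership to strictly exceed 0.5, which
guarantees uniqueness; the assigned fraction is reported.

## Target prediction

The seed is miRNA positions 2–8.  UTR sense-strand patterns: 7mer-m8 =
reverse complement of positions 2–8; 8mer = 7mer-m8 followed by A;
7mer-A1 = reverse complement of positions 2–7 followed by A; 6mer =
reverse complement of positions 2–7.  UTRs are DNA (U→T handled at the
matching layer).  The scanner reports all exact, possibly overlapping
occurrences, with 7mer matches nested inside an 8mer occurrence reported
once as the 8mer; N never matches.  The default enabled types are the
canonical trio (8mer, 7mer-m8, 7mer-A1); 6mer is off by default since it
is weak evidence, and no context scoring or conservation filtering is
applied — the anti-correlation filter carries the evidence weight.
Multiple UTR records for one gene (via an explicit gene map) have their
sites unioned at the gene level.

## Anti-correlation integration and the network

Spearman's correlation (Pearson on mid-ranks, average ranks for ties) is
computed per predicted pair across the 16 polarized samples; p comes from
the t approximation `t = ρ√((n−2)/(1−ρ²))`, BH-adjusted across all
predicted pairs jointly.  Pairs with a constant vector are emitted with a
null SCC and excluded from testing.  The refined targetome keeps pairs
with SCC < −0.5 and adjusted p < 0.05 (strict); the high-confidence
network keeps SCC < −0.8, resolving the sign ambiguity in "more than 0.8
negative correlation" as a magnitude threshold on negative correlations,
consistent with the repression model.  The network is bipartite by
construction; miRNA DE direction splits it into M1 and M2 subnetworks;
hubs are genes ranked by miRNA degree; genes carry TF / C2H2 / DE
annotations from user-supplied lists.  Per-miRNA Fisher exact tests
(two-sided, hypergeometric enumeration as implemented in scipy) compare
predicted targets with an experimentally validated set over the detected
universe.

## Enrichment statistics

**GSEA.**  Ranked list per miRNA = its refined targets ordered by the
moderated t (deterministic tie-break on gene id); gene sets are pathways
intersected with that list; miRNAs with fewer than 10 ranked targets are
skipped.  The running sum adds `|t|^w / Σ|t|^w` at hits (w = 1 by default)
and subtracts `1/(N−K)` at misses; ES is the extremum by magnitude, the
leading edge the set members at or before (after, for negative ES) the
extremum.  The null permutes gene labels — with two replicates per cell,
sample permutation is impossible — and the p-value is the +1-smoothed
frequency of same-sign null scores at least as extreme.  Conditioning on
the sign matters: the ES sign is chosen post hoc, and an unconditional
denominator doubles the false-positive rate (measured 12% at nominal 5%;
the conditional form tests at 6.3%, inside binomial 99% bounds).  NES
divides ES by the mean magnitude of same-sign null scores.  Raw p < 0.05
defines the miRNA → leading-edge-gene network (both raw and BH-adjusted
p are reported, since significance conventions differ).

**Hypergeometric heatmap.**  Per (miRNA, time point): universe = detected
genes, K = the miRNA's targets, n = genes DE at that time point
(|log2FC_t| > log2 threshold and adjusted p below threshold — the global
thresholds applied per time point), k = overlap; upper-tail p, BH-adjusted
jointly across all cells; display order of miRNAs from hierarchical
clustering of the significance-flag patterns.

**Cluster ORA.**  One-sided hypergeometric per cluster × pathway over the
detected universe, BH within cluster, members deduplicated; each row lists
the overlapping genes and the DE miRNAs targeting at least one of them
(one defensible reading of how pathways map to "potentially regulatory"
miRNAs; no formal rule is published).

## The synthetic-data generator

The generator is the package's test bed and defines the conditions all
recovery numbers refer to.  Defaults: 2500 genes, 60 miRNAs, four DE
archetypes of 150 genes each (M1-high decreasing, M1-high increasing,
M2-high stable, M2-high increasing; linear log2 ramps 1.7→0.3 of amplitude
`logfc_magnitude` = 2), 8 M1- and 6 M2-specific miRNAs split into early
(peaking at 1–2 h) and late (4–8 h) classes with per-miRNA kinetic jitter,
12 exclusive targets per miRNA plus 6 shared targets with 3–5 regulators
each (the planted network hubs).  Counts are negative binomial with
variance μ + φμ² (φ = 0.05, one dispersion for all features), log-normal
baselines, and uniform per-sample library factors in [0.7, 1.3].

Two generator choices deserve explanation.  First, planted targets are
drawn from the archetype DE genes of the *opposite* condition: an
M1-specific miRNA represses genes that are relatively M2-high.  This
mirrors the real biology of polarization targetomes (target status is
orthogonal to trend family, and repressed targets are down in the
condition where their regulator is up) and it is what makes four-cluster
recovery possible — targets planted as otherwise-null genes form shape
families of their own that fuzzy c-means latches onto at c = 4.  Second,
miRNA trend amplitudes are half the gene amplitude (≈1 log2 unit with
jitter): induction of miRNAs during early polarization is more modest than
the downstream transcriptional response, and it keeps the repression term
(`repression_slope` × the regulator's log2 trend, slope 1.5 by default;
doubled for a "strong" subset used to plant a recoverable GSEA pathway) a
perturbation of the target's own trend rather than a replacement for it.
At `repression_slope = 0` the miRNA term vanishes exactly; at
`logfc_magnitude = 0` and slope 0 the bundle is a global null used for
calibration tests.

Sequences: every miRNA is a random 22-nt RNA with a unique seed; each
target UTR (200 nt) receives one non-overlapping planted canonical site
per regulator (type drawn from the canonical trio) and is rejection-sampled
until the scanner finds exactly the planted regulators and nothing else;
non-target UTRs are rejection-sampled to contain no canonical site for any
simulated miRNA.  Predicted pairs on a bundle therefore equal the planted
pairs exactly, which is what lets recovery statements be sharp.

What the generator does **not** emulate: read-level artifacts (mapping,
duplicates, GC bias), heterogeneous dispersions, isoform structure, miRNA
biogenesis, indirect (secondary) regulation, correlated gene-gene noise,
and non-canonical target sites.  Passing recovery tests therefore
demonstrates the pipeline's correctness and power under its own model
assumptions — not performance on real sequencing data, where fold-change
magnitudes, dispersion and target-site behavior are less clean.

## Problem sizes and determinism

Default analyses run on the 2500 × 18 / 60 × 18 matrices above; the test
suite and the acceptance script use these sizes or smaller, with GSEA at
500–2000 permutations.  Every random step (simulation, FCM initialization,
GSEA permutations) is driven by explicit seeds; identical configuration
and seed reproduce every output file byte-identically.  Tables are written
with 6 significant digits (p-values: 4-digit scientific), which defines
the byte-stable output format.

## Known limitations

- The fuzzy-cluster recovery of the fourth archetype (M2-high increasing)
  sits closest to its stable neighbor; across seeds its recovery ranges
  roughly 0.77–1.0, a genuine property of soft clustering on adjacent
  trend shapes rather than a defect.
- The Spearman p-value uses the t approximation at n = 16; an exact
  permutation p is only warranted for very small n and is not the default.
- The DE model tests a single condition main effect; time × condition
  interaction contrasts and count-model (NB GLM) testing are out of scope.
- DAVID/Broad-GSEA/TargetScan web resources are not queried; pathways,
  UTRs and annotations arrive as local GMT/FASTA/TSV files.
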