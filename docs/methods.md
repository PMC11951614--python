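# Methods

This note records the models, parameter choices and numerical conventions
behind `methylmemory`, and what the synthetic generators do and do not
emulate.

## Differential methylation

**Input model.** Each sample is a set of per-CpG methylated/unmethylated
read counts (M, U) in the Bismark CpG-report dialect, 1-based positions.
Plus/minus records of one CpG dinucleotide are collapsed onto the
plus-strand coordinate with summed counts.  All samples are outer-joined
onto a common CpG universe; a CpG absent from a sample has coverage 0
(no imputation), which is the conservative reading of a per-replicate
coverage rule.

**Site filter.** A CpG is retained iff M + U ≥ 2 in *every* replicate of
both compared groups, and its chromosome is autosomal ("chr" prefix
optional; any non-numeric suffix such as X/Y/M is excluded).  The
per-replicate rule means one 1X replicate sinks a site regardless of the
others.

**Smoothing.** Raw methylation M/(M+U) is smoothed per chromosome with a
coverage-weighted local quadratic fit: for CpG *i* the window is the
smallest symmetric interval containing ≥ ns CpGs (default 70) and spanning
at least 2h bp (default h = 1000), weights are tricube in scaled distance
times read coverage, and the fitted value at *i* is clamped to [0, 1].
These defaults are the published defaults of the smoother this design
follows.  A quadratic fit reproduces constant and linear signals exactly;
a singular local system falls back to the weighted mean.  Chromosomes with
fewer than 3 CpGs are returned as raw ratios and flagged.  Smoothing never
crosses chromosome boundaries and is translation-equivariant.

**t-statistics.** For groups A, B with n_A, n_B replicates of smoothed
values, per CpG:

    t_raw = (mean_A − mean_B) / (sd_pool · sqrt(1/n_A + 1/n_B))

sd_pool is the replicate standard deviation pooled across groups, floored
at its genome-wide 75th-percentile quantile (a positive floor is
guaranteed: if the quantile is 0 the smallest positive sd is used), then
smoothed by a k-CpG running mean (k = 21, the interpretation adopted for
the cited method's k).  With local correction enabled (default), a coarse
trend — per-chromosome bin medians at halfwidth/5 resolution (halfwidth
25 kb), running-mean smoothed and linearly interpolated back to CpG
positions — is subtracted from t_raw.  Every step is odd-symmetric, so
swapping the groups negates the corrected track exactly.

**DMR calling.** Cutoffs are the empirical 0.05/0.95 quantiles of the
corrected t over all retained CpGs; candidates are maximal sign-pure runs
beyond a cutoff.  Candidates are split at every inter-CpG gap > 300 bp,
then fragments are kept iff n ≥ 5 CpGs and |mean smoothed difference| ≥
0.10.  Split-before-filter is the default order (it guarantees every
emitted DMR satisfies all constraints simultaneously); the literal
filter-then-split order is available via a flag.  Thresholds are
inclusive, with a 1e-12 guard against float summation error at the 10%
boundary.  The mean difference uses smoothed values, consistent with the
upstream smoothing; DMR intervals are emitted 0-based half-open spanning
the outermost member CpGs.  Direction convention: "hyper" means the first
argument group is more methylated.

**PCA.** Samples × smoothed-methylation matrix, zero-variance CpGs
dropped, columns centred and scaled to unit variance, SVD; explained
variance fractions sum to 1.

## Memory analysis

Meta-region profiles rescale each DMR to [0, 1] with flanks of 0.5× the
region width per side (total profiled span 2× the width), 30 in-region +
15 bins per flank, averaging each region's per-bin CpG mean and then
averaging regions unweighted — a region contributes equally regardless of
CpG count (a CpG-weighted variant would down-weight sparse regions;
unweighted matches standard meta-plot practice).

Classification of a recovered group at one DMR uses the member-CpG group
means: with d_adm = mean_ADM − mean_control and d_rec = mean_recovered −
mean_control, the label is `reverted` if |d_rec| ≤ tol (tol = 0.01; there
is no principled revert tolerance, so it is exposed), `opposite` if the
signs disagree, `more_extreme` if |d_rec| ≥ |d_adm|, else `intermediate`.
A trio with |d_adm| ≤ tol is not a differential region and raises.  The
"more extreme than both ADM timepoints" subset applies the magnitude
comparison conjunctively against each timepoint; when one timepoint's own
difference is below tol its sign is treated as noise and only magnitudes
are compared.

Gene-level overlap of two DMR sets reports all three denominators
(first set, second set, union) explicitly, since "% of the total" is
ambiguous; coordinate-level overlap is available by intersecting the DMR
interval sets directly.

## Enrichment

DMR-gene intersection is half-open interval overlap (≥ 1 bp; abutment is
not overlap) via an interval tree, with an explicit error on chromosome
naming mismatches.  Overrepresentation is the one-sided hypergeometric
tail (equivalent to Fisher's exact for enrichment), computed as
`hypergeom.sf(k−1, N, K, n)`; the universe is the annotation's gene list
(parameterised — background choice is a genuine free parameter in this
kind of analysis).  Odds ratios apply a Haldane 0.5 correction when a 2×2
cell is zero.  BH adjustment is joint across testable sets; sets disjoint
from the universe are reported untestable rather than silently dropped.

Feature enrichment compares the observed fraction of DMRs overlapping a
feature class with the same fraction in n_draws random placements that
preserve each DMR's length and chromosome; empirical p =
(1 + #draws ≥ observed)/(1 + n_draws), ratio = observed / mean(null).
Random regions are not GC-matched here; GC matching lives in the motif
module where composition matters.

## Motif analysis

Regions of interest are DMRs ± 50 bp (clipped at chromosome bounds).
PWMs are probability matrices, pseudocount-regularised on load; scores are
log2-odds against the background composition, N bases contribute 0.  Both
strands are scanned (minus strand via the reverse-complement matrix),
with hits reported at plus-strand window starts.  The default score
threshold is 80% of the maximum attainable score, common PWM practice;
per-motif thresholds can be supplied.  Backgrounds are sampled uniformly
over the genome, length-matched, accepting candidates within ±0.05 GC of
their foreground region (tolerance doubling with a warning after 10,000
rejections).  Enrichment is region-level presence/absence (ZOOPS) with a
one-sided Fisher's exact test per motif and BH across motifs — a
deliberately transparent test construction rather than a motif-specific
scoring model; only known-motif libraries are scanned (no de novo
discovery).

## Co-expression

Detection is count ≥ 1 (panel-based spatial counts are already thresholded
detections; the threshold is a parameter).  The observed statistic is the
pair proportion x·y / C(g, 2) over the cell's detected genes — the "in a
cell" denominator; C(N, 2) is available by flag.  The random expectation
is the closed form m_A·m_B / C(N, 2): drawing g panel genes without
replacement, E[x_r·y_r] = g(g−1)·m_A·m_B/(N(N−1)) under the multivariate
hypergeometric, and dividing by C(g, 2) cancels g entirely.  A
resampling-based expectation (`expected_pair_proportion_mc`) is provided
for sensitivity analysis and is verified against this algebra in the
tests.  Cells with x·y = 0 have an undefined score and are excluded from
distributions; a continuity mode (x·y → 0.5) exists for sensitivity.
Group comparisons use the Wilcoxon rank-sum test: exact when both n ≤ 20
without ties, otherwise the normal approximation with tie and continuity
corrections; an all-tied comparison returns p = 1.  Marker sets must be
disjoint (shared genes can be dropped from all sets with a warning via
`make_panel`).

Spot purity keeps spots at or above the linear-interpolation percentile of
the target type's proportion with no other type's proportion strictly
greater (ties pass, so identical spots are all kept).  Pseudobulk profiles
sum n = 10 cells drawn uniformly without replacement, seeded.

## Synthetic data

The methylome generator emulates the replicate structure of a
transition-recovery WGBS design.  CpG positions come from two superimposed
homogeneous point processes — background (0.01 CpG/bp) plus CpG-dense
islands — because the smoother and the 300-bp split rule are sensitive to
clustered spacing.  Coverage is negative-binomial (mean 12, shape 5, near
the study's nominal WGBS depth); methylated counts are beta-binomial with
precision a+b = 100, giving replicate overdispersion so the t-statistic
denominator is non-degenerate (the real data's dispersion is unpublished;
100 is a free parameter, not an estimate).  Group means default to 0.5 so
planted shifts of either sign stay in range; all means are clamped to
[0.02, 0.98].  Planted DMRs are non-overlapping, contain ≥ 8 CpGs, and
alternate hyper/hypo; the recovered group's mean inside a DMR is
control + m·Δ with m configurable per DMR, directly encoding
"intermediate" (m < 1) versus "more extreme" (m > 1) memory as recoverable
truth.  A short chrX is always generated to exercise the autosome filter;
it is kept shorter than autosomes because it carries no planted signal.

What the generator does **not** model: read-level data (no FASTQ, no
bisulfite-conversion errors), non-CpG contexts, copy-number or mapping
artefacts, inter-chromosomal heterogeneity, and realistic genome-scale
CpG landscapes.  Passing recovery tests therefore show the pipeline's
filters and statistics behave as specified under the stated noise model,
not that the biological effect sizes of any particular tissue are
recoverable.

The genome generator plants exact consensus occurrences (recorded
position/strand, non-overlapping) into i.i.d. background sequence at a
stated GC; the cell-panel generator gives each cell Poisson counts with
elevated means at its own program's markers, and transition cells draw
elevated counts from both programs of a designated pair.  All generators
are pure functions of (config, seed).

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline on a
5 Mb autosome (~50,000 retained CpGs, 40 planted DMRs) for recovery and
null calibration, 2 Mb three-group simulations for memory classification,
100 kb genomes × 20 seeds for motif recovery, and 100,000-draw
Monte-Carlo checks of the co-expression closed form — sizes chosen so a
full run completes in a couple of minutes on one CPU while leaving every
statistic comfortably away from small-sample degeneracy.

## Known limitations

- The local-correction trend estimator (binned running median) follows the
  cited method's *intent* (remove coarse drift); the original's exact
  estimator is not published in the source text, so the halfwidth and
  estimator are exposed as parameters.
- Whether the 10% difference cutoff in the original analysis used raw or
  smoothed means is unstated; smoothed is the default here, raw is a flag.
- The motif enrichment deliberately replaces a motif tool's internal
  background and scoring machinery with a transparent ZOOPS/Fisher
  construction; absolute p-values are not comparable to that tool's,
  rankings of strong signals are.
- `fraction_of_union ≤ min(fraction_of_a, fraction_of_b)·(|A|+|B|)/|A∪B|`
  and similar set identities hold by arithmetic and are asserted in tests,
  not re-derived at run time.
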