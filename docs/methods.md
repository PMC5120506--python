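# Methods

## Data model and assumptions

The package targets proportion-scale methylation (beta values in [0, 1])
measured on a tiling array whose probes are grouped into genomic regions
(dense runs, inter-probe gaps ≤ ~100 bp, regions ≥ 1 kb apart) plus a set
of CpG-free control probes that should read as unmethylated.  Samples come
in monozygotic twin pairs discordant for a binary phenotype; each pair has
exactly one case and one control.  Batches are never compared: the model
constructor rejects mixed-batch cohorts and the pipeline loops over batches
independently, so batch separation is structural, not conventional.

Modeling runs on M-values, M = log2(p/(1−p)) with p clamped to
[eps, 1−eps] (eps = 0.01 by default, configurable): the logit transform is
closer to homoscedastic than the bounded proportion scale.  Region
*statistics* (avg, max, area.raw) are nevertheless reported on the
proportion scale, which is what a reader of a DMR table expects
("percentage methylation difference").

## Probe-level paired model

For probe j with M-value vector y over the 2n samples,

y = pair-block γ + phenotype β_j + (optional covariates) + ε.

Pairing enters as one indicator per pair (a fixed-effect block) rather
than explicit differencing: the two are algebraically equivalent without
covariates (β̂_j is exactly the mean within-pair M difference, a property
the tests assert to 1e-10) and the block form admits per-sample covariates
naturally.  All probes share one design matrix, so the fit is a single
matrix product; two-sided p-values use the t distribution with
n_samples − rank residual degrees of freedom.

The cell-proportion covariates are the triple (neutrophil, NK, CD4+CD8).
Because QP-estimated proportions lie on the simplex, the triple sums to
exactly 1 and is collinear with the pair-block intercept; the model
detects this and drops the last column, which changes nothing about the
fit but keeps the design full rank.  Covariate adjustment on the M scale
absorbs cell-composition signal only approximately (the mixture is linear
on the proportion scale and the logit is not); the exact-absorption
property is therefore tested on the proportion scale, where it holds to
solver precision.

## Bump hunting

Per-probe coefficients are smoothed within regions before thresholding.
The default smoother is a tricube-weighted local linear fit over the
k = max(3, ceil(span·n)) nearest in-region probes (span 0.3); regions with
fewer than 4 probes use a centered running mean (window 3, truncated at
edges).  Smoothing never crosses region boundaries.  The smoother is
hand-written (numba-compiled when numba is importable, with an identical
pure-python fallback) because it runs inside every bootstrap iteration —
thousands of calls per analysis — where a generic LOESS routine would
dominate the runtime.

Candidates are maximal runs of consecutive probes with |smoothed| ≥ cutoff
(inclusive comparison at the boundary), constant sign, inter-probe gaps
≤ max_gap, length ≥ min_probes.  Defaults: cutoff = 0.995 quantile of the
|smoothed| distribution, min_probes = 3, max_gap = 300 bp.  These three
defaults are package choices — reasonable for ~10-probe regions at ~5 000
probes genome-wide; at much smaller array sizes the 0.995 quantile can fall
*inside* a genuine bump and truncate it, so for small custom designs an
absolute cutoff (`cutoff_abs`) is preferable.

## Permutation filter

For a candidate with probe set S, each sample is summarized by its mean
(and separately its maximum) methylation over S; the statistic is the mean
over pairs of (case − control) summaries.  The null flips each pair's
labels independently: all 2ⁿ assignments are enumerated whenever 2ⁿ ≤ cap
(default cap 4096, i.e. up to 12 pairs), otherwise cap Monte-Carlo
assignments are drawn with the identity included.  The two-sided p-value
counts assignments with |statistic| ≥ |observed|, identity included, so
exhaustive p-values are multiples of 1/2ⁿ and never zero.

A candidate is excluded iff permuted p > 0.1 for **both** summaries (the
conjunction rule).  The filter targets outlier-driven candidates: one
extreme pair among n−1 null pairs produces the same |statistic| under
every flip of the null pairs, so its permuted p is ~1 regardless of how
large the outlier is.  The final call instead requires
min(p_avg, p_max) < 0.1 (strict); at the attainable granularities (1/32,
1/128) no p equals 0.1 exactly, so the boundary convention never bites.

## Bootstrap FWER, stratified by probe count

Null data are generated by a residual bootstrap under the no-phenotype
model: fit the pair-block-only model, resample residual *columns* with
replacement, add back the null fitted values.  Resampling whole columns
preserves the cross-probe correlation structure; an alternative
within-pair label-permutation scheme (`scheme="pairflip"`) is provided.
Each of the B iterations re-runs the entire candidate pipeline —
smoothing, cutoff (the quantile is re-resolved on the null data),
minimum-run filtering, and the permutation filter.  Surviving null
candidates contribute (nprobes, avg, max, area.raw) to the pool.

Raw area-based ranking favors long candidates, so the FWER is estimated
within probe-count strata: by default the quartiles of the null
candidates' probe counts define the bins, and bins holding fewer than 20
null observations are merged into their nearest neighbor (fixed edges can
be supplied instead).  For candidate statistic s in stratum g,

FWER_s = #{iterations whose max |s| over null candidates in g ≥ |s_obs|} / B,

with iterations contributing no in-stratum candidate counting as maximum
0.  FWER = 0 therefore means "below resolution, < 1/B" and is flagged as
such rather than replaced by a pseudo-count.  Absolute values are used in
the comparison (the signed alternative would halve the null at no clear
benefit for a two-sided question).  A DMR passes when FWER ≤ 0.10 for at
least one of the three statistics; the summary table also carries a
looser report-level column at 0.20.  B defaults to 2000 for production
runs; the test-suite and acceptance profiles use B = 200, which resolves
FWER to 0.005 and keeps a full 100-replicate calibration study inside a
few minutes on one CPU.

## Deconvolution

Marker discovery runs the same smoothing/run machinery on one-vs-rest
mean differences of the sorted-cell panel, with an absolute cutoff of 0.1
on the proportion scale and a 2-probe minimum (sorted-cell contrasts are
large; the quantile cutoff would be needlessly data-dependent).
Overlapping candidates from different contrasts are merged into their
interval union.  The reference entry B[k, m] is the mean over replicates
of cell type k of the mean methylation over marker m's probes.  Marker
informativeness is the one-way ANOVA F statistic of the marker's
per-sample means on cell-type labels; the top k (default 300) are kept,
ties broken by genomic order.

The per-sample QP, min ‖x − Bᵀw‖² subject to w ≥ 0 and Σw = 1, is solved
exactly: for each of the 2^K − 1 supports the equality-constrained KKT
system is solved and the feasible solution with the smallest objective is
returned.  The optimal active set is among the enumerated supports, so
this is the global optimum with no iterative-solver tolerance; it is
practical for panels up to ~10 cell types.  Markers missing in a sample
are dropped pairwise and the QP re-solved on the survivors; a sample with
fewer usable markers than cell types is rejected as underdetermined.

## Preprocessing

QC rules: probes with quality strictly below 80 are discarded; control
probes' median must sit below the non-control median per sample; a sample
whose correlation with *every* other sample falls below the threshold
(default 0.8) is flagged (a sample is bad when nobody vouches for it —
flagging on the minimum correlation would let one bad sample flag the
whole cohort); when a raw untreated channel is available, samples whose
untreated log-intensity SD is an outlier (z > 3) are flagged.  Each
discarded probe or flagged sample cites exactly one rule.

Within-sample normalization fits a LOESS baseline (statsmodels lowess,
span 0.3, 2 robustness iterations) of the log-ratio on average
log-intensity over the control probes, subtracts the interpolated baseline
from all probes and re-centers so the control mean is exactly zero; it
requires ≥ 20 control probes.  Between-sample normalization is subset
quantile normalization anchored on the controls: the reference is the
cross-sample mean of sorted control values; control probes are mapped by
rank (stable within ties) so every sample's sorted control vector equals
the reference exactly and the step is idempotent to machine precision,
while non-control probes go through the monotone interpolant (anchored at
(0,0) and (1,1), ties averaged).  Rank-by-stable-order tie breaking means
two exactly-equal control values can map to adjacent distinct reference
values; order is never reversed.  The two-channel path estimates
p = treated/(treated + untreated); probes with zero total intensity become
missing and are reported.  Probes missing in any retained sample are
excluded from modeling (complete-case policy).

## The synthetic generator

`twindmr.simulate` emulates the study conditions end to end: a design of
n_regions regions with 8–12 probes at 30–100 bp spacing (uniform), ≥ 1 kb
between regions, ~5% control probes, qualities Uniform[60, 100]; a
sorted-cell panel over (neutrophil, CD4T, CD8T, CD56NK) in which each
marker region's designated cell type deviates from a shared baseline by
≥ 0.2; and twin cohorts where each sample's methylation is
Σ_k w_k μ_k(j) + phenotype·delta·1[j ∈ planted] + pair-shared
Normal(0, 0.02²) + Normal(0, noise_sd²), clipped to [0, 1], with
w ~ Dirichlet(8, 5, 3, 2) (roughly blood-like: neutrophil-dominated).
Control probes read Uniform(0.02, 0.10) plus noise.  An optional
`proportion_shift` adds a phenotype-linked composition change; an optional
per-batch intercept exists but makes no claim of realism.  The stylized
two-channel emission (treated = p·S, untreated = (1−p)·S,
S ~ LogNormal) exists only to exercise normalization and round-trips the
estimator exactly.

What the generator does **not** emulate: scanner physics, dye bias,
McrBC fragment-size effects, CpG-density-dependent probe behavior,
spatially correlated noise, or realistic batch structure.  Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under clipped-Gaussian noise with mixture structure — not
performance on real CHARM intensities.  Clipping at [0, 1] (rather than
logit-normal noise) preserves the planted delta exactly away from the
boundaries, which is what the exactness oracles need; near-boundary
probes attenuate.

## Numerical and degenerate-case choices

* Permutation comparisons use a 1e-12 relative tolerance so exact
  sign-symmetric ties count as ties in floating point.
* `max` is the *signed* per-probe difference of largest magnitude, so
  hypomethylated DMRs keep their negative sign; ties take the first probe.
* Zero-variance paired differences in the proportion t-test give p = 1
  (all-zero) or p = 0 (constant non-zero shift).
* A degenerate constant sample in between-sample normalization maps to
  the reference median with a warning.
* Single-sample QC skips the correlation rule with a warning.
* A failed bootstrap iteration is recorded as empty (it still counts
  toward B) with a warning.
* All randomness flows through explicit integer seeds; identical seeds
  give bitwise-identical pipelines (asserted in the test suite).

## Known limitations

* Cell-composition correction on the M scale is approximate (see above);
  the package mirrors common practice rather than fitting a nonlinear
  mixture model.
* The probe-quality score is treated as a supplied number in [0, 100];
  no attempt is made to reproduce platform-internal quality metrics.
* CpG-density / fragment-bias correction terms of the original array
  pipeline are not implemented (no raw data to calibrate them against).
* FWER stratification ("similar number of probes") has no canonical
  definition; quartile bins with thin-bin merging are a pragmatic default
  and configurable fixed edges are provided.
* Reference-free deconvolution and cell types beyond the supplied panel
  are out of scope, as are random-effects meta-analysis and gene
  annotation beyond interval arithmetic.
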