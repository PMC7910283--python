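# Methods

This note documents the models and procedures implemented in `chromavice`,
the parameter choices that matter, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Coordinates and V-plot construction

All in-memory coordinates are BED-native 0-based half-open, regardless of
source dialect. A fragment's midpoint is `floor((start + end)/2)`; the
center of an even-length feature is `start + floor(length/2)`. Both floors
are arbitrary one-basepair conventions chosen for determinism.

V-plots count fragment midpoints around oriented features within
`flank = 500` bp, in position windows of `width = 10` bp sliding by
`step = 8` bp. Window starts run from `−flank` while `start ≤ flank −
width`, giving 124 windows `[−500,−490), [−492,−482), …, [484,494)` at the
defaults. Because `step < width`, consecutive windows overlap by 2 bp and a
midpoint in the overlap is counted in both windows — each window is summed
independently. The matrix also tracks the number of distinct fragments
binned; the two totals coincide exactly when `step == width`.

Features closer than 500 bp (center-to-center) to another feature are
excluded — both members of each violating pair — so neighbouring sites do
not write into each other's V-plot. Fragments are oriented by feature
strand (positions sign-flipped for `−` features; `.` is treated as `+`).
Fragment sizes are restricted to 41..500 bp. The lower cut follows the
size-iteration convention starting at 41 (prose saying "smaller than 40 bp
are excluded" would admit 40; the explicit loop bound wins). The upper
bound is configurable; 500 bp keeps the size axis at L = 460 values, i.e.
the maximum size minus 40.

## Normalized information, CIE, f-VICE

Per window, the fragment-size count vector is summarized by

    I(x) = 1 − H(x) / H_max,

with H the plug-in (maximum-likelihood) Shannon entropy and
`H_max = log L` for L possible sizes. Natural logs are used for both; the
ratio is base-invariant. `I = 1` for a point mass, `0` for uniform, and
NaN (undefined) for an empty window. No shrinkage or bias-corrected
entropy estimator is applied — the plug-in estimator's coverage bias is
exactly what the expected-information normalization cancels.

The expected profile permutes fragment-size labels against position labels
over the pooled fragment list (pooled, not per feature: the permutation is
applied to the single concatenated list), rebuilds the matrix, and
recomputes I. One permutation is the default; `n_permutations > 1`
averages profiles. `CIE = log2(I_obs / I_exp)` per window, with both
informations floored at 1e-6; windows undefined on either side get CIE 0
and are flagged, so positional sums remain well-defined.

f-VICE sums per-bp CIE over landmark intervals: positions −25..25
(TF-proximal) plus half of (−70..−50 and 50..70, TF-adjacent). CIE is
computed per 10-bp window, so per-bp values at integer positions are
obtained by linear interpolation of window-center values (nearest-window
assignment is available as an option; both agree on constant profiles,
where the unit profile yields 51 + (21+21)/2 = 72). Non-positive per-bp
values are clamped to zero before summing. The clamp condition is read as
"keep positive values, zero out non-positive": the literal side condition
(`> 1 → keep, ≤ 0 → zero`) leaves (0,1] unmapped and would discard most of
the signal.

Cross-motif normalization fits OLS `f-VICE ~ log10(m) + log10(f)` (m =
bound instances, f = fragments at bound instances) and divides residuals
by the CTCF residual, pinning CTCF at 1; a regression-free `raw/raw_CTCF`
ratio is also emitted. Sample QC correlates a sample's CIE profile with a
reference (e.g. ubiquitous CTCF-cohesin sites) over windows within 200 bp
of the center and passes at Spearman ρ ≥ 0.8.

## BMO

Per motif instance of one PWM: (1) count fragments overlapping
`[center−100, center+100)` whose Tn5 integration sites (first and last
fragment base) both fall outside the motif interval — in-motif
integrations are dominated by sequence bias; (2) count same-PWM instances
with centers within ±100 bp. The accessibility background NB is fitted on
instances outside accessibility peaks, resampling 10,000 instances 100
times and averaging the (mu, size) estimates (when fewer are available,
one fit on all of them, with a warning). The co-occurrence NB is fitted on
all instances. The flank is anchored at the motif center and both
backgrounds use the same counting rules as the foreground.

NB fitting maximizes the profile likelihood in the overdispersion `size`
(variance = mu + mu²/size) with the mean fixed at its MLE (the sample
mean), solving the score equation by bracketed root-finding; method of
moments is the flagged fallback, and variance ≤ mean (Poisson-like) data
yields a large flagged `size`. Upper-tail p-values are `P(X ≥ k)`
(survival at k−1, so p(0) = 1). The two p-values combine as Stouffer's
`z = (Φ⁻¹(1−p₁) + Φ⁻¹(1−p₂))/√2`, with boundary p-values clipped into the
open interval by a machine-epsilon margin. A consequence worth knowing:
an instance with zero co-occurring motifs has p₂ = 1 and receives a large
negative z₂, so isolated instances need overwhelming accessibility
evidence to be called — the predictor is strongest where binding sites
cluster. Benjamini–Yekutieli (valid under arbitrary dependence) adjusts
the combined p-values; bound means adjusted p < 0.05.

## Permutation statistics

**CIE asymmetry.** Statistic: log2 of summed positive CIE left of center
over right (window centers of exactly 0 would be excluded; the default
grid has none). Null: every fragment has a 50% chance of mirroring its
relative midpoint, with full CIE recomputation per resample. Both the
empirical p (with the +1 correction) and the normal-extrapolated p from
`z = (obs − null_mean)/null_sd` are computed; the normal p is used when a
Shapiro normality check on the null exceeds 0.01, the empirical p
otherwise. Type-I error is verified at ~5% on symmetric simulations.

**Rank-sum group enrichment.** Motifs ranked ascending by f-VICE
(midranks for ties); group rank sums compared against label permutations
that preserve all group sizes simultaneously; enrichment is
log2(observed / null median); groups under 5 members are dropped. The
reported p doubles the tail probability toward the observed direction —
the direction is chosen post hoc, and the undoubled directional tail
would reject true nulls at twice the nominal rate. Ties count into the
tail (with a small roundoff guard), keeping the test conservative. BH FDR
is applied across groups.

**Decile symmetry.** For k-mer f-VICE decile transition counts,
`X_ij = log2((sel_ij/Σsel)/(all_ij/Σall))` with a 0.5 pseudocount per
cell, diagonal ignored. The statistic `T = Σ_{i<j}(X_ij − X_ji)` is one
natural summary of up-versus-down bias (no canonical choice exists); the
null swaps each symmetric pair independently with probability ½, which
flips that pair's term, and the two-sided empirical p counts
`|T_null| ≥ |T|`.

**Other pieces.** TSS direction bias is the log2 ratio of nearest-TSS
occurrences left vs right of oriented motifs (+1 pseudocount, flagged,
when a side is empty); concordance of asymmetry directions uses the exact
two-sided binomial test at null 0.5 (minlike two-sidedness). The f-VICE
mixture is a 2-component Gaussian EM fit (10 seeded restarts) after
dropping motifs whose bound-instance count is in the lowest decile; the
higher-mean component is "high", split at posterior 0.5, with BIC reported
for the mixture and a single Gaussian. Quantile matching processes
covariates sequentially, computing 20-quantile bins on the union and
downsampling the larger set per bin. Canonical k-mers keep the
lexicographically smaller member of each reverse-complement pair and
exclude palindromes — (4096 − 64)/2 = 2016 for k = 6. F1 follows the
standard precision/recall form; AUPR integrates the precision-recall curve
trapezoidally; truth labels require full containment of the motif in a
ChIP peak.

## Synthetic data

`PhasingModel` draws fragment (position, size) pairs per feature. With
probability `theta` a fragment is structured: short (mean 80 ± 20 bp,
truncated to 41–120 bp — TF-protected) at the center, or mononucleosomal
(185 ± 25 bp) at phased offsets ±115 and ±305 bp (a ~190 bp repeat around
a ~30 bp protected core), with 15 bp positional jitter. Otherwise it is
background: uniform position, size drawn from the same marginal mixture —
so `theta` controls only the position-size coupling, not the marginal size
histogram, and `theta = 0` is an exact null for CIE. Mean f-VICE is
strictly increasing in `theta` (Spearman ρ ≈ 0.98 over a
{0, 0.25, 0.5, 0.75, 1} grid).

The BMO genome places single-PWM motif anchors at 1 kb spacing; each is
bound with probability 0.2. Bound instances are both accessible — NB
fragment counts with mu 20 versus background mu 2 (overdispersion size 5),
a ratio typical of sites inside versus outside peaks — and clustered: a
same-PWM partner is planted within ±100 bp with probability 1.0 for bound
and 0.05 for background instances. Clustering is part of the definition of
the bound class here, matching both the biology BMO exploits and its
combination rule, under which isolated instances are heavily penalized
(see above). Fragments (36 bp) are placed to overlap the ±100 bp window
with integration sites outside the motif, so flanking counts equal the NB
draws exactly; peaks cover anchors whose draw reaches the midpoint of the
two means, mimicking peak calling.

Not emulated: Tn5 sequence/GC bias, read-level noise, nucleosome
repeat-length heterogeneity, inter-chromosomal structure, diploid
genomes. Passing tests therefore demonstrate correctness and calibration
of the estimators under controlled coupling, not performance on any
particular real genome.

## Problem sizes and numerical choices

Simulation-based checks use: 10^5 fragments (100 features × 1,000) for CIE
null calibration; 1,000 anchors for BMO recovery; 200 replicates for each
type-I-error and null-FDR check (3·SE acceptance bands around the nominal
rates); 10 replicates per `theta` for monotonicity; permutation counts of
100–1,000 inside calibration loops and 50,000+ where a single test is
compared against an exhaustive oracle. These sizes make every Monte-Carlo
band sharp enough to detect miscalibration while keeping the full suite
fast. Entropy computations vectorize over the (size × window) matrix;
information floors (1e-6) only matter for pathological near-zero
information profiles. All randomness flows through
`numpy.random.Generator` seeds; every CLI run records its seeds in a
manifest.

## Known limitations

- CIE at a window reflects the pooled fragment list; motifs in dense
  clusters can dilute each other's signal (the 500 bp exclusion mitigates
  but cannot remove this for unselected feature sets).
- The f-VICE landmark intervals are tuned to TF-like V patterns;
  features organized at other distances (e.g. A-tract nucleosome
  exclusion) need the full CIE profile, not the scalar.
- The normal extrapolation of the asymmetry p assumes a normal null; the
  implementation checks this and falls back to the empirical p, which is
  bounded below by 1/(n_permutations + 1).
- BMO's co-occurrence term penalizes isolated motif instances by
  construction; on motif sets where binding does not cluster, the
  accessibility term alone must carry the call and recall drops.
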