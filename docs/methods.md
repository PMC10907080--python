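# Methods

This note documents the models, numerical conventions and design choices
behind `desnet`, and what the synthetic test bed does and does not establish
about real data.

## Data model and geometry

All volumes in one analysis live on a single `VolumeGrid` — a voxel lattice
plus an invertible 4×4 voxel-index→mm affine (MNI-style, 0-based indices,
coordinates at voxel centres). Grids are compared bitwise and mixing grids
raises before any computation; there is no implicit resampling, because a
silent resample would change sphere membership and voxel counts that the rest
of the pipeline treats as exact.

mm→voxel conversion rounds to the nearest index with halves away from zero.
The convention matters: an off-by-one voxel moves a seed sphere, and with it
every downstream count. Seed spheres include a voxel iff its centre lies
within the radius of the seed coordinate; radius 0 degenerates to exactly the
containing voxel, which also gives the single-voxel reading of the
concordance rate.

Defaults with units: seed sphere radius 3 mm (configurable — the right value
depends on acquisition resolution); points-only atlas kernel 5 mm;
significance level α = 0.05; 1000 permutations; hub percentile 90.

## Seed maps and group inference

A seed's signal is the mean time series over its sphere; per-voxel Pearson
correlations are Fisher-z transformed with |r| clipped to 1−10⁻⁶ so the
transform stays finite (self-correlation voxels then carry z ≈ 7.25 rather
than ∞). Zero-variance voxels contribute z = 0; a zero-variance seed signal
is an error, not a silent zero.

Group inference is a one-sample sign-flip permutation test with per-tail
familywise control via the maximum-statistic distribution: for each sign
pattern the per-voxel t statistic is computed, the maximum over voxels forms
the null, and a voxel is significant in a tail when the fraction of patterns
whose maximum reaches its observed t is at most α. When 2ⁿ ≤ n_perm all
patterns are enumerated (`p_mode="exhaustive"`, seed-independent and
subject-order invariant); otherwise n_perm patterns are sampled with the
identity always included, so p ≥ 1/n_perm. Degenerate voxels (zero variance
across subjects) get t = ±∞ by the sign of the mean, which makes the
identical-maps case behave correctly under enumeration. The two tails are
tested separately at α each — the familywise rate *per tail* is what the
procedure controls, and what the calibration test measures; the union of both
tails runs at ≈ 2α by construction.

## Network aggregation

Frequency maps count, per voxel, the percentage of a category's seeds whose
significance mask covers it; aggregation is exact integer counting, which is
why leave-one-out maps can be rebuilt by decrementing counts with voxel-exact
equality to a from-scratch rebuild. Bipartite labels resolve the two
polarities voxelwise: +1 where positive frequency strictly exceeds negative
(and is nonzero), −1 symmetric, 0 on ties and double zeros. Ties are left
unassigned deliberately: unassigned territory contributes no resection
importance, the conservative direction for clinical scoring.

Percentile thresholds (network cores, hub cutoffs, resection importance) are
computed with linear interpolation over the *strictly positive in-grey-matter*
values, everywhere through one shared helper, so hub selection and resection
scoring cannot drift apart. Computing percentiles over positive support
rather than all grey matter is a genuine design choice: including the empty
background would deflate every cutoff toward zero; the switch is exposed for
sensitivity analysis.

Coverage compares supports (any strictly positive value) within grey matter;
a zero-coverage atlas yields an undefined fold change (`None`), never
infinity.

## Leave-one-out validation

The concordance rate of a point against a frequency map is the mean of
freq/100 over the point's sphere; a point is predictive iff its positive
concordance strictly exceeds the negative one (ties fail, matching the strict
inequality in the classification rule). Pooled accuracy weighs every point of
every category equally; per-category accuracies are also emitted. Exceedance
curves are survival functions of the correctly classified points' positive
concordance on a uniform 101-point grid — presentational resolution only.

## Structure–function coupling

Streamline selection uses segment–sphere intersection (closest point on each
polyline segment), not vertex proximity, so the decision is independent of
the tractography step size; selection is invariant to orientation reversal.
Network membership is endpoint-based — "connecting to" is read as termination
— with whole-path intersection available behind a flag; endpoints falling
outside the grid belong to no network. Unbalanced designs average within
subject first, then across subjects.

## Single-subject normative model

Hub points are the stimulation points whose voxel frequency reaches the 90th
percentile of the positive map. Each subject is embedded as one feature per
hub: the Pearson correlation, over grey matter excluding the hub sphere
itself, between the subject's own seed map at that hub and the reference
cohort's mean map. Excluding the sphere removes the trivially shared
self-correlation component.

The scorer is a robust Mahalanobis distance (MinCovDet location/scatter)
minus the chi-square calibration radius √χ²₁₋α(p), so score > 0 is the
outlier side. Leave-one-out reference scores are computed with each subject
excluded from fitting; the strong-outlier cutoff is the median of the
outlier-side LOO scores (when no reference subject lands on the outlier side
the cutoff is the maximum LOO score, so nobody is labellable strong). The
mirror reading of that rule — median of the inlier-side scores — is
implemented behind `cutoff_rule="negative_median"`; the outlier-side median
is the default because it is the only reading under which "strong outlier"
is a strict subset of "outlier". A singular robust scatter is
ridge-regularized with a logged strength. Known limitation: with a few
hundred reference subjects the chi-square calibration of MCD distances runs
slightly liberal (observed outlier-side rates ≈ 0.06–0.11 at α = 0.05); this
is a property of the estimator, not a bug, and the calibration test bands it
accordingly.

The population comparison draws `sample_size` reference subjects with
replacement per iteration and computes Cohen's d (pooled unbiased SD,
direction reference minus clinical) against the fixed clinical sample;
iterations with zero pooled variance are excluded and counted. Defaults
follow the study design: 100 000 iterations of 66 subjects.

## Clinical statistics

Negative-response specificity deduplicates exact-coordinate repeats, drops
points outside grey matter (all counts logged), and compares the per-point
positive vs negative frequencies with the Wilcoxon signed-rank test, zeros
dropped before ranking (classic convention), exact null for n ≤ 25 without
ties and normal approximation otherwise. The rank-sum variant is computed and
reported alongside, because the two appear interchangeably in practice; the
paired signed-rank is the default as the statistically appropriate test for
paired readings.

Resection importance is the 90th percentile of a network's frequency over
the cavity's intersection with that network's bipartite compartment; an empty
intersection contributes 0 and a cavity touching exactly one compartment is
flagged perfect-bipartite (excludable from the correlation). Spearman
correlations use tie-corrected p-values.

Map similarity is Pearson's r over grey matter with significance from
variogram-matched surrogates: the map's values are permuted, smoothed with
k-nearest-neighbour Gaussian kernels at several scales (including double-pass
variants, smoother at short lags), and combined as a non-negative mixture
plus a white-noise nugget fitted by NNLS so the mixture's variogram matches
the source's at 25 equal-count lag bins (fit weighted by inverse variogram,
i.e. relative error, so the near-zero short-lag bins of smooth maps are
matched in relative terms). The two-sided p is (1 + #{|r_surr| ≥ |r|}) /
(n_surrogates + 1) — never zero, floor attained by self-similarity. Surrogate
quality is self-checked: the mean surrogate variogram stays within ±20% of
the source at every lag bin, and under independent maps the p-distribution is
uniform.

## Synthetic test bed

The generator plants exactly the structure the analysis assumes. Latent
networks are spherical loadings with a unit plateau (80% of the radius) and a
cosine taper to zero; the narrow taper keeps the loading > 0.5 territory and
the statistically detectable territory nearly coincident, which is what makes
planted-truth Dice scores a sharp diagnostic rather than a profile-shape
artifact. Anti-correlated pairs share signal through s_b = ρ·s_a +
√(1−ρ²)·η, giving the closed-form attenuated voxel correlation used as a test
oracle. Defaults — 24×28×24 grid at 4 mm, 40 subjects × 200 timepoints,
signal SD 1, noise SD 2, ρ_anti = −0.6, blob radius 14 mm — were fixed from
an SNR analysis: core seed correlations ≈ 0.2 and anti-correlations ≈ −0.12,
in the range typical of resting-state seed maps, with the full pipeline
running in about half a minute.

Patient cavities are two-lobed sphere unions, one lobe jittered around each
bipartite compartment independently, so the removed share of the positive and
negative network vary independently — the structure the outcome model
(score = intercept − slope·importance₊ + noise) assumes. Tractograms are
straight polylines with uniform step; planted endpoint fractions are exact by
construction.

What passing tests show — and do not. The synthetic cohort has Gaussian
white-in-time signals, no haemodynamics, no motion, no spatial noise
correlation, sharp-edged networks and spherical cavities. Recovery at the
stated SNR therefore validates the *machinery* (exactness of the permutation
and counting logic, calibration of the error control, correctness of the
geometry) and the qualitative behaviour of the method, not its effect sizes
on real scanners. Quantities that scale with anatomy — notably the
grey-matter coverage fold gain, which at desk scale is ~1.5–2× while
whole-brain analyses report order-of-magnitude gains — are scale-dependent
and only their direction is meaningful here.

## Problem sizes

Test and acceptance runs use the default synthetic scale above; the
familywise calibration uses 8 subjects on a 12³ grid over 200 replicates, the
normative calibration 200 reference plus 50 perturbed subjects on a 16×18×16
grid, and surrogate checks a 10³ grid (~550 in-mask voxels) with 25 lag bins.
These sizes were chosen so the complete suite exercises every stage end to
end in a few minutes on one CPU.
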