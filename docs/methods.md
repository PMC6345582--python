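# Methods

## Estimation core

All continuous MI quantities use the Gaussian-copula estimator: each variable
is mapped column-wise to standard-normal scores via Φ⁻¹((rank − 0.5)/n)
(average ranks on ties), after which MI is the Gaussian closed form from
covariance determinants.  This is a semi-parametric lower bound on the true
MI, invariant to strictly monotone marginal transformations.  Values are in
bits by default; a `base` argument gives nats.  An analytic small-sample bias
correction (digamma expansion of the expected log-determinant of a sample
covariance) is subtracted by default so that independent variables estimate
near zero; corrected estimates may be slightly negative and are stored
unclipped so permutation nulls stay centered.  Mixed continuous–discrete MI
uses class-conditional Gaussian entropies on the copula scores; binary×binary
quantities (visibility bits vs. behavioral contrasts) use plug-in contingency
MI, which is exact for that case.

Co-information is RED = I(F;D) + I(F;M) − I(F;(M,D)).  The joint term is
built by the chain rule, I(F;M,D) = I(F;D) + I(F;M|D), with I(F;M|D) the
class-weighted Gaussian MI of the globally copula-normalized variables within
each decision class; the three stored components therefore satisfy the
identity exactly (to float round-off), and RED reduces computationally to
I(F;M) − I(F;M|D).  Positive RED is redundancy (activity and decision share
feature information); negative is synergy.  A fully discrete plug-in route
exists for oracle checks on small alphabets.

The mapping stages (MI images over 20,480 pixels, representation and
redundancy matrices over voxel × time, and their permutation nulls) use
vectorized kernels computing the same quantities from sufficient statistics
via matrix products; they are tested to agree with the scalar estimators to
1e-10.  Columns with zero variance (never-revealed pixels, flat channels)
yield MI exactly 0 by convention.

## Stimulus sampling

The base image (reference 256 × 256 px spanning 5.72°) is decomposed into six
one-octave SF bands with upper cutoffs [128, 64, 32, 16, 8, 4] cycles/image
by a telescoping bank of zero-phase even-order (order-6) Butterworth
low-pass transfer functions: band k = LP(c_k) − LP(c_{k+1}), band 6 = LP(4)
including DC.  The telescoping construction reconstructs the input exactly
(sum of bands equals the image to machine precision) while keeping ≥ 90% of
a pure sinusoid's energy in its octave; the filter family and order are
arguments.  Bands 1–5 are sampled through masks of randomly centered
Gaussian apertures (σ = 0.13, 0.27, 0.54, 1.08, 2.15° respectively),
combined per band by pointwise maximum clipped to 1 (sum-then-clip is an
option); 60 apertures per trial, allocated across bands proportionally to
1/σ² (equal expected revealed area, at least one per band, remainder to the
finest bands): [46, 10, 2, 1, 1].  Aperture centers are uniform over the
image with no edge padding by default (padding is an option).  Masks are
downsampled to 64 × 64 by bilinear interpolation for all analyses.
Coordinates are 0-based, row-major, origin top-left.

## Statistical thresholds

Familywise error is controlled by maximum statistics: shuffle the labels (or
coefficients, or decisions — whatever the null breaks), recompute the full
statistic image, take its maximum, and threshold the observed image at a
percentile of the max distribution.  Defaults follow the analyses they serve:
10,000 permutations / 99.9th percentile for behavioral pixel maps, 200 / 95th
for representation, redundancy, and decision-MI matrices.  Percentiles use
linear interpolation between order statistics throughout (this makes
thresholds bit-reproducible).  Boundary conventions: a mask value exactly at
the 0.2 visibility threshold falls in the "no to low visibility" bin;
significance is strict inequality (statistic > threshold).

## Brain features

Because the full per-pixel × voxel × time coupling is intractable, MI images
are first computed against a reduced activity matrix.  The reduction is the
caller's choice; the provided helper is PCA across voxels of the amplitude
channel on a coarse time grid (an ICA reduction can be passed instead — any
linear reduction serves, since the images are only used to find spatial
structure).  NMF (scikit-learn, nndsvda initialization, coordinate descent,
fixed seed) factorizes the vectorized images; each component is thresholded
at 15% of its maximum and L2-normalized.  The number of components is a
config value (an elbow-rule helper `select_nmf_k` picks the smallest k whose
relative reconstruction-error improvement drops below 1%, capped at 25).
Feature classification uses strict percentile rules — two-class MI above the
75th percentile across features ⇒ diagnostic of that percept; three-class MI
below the 25th percentile ⇒ nondiagnostic; ties at a percentile stay
unclassified; if both rules fire, diagnostic wins with a warning.  Note the
strict-percentile construction can, by design, label at most roughly a
quarter of features per rule.  The cross-observer common basis uses cosine
k-means, implemented as Euclidean k-means on L2-normalized rows (equivalent
ordering on the unit sphere), best of n restarts.

## Dynamics

Max-MI courses take, per voxel, the maximum unthresholded MI over a feature
subset in fixed windows.  Onset is the start of the first window exceeding
the representation threshold, offset the end of the last, duration their
difference; divergence profiles use 10 ms windows (40 over 0–400 ms), while
onsets/offsets for regressions and the junction are computed at time-point
resolution (one window per 2 ms sample).  Wavefront regressions are
iteratively reweighted least squares with a Tukey bisquare weight
(statsmodels RLM); voxels more than 3 SD from the median onset are excluded
first; slope p-values use the asymptotic normal approximation.  Distances are
Euclidean from the earliest-onset voxel.  The divergence similarity is the
de-meaned dot product of the diagnostic and nondiagnostic voxel vectors per
window, against a null that shuffles the entries of the two vectors
independently (joint shuffling is an option; the independent default is the
more conservative null for pattern alignment), with bounds at the 0.625 and
99.9375 percentiles (two-tailed 0.05, Bonferroni over 40 windows).  The
junction is the latest offset among nondiagnostic voxels whose distance
exceeds the 75th percentile.

## Behavior representation

Redundancy matrices apply RED per (diagnostic feature, voxel, time) cell;
the permutation null shuffles decisions with features and activity fixed
(class sizes, hence bias terms, are permutation-invariant).
Decision-specific redundancy restricts trials to one two-class contrast
before any computation.  Representational complexity counts, per voxel, the
distinct features with at least one significant cell in each of five
contiguous 20 ms windows spanning 120–220 ms ("evenly distributed" is
interpreted as equal-width contiguous; width is configurable); a separate
`median_complexity` utility aggregates across observers so single-observer
runs stay first-class.

## Synthetic observer

The generator plants everything the pipeline is supposed to find, at desk
scale (defaults: 64 × 64 masks, 5 bands, 500 voxels, 2 ms steps over
0–400 ms, 1,500 trials).  Six features with disjoint disk supports sit in the
first three SF bands — two diagnostic of "the nuns" (band 1), two of
"Voltaire" (bands 2–3), two nondiagnostic — reflecting that only the finer
bands carry localizable information at the aperture scales used (features
planted in the coarsest bands are intrinsically smeared by the large
apertures and were not resolvable, so the reference observer keeps all
supports in resolvable bands).  Decisions follow a noisy evidence race:
per-percept evidence is the equal-weight mean of the standardized visibility
of that percept's features plus Gaussian noise (SD 0.7, a reliable observer),
and the argmax percept wins unless it falls below a "don't know" threshold
calibrated as the 25%-quantile of the max evidence (so the "don't know" rate
hits its target exactly).  There is no behavioral model to inherit — the
original measurements were of humans — so this rule is a stand-in chosen for
transparency.

Activity: each wavefront voxel encodes one nondiagnostic *and* one
diagnostic feature from the same distance-graded onset (60–120 ms at
0.5 ms/mm), through a shared half-cosine envelope (boxcar optional); the
nondiagnostic copy is truncated at the planted junction (150/170/190 ms)
while the diagnostic copy persists to ~378 ms.  The shared envelope keeps the
two voxel patterns proportional before the junction — which is what makes the
divergence statistic's collapse sharp — and the truncation makes offsets
crisp.  A 12-voxel integration group accumulates the four diagnostic features
at staggered onsets (135, 158, 181, 188 ms, common offset 198 ms, 1.8× gain
as a convergence zone), producing a representational-complexity ramp that
peaks in window 4 of the 120–220 ms span.  Gains are 1.5 (SNR 1.5 per sample
at envelope peak against unit noise); the gradient channel is the discrete
temporal derivative of the final amplitude (noise included).  Coefficient
cross-talk between features sharing a sparsely sampled band is a real
property of Bubbles sampling; it was measured and kept below |ρ| ≈ 0.1 by the
band placement above, so it does not masquerade as shared representation in
the divergence null.

What the generator does **not** emulate: volume conduction / field spread,
spatially correlated noise, oscillatory dynamics, eye movements, learning
across sessions, or any biophysical forward model.  Passing tests therefore
demonstrate that the estimators and procedures recover planted structure
through the full analysis chain at realistic trial counts — not that real
recordings would yield these effect sizes.

## Problem sizes and numerical choices

Test and acceptance runs use reduced sizes chosen to keep the full suite in
the minutes range: FWER calibration on 32 × 32 maps (500 datasets, 500
trials, 200 permutations); template recovery at 2,000 trials; feature
recovery at 1,500 trials × 500 voxels; dynamics and complexity recovery on
64-voxel observers at 500 trials with 50 permutations, 20 seeds.  Voxel
counts are input dimensions, never constants.  Determinism: every stage
draws from a named substream of one top-level seed; reruns are bit-identical
(hash-verified in the suite).  Degenerate inputs are rejected with named
errors (constant columns, empty contrast classes, singular covariances,
sub-minimum class sizes); zero-variance mapping columns yield MI 0 rather
than an error.

## Known limitations

GCMI is a lower bound: it captures monotone dependence only, so strongly
nonmonotone encodings would be underestimated.  The chain-rule joint term in
RED inherits the class-conditional Gaussian assumption.  The junction marker
is biased late by up to one time step because the gradient channel extends a
representation by one sample past its amplitude offset.  NMF is a local
optimizer: component quality depends on k and initialization (both seeded
and configurable), and recovered features are identified only up to the
Hungarian matching used in reports.
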