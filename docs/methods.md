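# Methods

This note records the modeling and numerical choices behind `dgcnet`, what the
synthetic validation scenarios do and do not emulate, and the known
limitations.

## Dynamic MVAR estimation

The recursive estimator is recursive least squares (RLS) with exponential
forgetting, run per time point over all targets jointly: with regressor vector
`x_t = [y(t−1), …, y(t−p)]`, gain `g = P x / (λ + xᵀP x)`, coefficient update
`W ← W + g (y_t − Wᵀx)ᵀ`, and `P ← (P − g xᵀP)/λ` with `λ = 1 − F`. The
inverse-correlation matrix is initialized to `δ·I` with `δ = 1000` and
re-symmetrized each step against round-off drift; a non-finite or non-positive
gain denominator triggers a regularized restart (`P ← δ·I`) with a
`RuntimeWarning`, never a silent NaN. This filter is the
exponentially-weighted special case of the Kalman-filter family often cited
for time-varying autoregressions: state-transition identity, no process
noise, observation noise absorbed into the gain normalization.

* `F = 0` (λ = 1) is accepted as the no-forgetting limit; the final-time state
  then equals a growing-window OLS fit up to the `1/δ` ridge term (≈1e−7 at
  the sample sizes used in tests). This limit is also the natural setting for
  the sequential group-initialization pass, which chains both `W` and `P`
  across runs so the chained state is an all-runs estimate.
* The intercept is absorbed by mean-centering each series before filtering;
  the per-column means are recorded. The static fit reconstructs the
  intercept from the means.
* The forgetting grid is `{0.01, 0.02, 0.05, 0.10, 0.15, 0.20}`. The
  selection objective pools the squared one-step-ahead (a priori) prediction
  errors over regions into a per-time energy and minimizes its variance over
  post-burn-in times. Pooling over regions (rather than per-region variances
  averaged) is our choice; the two differ only in weighting.
* Steady-state coefficient noise scales roughly as `√(F/(2−F))` per
  coefficient (≈0.10 at F = 0.02, ≈0.16 at F = 0.05 for unit innovations).
  This noise floor, squared twice on the way to the symmetrized connectivity
  `C = DGC_ij² + DGC_ji²`, sets the surrogate threshold th₀ and hence which
  true couplings are detectable: a coupling `k` is reliably separated from
  the null when `k²` exceeds a small multiple of the null DGC level
  (≈0.04 at F = 0.02, ≈0.1 at F = 0.05).
* Burn-in: the first 50 samples of the DGC series are discarded by default
  (filter convergence), matching the transient we observe from zero and
  group-level initializations alike.
* BIC order selection uses the multivariate Gaussian likelihood with penalty
  `R²·p·ln(T−p)`; ties break toward the smaller order.

## Surrogate null and distance transform

Phase randomization draws independent uniform phases per region and frequency
bin (DC and Nyquist untouched), preserving each region's amplitude spectrum
exactly while destroying cross-region temporal structure. The null statistic
pools off-diagonal `C` values across connections and post-burn-in times from
all surrogates; th₀ is a single pooled percentile (95th by default).
Per-connection thresholds are available (`pooled=False`) but are not the
default: the downstream calibration consumes one number.

The reversed-S transform `D = 1/(a + b·f^C)` is calibrated by `a = 1` and the
anchor `D(th₀) = 0.5`, giving `log f = −log(b)/th₀`. `log f` is the
authoritative stored parameter (at the published constants `f = 5¹⁰⁰ ≈ 8e69`,
not representable usefully in linear scale); evaluation is
`expit(−(log b + C·log f))`, exact for any finite `C ≥ 0`. `b = 0.2` is kept
as published; the companion "steepness < 0.02 at C = 0" condition quoted
alongside those constants is not internally consistent with them (the
derivative at 0 is orders of magnitude larger), so we honor the explicit
constants and the anchor, and do not attempt to reproduce the steepness
derivation. Diagonals are forced to zero after the transform, making each
per-time matrix a symmetric, bounded (`≤ 1/(1+b)`), zero-diagonal distance
matrix.

Note one consequence of the double squaring (`DGC = k²`, then `C ~ DGC²`):
the transform is extremely sharp around th₀, so moment-to-moment sampling
noise makes individual connections flicker across the threshold. The level-1
smoothing below is what integrates that flicker out.

## Three-level clustering

**Level 1.** The cited evolutionary-clustering scheme ("cluster at time t
taking recent results into account") is realized as exponential smoothing of
the distance matrices, `S_t = α·S_{t−1} + (1−α)·D_t`, followed by static
average-linkage agglomerative clustering per time point. Smoothing the input
rather than the memberships keeps the procedure testable against closed
forms (the step response is exactly geometric) and gives the same qualitative
behaviour: larger α yields temporally stabler partitions (a property the test
suite asserts as monotone label-volatility). α is selected on a grid by
one-step-ahead prediction error `Σ_t ‖S_{t−1} − D_t‖²_F`, the degenerate
single-parameter form of an information criterion. A single global α is used;
per-time adaptation of the forgetting weight is not implemented. Labels are
canonicalized per time point (cluster containing the lowest region index
first); identity across time is established only by the level-2 distance.
The default cluster count is 6, following the prior community estimate for
directed resting-state networks; silhouette-based selection is available.

**Level 2.** The partition distance is the greedy maximal-overlap label
matching: repeatedly match the cluster pair (one per partition) sharing the
most regions, give both a fresh common label (ties: lowest cluster index in
the first partition, then the second), and when the maximal overlap reaches
zero give every remaining cluster its own label; the distance is the count of
regions whose labels disagree. This greedy matching is *not* an optimal
assignment: on random partition pairs it exceeds the optimal-matching
distance in a few percent of cases, and it is not invariant to tie-break
order in general. It also does not satisfy the triangle inequality in all
cases; the test suite audits rather than assumes these properties. It is kept
because it is the procedure that defines the method. Identical consecutive
partitions are deduplicated before the pairwise distance matrix is built
(the T×T matrix is reconstructed from unique rows), which makes the T ≈ 10³
regime cheap. States come from average-linkage clustering with the state
count maximizing the mean silhouette over k ∈ [2, min(20, T−1)]; an
all-identical partition sequence returns one state with a warning.
Dwell-time standard deviations use the population convention (divide by n),
as a descriptive summary. The dominance threshold scans a bin-width-5
histogram of occurrence counts, starting after its first nonempty bin, for
the first empty bin followed by another empty bin ("value zero and zero first
difference"); counts above that bin edge are dominant. If no such gap exists
below the maximum count there are no dominant states (warning).

**Level 3.** Dominant level-2 agents are vectorized as the row-major
off-diagonal entries of their distance matrices and clustered by weighted
k-means (weights = occurrence times): weighted k-means++ seeding, Lloyd
iterations with weighted centroid updates, empty clusters re-seeded at the
farthest point, best of 10 restarts; the weighted objective is asserted
non-increasing every run, and integer weights reproduce unweighted k-means on
a replicated dataset exactly. The silhouette used for selecting k is
weight-averaged by default (unweighted available). The dominant group
configuration is the cluster with the largest summed weight, and each cluster
is represented by the member agent nearest its centroid.

## Simulator (validation conditions)

All scenarios are lag-1 vector autoregressions on 12 regions with identity
innovation covariance and 3×3 diagonal blocks. Diagonal coefficients are
uniform on [−0.5, −0.1] (negative: low-pass dynamics, as in slow hemodynamic
signals); within-block off-diagonal coefficients have random sign and
magnitude uniform on [0.3, 0.5]. The magnitude is bounded away from zero
deliberately: a validation scenario must have an identifiable ground truth,
and a region coupled to its block with near-zero coefficients carries no
recoverable membership signal — with couplings below ≈0.2 the partition is
unrecoverable in principle at the estimator's noise floor, regardless of the
clustering. If a draw is unstable the matrix is rescaled to spectral radius
0.95 (preserving sparsity and diagonal sign). The sinusoidal scenario
modulates every nonzero entry by `1 + 0.5·sin(t/100 + φ)` with independent
phases (period 200π samples) and globally rescales if any instantaneous
radius exceeds 0.95; the shifting scenario rolls the matrix by one row and
one column every 200 samples. Initial states are drawn from the stationary
distribution of the t = 0 model, so realizations start in steady state.

What the simulator does **not** emulate: hemodynamic convolution and its
lag-confounds, measurement-noise autocorrelation, non-identity innovation
covariance (instantaneous correlation), region-count scale (12, not ~164),
and session/subject heterogeneity. Passing the validation suite therefore
demonstrates the estimator and the clustering recover the kind of structure
they are designed for — not that fMRI preprocessing artifacts are handled.

The synthetic behavior generator draws DEC/SEC from log-normal distributions
(nonnegative, right-skewed, like empirical connectivity metrics), composes
the score linearly plus Gaussian noise, and duplicates each subject's metrics
and score across its two runs. Duplication is exact so that the zero-noise
case is an exact linear system.

## Behavior GLM

Per (test, connection) cell, the two regressors and the behavior vector are
mean-centered and the no-intercept two-regressor OLS is solved in closed form
(centering the behavior does not change the coefficients — centered
regressors are orthogonal to the constant — but keeps the residual variance
and hence the z-test meaningful). Coefficients are tested with `z =
estimate/SE` against the normal reference; the Bonferroni threshold is
`family α / number of tests`. Under the duplicated-score design these z-tests
deliberately do not correct for the run-level dependence (each score enters
twice), which makes them anti-conservative by about √2; this mirrors the
original design and is documented rather than fixed (the calibration test in
the suite therefore uses independent observations). Cells with
|corr(DEC, SEC)| > 0.999 (or a singular Gram matrix) are flagged and skipped,
and excluded from both numerator and denominator of the explained-variance
grand means. Regressors are centered but not scaled by default; a
`standardize` flag exists, and the symmetric α = β construction yields
`frac_dec = 0.5` only under standardization. Explained-variance means are
grand means over observations and all retained cells.

## Problem sizes in the test suite

The validation suite runs the simulator at T = 1000, R = 12 with 20
replicates for the constant-scenario statistics, 3 seeds for shifting-scenario
partition recovery with 20 surrogates for the null, and 50-replicate
Monte-Carlo checks for the two model-selection criteria at reduced dimensions
(R = 6, T = 600); the end-to-end pipeline test uses T = 400 with 10
surrogates. These are the package's chosen desk-scale conditions; the
published-scale analogues (10³ replicates, 10³ surrogates, 164 regions) run
through exactly the same code paths via the configuration.

## Known limitations

* RLS-with-forgetting is a causal filter: estimates lag abrupt coefficient
  changes by roughly `1/F` samples, and no forward–backward smoothing is
  offered.
* One pooled th₀ treats all connections as exchangeable under the null;
  connections with unusual spectra would deserve the per-connection option.
* The greedy partition distance is non-metric in edge cases (see above).
* Weighted k-means inherits k-means' convexity assumptions in agent space;
  restarts mitigate but do not eliminate local minima.
* The behavior GLM is per-cell OLS, not a mixed model; run-level dependence
  is acknowledged, not modeled.
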