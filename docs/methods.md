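# Methods

This note documents the statistical models implemented in `nirerr`, the
assumptions behind them, the synthetic data generator used to validate the
chain, and the numerical and design choices that were genuinely open.

## ASCA decomposition

For a design with factors F₁…F_k and selected two-way interactions, the
n × p spectra matrix X is grand-mean centered, X_c = X − 1m′, and split
additively:

    X_c = Σ_F X_F + Σ_{F×G} X_{F×G} + E

X_F assigns to each row the mean of X_c over its level of F; X_{F×G}
assigns the F×G cell mean minus both main effects; E is what remains. For
balanced designs these matrices are mutually orthogonal, so the squared
Frobenius norms (SS) are exactly additive and the percentage table sums
to 100. ANOVA's usual assumptions apply (independent rows, additive
effects, within-cell homoscedasticity); PCA of an effect matrix
additionally assumes linear structure across channels.

Mildly unbalanced designs (typically after outlier removal) are handled
with the same cell-mean estimators under a warning; SS additivity is then
only approximate, and the report says so rather than silently renormalizing.

**Permutation test.** The tested factor's level labels are freely permuted
over rows (for an interaction, the pair of label columns is permuted
jointly while all other design columns stay attached to their rows) and
the effect SS is recomputed under the same cell-mean scheme;
p = (#{SS_null ≥ SS_obs} + 1)/(n_perm + 1), so p is never exactly 0. This
is the simplest exchangeability-based scheme; permuting raw labels for an
interaction (rather than permuting residuals after removing main effects)
is a documented approximation. The default is 2000 permutations with
significance at p < 0.05.

**Sub-models.** Loadings are right singular vectors of the effect matrix;
effect scores (the projection of the effect matrix) collapse to one point
per level, so the default visualization output is the residual-augmented
scores (X_F + E)·P, which restore the within-level spread against which
level separation must be judged. Explained variances are singular values
squared over the effect SS. Level centroids are means of augmented scores.

## Replicate-based error estimation

Errors are estimated from experimental replicates: E's row i is spectrum i
minus the mean of its replicate group. The default grouping is the
sample × session × background-timing cell — replicates are only exchangeable
within a session and background regime — and pooling across cells gives

    Σcov = EᵀE/(n − g),    dof = n − g,

the classical pooled within-group covariance. Grouping is configurable and
recorded in outputs, since which factors must be pooled over is an
empirical question answered by the ASCA screening. rank(E) ≤ min(n − g, p);
both the dof and this rank bound are tracked separately (derivative edge
truncation can push p below n − g).

Σcor(i,j) = Σcov(i,j)/√(Σcov(i,i)Σcov(j,j)). Channels whose error variance
falls below 1e−12 times the maximum variance are excluded from Σcor (NaN
rows/columns, indices reported) instead of producing unstable ratios.

Preprocessing and replicate-mean subtraction do not commute, so error
surfaces for each preprocessing variant are computed by re-running the
pipeline on the spectra, never by transforming a raw error matrix.

## K index and imbedded correlation

With λ₁ ≥ … ≥ λ_p the eigenvalues of Σcor and EV_m = λ_m/Σλ,

    K = Σ_m |EV_m − 1/p| / (2(p − 1)/p).

The normalizer is the value of the numerator in the perfect-correlation
limit (EV = (1, 0, …, 0)), so K ∈ [0, 1], K = 0 iff all EV_m = 1/p
(uncorrelated) and K = 1 under perfect correlation. Small negative
eigenvalues of Σcor (round-off from rank-deficient E; Σcor is PSD in exact
arithmetic) are clipped at 0 before normalization.

When rank(E) = r < p, at most r eigenvalues are nonzero and K is minimized
by the equal-eigenvalue spectrum (r values of p/r): the imbedded
correlation

    K_min(p, r) = (p − r)/(p − 1).

`imbedded_k` always evaluates both routes — the closed form and the direct
K evaluation on the equal-eigenvalue spectrum — and asserts agreement to
1e−12. For the two supported instrument configurations this gives
K_min(236, 42) = 0.826 (45 pooled replicates minus 3 session means) and
K_min(74, 45) = 0.397 to three decimals. The meaningful diagnostic is the
distance K − K_min, not K alone.

**Image histogram.** Σcor entries map to gray levels g = (ρ + 1)/2 and are
binned into 256 equal-width bins on [0, 1] (8-bit image convention; the
bin count is configurable, the last bin right-inclusive so counts always
sum to the pixel count). The unit diagonal is histogrammed by default —
it is part of the image — with a flag to exclude it. Summary statistics:
mode location, skewness, and tail mass beyond configurable thresholds.

## Gross-outlier screening

PCA on the mean-centered matrix; a spectrum is flagged when it exceeds
either the Hotelling-T² limit, k(n−1)(n+1)/(n(n−k)) · F_{1−α}(k, n−k), or
the Q-residual limit (Jackson–Mudholkar approximation) at confidence 1−α.
Defaults: α = 0.01 and the smallest k reaching 90% explained variance.
Flags are returned, never silently applied; dropping rows is a separate,
explicit step so design-balance bookkeeping stays visible. On null
Gaussian data the combined flag rate approaches ≤ 2α.

## Preprocessing operators

- **SNV**: per-row centering and scaling to unit sample sd (n−1
  denominator, matching the pooled-covariance dof convention used
  throughout); invariant to per-row affine transforms with positive slope.
- **MSC**: per-row least squares x = a + b·ref (reference = mean spectrum
  by default), corrected row (x − a)/b; |b| below 1e−12 is an error.
- **Savitzky–Golay derivative**: default window 7, polynomial order 2,
  first derivative. The derivative scale is per channel-index step (the
  common chemometrics convention — downstream analyses interpret shapes,
  not units; a per-nm flag exists). Edge handling is truncation: the
  (window−1)/2 unsupported channels per side are removed from matrix and
  grid (236 → 230 with the defaults), which is also why near-zero-variance
  channel exclusion exists downstream.
- **Mean centering** is applied inside ASCA (grand-mean centering), not
  duplicated as a pipeline default; the pipeline order is user-specified
  and recorded in output provenance.

## Synthetic data generator

Each simulated spectrum is

    x_i = m_i·[baseline(sample) + session(session) + drift + supply] + a_i + ε_i

- **Baselines**: sums of Gaussian bands on the nm axis; two darker
  low-reflectance synthetic samples (mean levels 0.18, 0.26, as for
  colored curved pills) and two brighter ones (0.52, 0.60, compact white
  tablets).
- **Session offsets**: smooth random curves (low-order sinusoids), rms
  amplitude `session_offset_scale` (default 0.010 reflectance), fixed by
  the seed.
- **Background drift**: at the "session-start background" level only, a
  linear offset `background_drift_slope`·(replicate_order − 1) (default
  0.0015/step), emulating backgrounds growing stale over a session;
  per-sample backgrounds have no drift.
- **Power-supply offset**: a smooth curve (default rms 0.008) on the
  non-reference level, when that factor is configured.
- **Scatter**: m_i log-normal with log-sd 0.08, a_i Gaussian with sd 0.002.
- **Noise**: ε_i ~ N(0, Σ) with Σ = D^{1/2}RD^{1/2};
  R = w·R_smooth + (1−w)·R_band, R_band(i,j) = ρ^{|i−j|},
  R_smooth a squared-exponential kernel. Defaults ρ = 0.95, w = 0.3,
  kernel length 100 nm, sd profile = 0.004·(1 + Gaussian bump) — a
  scatter-dominated, strongly channel-correlated, heteroscedastic regime,
  the standard qualitative description of compact-solid NIR reflectance
  error. Σ is the generator's exposed ground truth, so estimator recovery
  is directly testable; under these defaults the estimated K values fall
  in the high-correlation range typical of raw miniaturized-NIR data and
  the raw > SNV > first-derivative ordering of K holds as a strong
  tendency.
- **Seeding**: one root seed; structural effects and each spectrum draw
  from spawned substreams, so results are bit-reproducible and subsetting
  does not reshuffle draws.

What the generator does **not** emulate: radiometric instrument physics
(integrating sphere vs fiber optics appear only as different noise/scatter
magnitudes), heavy-tailed or drifting-variance noise, wavelength-axis
miscalibration, and chemically structured sample differences beyond band
amplitude/position. Passing recovery and ordering tests therefore
demonstrates correctness of the estimators under Gaussian structured
noise, not fidelity to any particular instrument.

## Problem sizes used in validation

The test suite and acceptance checks run on reduced problem sizes chosen
to exercise every code path while staying quick on a laptop: permutation
calibration uses 500 null simulations of an 18 × 8 session design with 200
permutations; covariance recovery uses 2000 spectra × 40 channels; the
K-ordering tendency uses 20 seeded end-to-end runs at 60 channels. The
full-size presets (360 × 236 and 720 × 74) are exercised for design
construction, simulation and the CSV round trip.

## Known limitations

- Only two-way interactions; no covariate adjustment (ASCA+), bootstrap
  confidence regions, or >2-way terms.
- No shrinkage or maximum-likelihood covariance estimation; with p ≫ n − g
  the error surfaces are rank-deficient by construction and are
  interpreted through the imbedded floor rather than regularized.
- Unbalance handling is the pragmatic cell-mean scheme; heavily unbalanced
  designs deserve a proper general linear model formulation.
- The permutation scheme for interactions (raw-label permutation) is
  approximate; exact restricted permutation schemes are not implemented.
- No statistical test on K differences between preprocessing variants;
  orderings are reported as tendencies.
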