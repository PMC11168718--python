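# Methods

## Two-block model and preprocessing

The analysis relates a participant-by-variable brain matrix **X** (n × p)
and behavior matrix **Y** (n × q).  Nuisance covariates — age (months), sex,
total head size, site, scanner, plus any extra columns supplied (e.g.
household income) — are removed from every column of both blocks by ordinary
least squares on an intercept + continuous covariates + dummy-coded
categoricals (first-level reference).  Residuals are Z-transformed with the
n−1 denominator; the scale choice cancels in every correlation but fixing
one convention makes latent-score identities exactly testable.

Sites are modelled as nested within scanner models (one scanner per site),
which makes scanner dummies exact linear combinations of site dummies.  The
design builder scans columns left to right and drops any column already
spanned by earlier ones (recorded, not fatal), mirroring the aliasing
behaviour of standard linear-model software; genuinely collinear continuous
covariates still raise an error naming the offenders.

On the default Spearman path each residualized column is replaced by average
ranks (ties → mean rank) and re-Z-transformed before any cross-product is
formed, so plain matrix products of the transformed data are exactly
Spearman correlations of the residuals, ties included.  Ranking happens
*after* residualization (residualize → rank → Z): residuals are what the
analysis Z-transforms, and the rank step belongs to the cross-product
construction.  The Pearson path skips the ranking.

## CCA and PLS as two SVDs

With R_XY, R_XX, R_YY the (Spearman or Pearson) correlation matrices of the
transformed blocks:

* PLS: SVD of R_XY.  Loadings are U and V; singular values are covariances
  of unit-weight score pairs on the standardized data.
* CCA: SVD of Ω = R_XX^{−1/2} R_XY R_YY^{−1/2}.  Singular values are
  canonical correlations; reported loadings are the canonical weights
  Wx = R_XX^{−1/2} U, Wy = R_YY^{−1/2} V, which satisfy Wxᵀ R_XX Wx = I so
  score pairs have unit variance and correlation s_i exactly.  Structure
  coefficients (R_XX Wx, R_YY Wy — correlations of variables with scores)
  are available as a secondary output.

The inverse square root uses an eigendecomposition with a relative floor:
eigenvalues below `eps` × the largest (default 1e−10) are pseudo-inverted to
zero.  In the intended regime n ≫ p the within-block matrices are well
conditioned and the floor only guards degenerate resamples; eigenvalues
negative beyond 1e−8 relative raise an error.  When R_XX = R_YY = I the two
methods coincide exactly.

Sign convention: each LV is oriented so that its largest-magnitude behavior
loading (V for PLS, Wy for CCA) is positive.  The direction of an LV is
intrinsically arbitrary; a deterministic convention makes outputs
reproducible across runs and platforms.  Near-equal singular values
(gap < 1e−6) are logged, not reordered.

## Significance: sum-of-squares permutation test

The statistic for LV k is the trailing eigenspectrum sum
T_k = Σ_{i≥k} s_i², computed from the observed decomposition and from B row
shuffles of the brain block (default 10,000 at study scale; a few hundred
suffice for calibration checks).  p_k is the add-one estimator
(#{T_k^(b) ≥ T_k^obs}+1)/(B+1), so p ∈ [1/(B+1), 1] and p = 0 is impossible.

Residualization constrains both blocks' residuals to the (n−k)-dimensional
subspace orthogonal to the design.  A plain row shuffle ejects the permuted
block from that subspace, giving null cross-correlations ~1/(n−1) variance
against observed ones of ~1/(n−k): the test then rejects well above nominal
(0.08–0.13 measured at n = 300 with a ~28-column design).  Each shuffled
matrix is therefore re-projected onto the residual subspace and its columns
re-standardized before the cross-product is rebuilt — the same device as
Freedman–Lane permutation of residuals — and the observed statistic is
computed through the identical projection (a no-op for plain residuals, a
negligible adjustment for ranked ones).  Measured type-I error at the 5%
level is 0.063 over 300 null studies with zero-inflated ordinal behavior and
0.03–0.05 with continuous behavior; the small residual excess on the ordinal
path comes from tie-induced discreteness of the rank transform.

Permutation is not re-run through the covariate regression itself (the
projection is equivalent and far cheaper); whether the original analyses
permuted raw or residualized rows is not decidable from their description,
and the projected-residual scheme is the calibrated choice.

## Resampling battery

All three procedures re-run the *full* analysis — residualization inside
every resample, then transform, cross-products, SVD — and are deterministic
given (data, configuration, seed).

**Split-half reproducibility.**  Participants are split into halves
(⌈n/2⌉ / ⌊n/2⌋, the odd one to the first half); each half is analyzed
independently; per LV, the Pearson correlation between the half-1 and half-2
loadings is recorded; the distribution over iterations is summarized by a
Z-test (mean/SD, threshold 1.96).  Because SVD signs are arbitrary, both
halves are first sign-aligned to the full-sample reference model (per LV,
joint flip of the brain/behavior pair when ⟨u,u_ref⟩+⟨v,v_ref⟩ < 0);
`alignment_mode="none"` preserves the uncorrected reading, whose r
distributions are sign-symmetric.  LVs are matched across resamples by index
only — axis swapping between close singular values is a real instability and
deliberately not corrected.  Degenerate half-samples (constant column) are
skipped and counted.

**Train-test reliability.**  An 80/20 split (configurable); the model is
fitted on the training side; the test side's own cross-product matrix
(R_XY for PLS, Ω for CCA) is built from independently residualized and
transformed test data; predicted singular values are
diag(U_trainᵀ C_test V_train), using the SVD singular vectors for both
methods — for CCA these are the generalized singular vectors, the vectors
whose projection reproduces S on the training side exactly.  That training-
side identity is exact to machine precision, so any shrinkage in the
predicted values is purely an out-of-sample effect.  A test split smaller
than q+2 rows is refused.

**Bootstrap stability.**  Rows resampled with replacement to the original n
(X and Y rows together, preserving their pairing); each refitted model is
sign-aligned to the full-sample reference; per-element percentile intervals
(default 95%) are taken over the bootstrap distribution of each loading, and
an element is flagged stable when its interval excludes zero.  Percentile
rather than BCa intervals: the plain bootstrapped interval is the stated
procedure and keeps flags monotone in the distribution.  Degenerate
resamples are redrawn (up to 20 attempts) and counted.

**Between-method comparison.**  Pearson correlations between CCA loadings
(canonical weights) and PLS loadings (singular vectors) for *all* LV pairs,
since a latent dimension may surface at a different rank in the two methods;
Pearson correlation is scale-free, so the methods' different loading
normalizations drop out.  Weights rather than structure coefficients are the
default comparand; structure coefficients can be computed and compared the
same way.

## Synthetic-data generator

The generator emulates the statistical structure of a large multi-site
pediatric cohort.  Per participant, latent scores z_l ~ N(0,1); brain
X = Σ_l c_l z_l a_lᵀ + covariate effects + noise, behavior likewise with
loadings b_l, where a_l, b_l are random unit-norm orthogonal columns
(recorded as ground truth) and c_l = sqrt(r_l/(1−r_l)) calibrates the
population correlation of the planted score pair to the configured effect
size r_l exactly when noise is uncorrelated.  Noise rows are equicorrelated
(one parameter per block, defaults 0.3) — a single-factor stand-in for the
moderate-to-high within-block correlation of regional thickness and subscale
scores.  Covariate effects are linear: fixed-magnitude random-sign
standardized slopes (default 0.1) for age, sex and head size, Gaussian
per-level shifts for site and scanner — so linear residualization is exactly
correct by construction.  Age is uniform over 107–133 months; head size
N(1450, 120) cm³; 21 sites nested in 5 scanner models.

Behavior columns are either left continuous (re-scaled to a 100 ± 15
performance-score-like scale) or pushed through a deterministic ordinal
transform: per column, values below the empirical `zero_inflation` quantile
(default 0.5) map to 0, and the rest map to {1..max_score} (default 10) by
monotone quantile binning against a geometric-like decaying marginal (ratio
0.55), reproducing checklist-style right skew and mass-at-zero.  The
transform preserves ranks among non-zero entries and maps ties to ties.  The
decay family is a stand-in chosen for shape, not a fit to any instrument's
published marginals.  One master seed spawns named substreams (covariates,
loadings, latents, noise, slopes), so identical configurations yield
identical studies.

What the generator does *not* emulate: regional measurement error,
longitudinal waves, family/sibling structure, missing data, site-by-effect
interactions, non-linear covariate effects.  Passing recovery tests on this
generator therefore demonstrates correctness of the machinery and its
behaviour under the modelled pathologies (zero inflation, skew, within-block
correlation, nuisance structure), not performance on real cohort data.

## Problem sizes and numerical choices in the test battery

The test suite exercises the battery at desk scale: recovery and
skew-degradation checks use n = 2000 with the default 68 × 11 blocks and
200–500 resampling iterations; type-I calibration uses 200–300 null studies
at n = 300, p = 10, q = 5 with B = 500 permutations; oracle equivalences
(generalized eigenproblem, SVD maximality) run on random instances at
n = 300–500.  Study-scale defaults (10,000 permutation/split-half/train-test
iterations, 1,000 bootstrap) remain the configuration defaults of the CLI
and `AnalysisConfig`-driven runs.

At a planted effect of 0.3 with 68 brain columns and n = 2000 the first
singular value sits near the noise spectrum's edge, so split-half Z for LV1
is small (≈1) and dominated by seed-level variability; increasing the
behavior block's zero inflation from 0 to 0.6 lowers it on average via rank
attenuation, but the trend is weak at this signal-to-noise ratio and is
asserted only at its endpoints.

## Known limitations

- The permutation test's projected-residual scheme is approximate when the
  rank transform intervenes (ranked residuals are only approximately
  design-orthogonal); measured miscalibration is ≤ ~1.5 percentage points at
  the 5% level under heavy zero inflation.
- LV index matching across resamples means that genuinely swapped axes
  (near-equal singular values) register as irreproducibility rather than
  being Procrustes-corrected — a deliberate, conservative reading.
- Equicorrelation is a one-parameter within-block dependence model; richer
  correlation structure (e.g. lobar blocks) can make CCA/PLS differences
  larger than the generator suggests.
- The ordinal transform's `seed` parameter is reserved; the mapping is a
  deterministic function of its input.
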