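# Methods

This note records the statistical models the package implements, the
choices made where the methodology left room, and what the synthetic-data
generator does and does not emulate.

## Trees and matrices

All statistics consume a rooted phylogeny with nonnegative branch lengths
via two matrices aligned to a canonical taxon order (lexicographic tip
labels): the Brownian covariance **C** (C_ij = root-to-MRCA path length,
C_ii = tip depth) and the patristic distance matrix **D** = diag(C)1ᵀ +
1 diag(C)ᵀ − 2C. Polytomies are handled natively — every formula is
matrix-based, so no random resolution is ever needed. Newick parsing and
writing are delegated to dendropy; validation (unique tips, nonnegative
lengths, single root) is ours. Missing branch lengths are an error by
default; an explicit flag imputes 1.0, because silently imputed unit
lengths would distort every depth-sensitive statistic. Zero-length
terminal branches are allowed but warned about: combined with duplicate
tips they make C singular, and the solvers then raise rather than
silently regularize.

## Blomberg's K

K is the ratio of the observed MSE0/MSE to its Brownian expectation
(README has the formulas). Numerically all solves go through a Cholesky
factorization of C; the explicit-inverse transcription of the formulas
exists only as a test oracle. The permutation test shuffles trait values
across tips and recomputes the GLS MSE against the fixed tree; the
P-value is one-tailed with +1 smoothing,
P = (1 + #{MSE_perm ≤ MSE_obs}) / (n_perm + 1), so P is never 0 and its
floor is 1/(n_perm+1). Lower MSE means more signal, hence the left tail.
The default 1000 permutations is configurable. Note the test is
degenerate on equal-branch star trees (C ∝ I makes every permutation
tie); this is inherent to the statistic, not an implementation artifact.

Species present in the trait table but not the tree (or vice versa) are
dropped with a logged warning before computation; it is an error only if
fewer than 3 species remain.

## WN / BM / OU fits

All fits are maximum likelihood (not REML); parameter counts are
k = 2 (μ, σ²) for WN and BM and k = 3 for OU, the convention under which
the AIC magnitudes of the three models are directly comparable. μ and σ²
are profiled in closed form through the GLS mean under each covariance
structure.

The OU model uses the non-stationary, root-fixed-at-the-optimum
parameterization on an ultrametric tree:

    V_ij = (σ²/(2α)) · exp(−α D_ij) · (1 − exp(−2α C_ij))

chosen because V → σ²C entrywise as α → 0, so BM nests exactly on the
boundary (verified to |ΔlogL| < 1e−4 at α = 1e−8). α is maximized on the
log scale over [1e−8, 50/T] (T = tree height) with 8 multistart points,
because the profile likelihood has a flat ridge at small α; an optimum on
a bound is flagged in the result, not raised. A stationary-OU covariance
and AICc are available behind options but are not defaults.

Akaike weights are w_i = exp(−Δᵢ/2)/Σ exp(−Δⱼ/2); "selected" is the
lowest-AIC (= highest-weight) model. Both raw AICs and weights are
reported so either convention of summarizing support can be read off.

## PVR / PSR

The eigenbasis is classical PCoA: Gower double-centering of the
elementwise-squared patristic distances, B = −½ J (D∘D) J. On ultrametric
trees the patristic metric is an ultrametric and hence Euclidean-
embeddable, so all n−1 nontrivial eigenvalues are positive and the basis
is complete (the PSR curve then saturates at R² = 1 exactly). For
non-ultrametric inputs eigenpairs with λ ≤ 1e−10·λ_max are discarded, the
standard PVR practice. Raw-distance centering is available behind a flag.

Eigenvectors enter the sequential regressions in descending-eigenvalue
order. Because the eigenvectors are orthonormal and centered, the R² at k
equals the cumulative squared projections of the centered trait divided
by its total sum of squares — identical to refitting OLS at each k, which
is exactly what the brute-force oracle in the tests does. The PSR area is
the trapezoid integral of (curve − identity) with the origin prepended,
so the 45°-line comparison is defined on all of [0, 1]. Null envelopes
are pointwise empirical quantiles (default level 0.95, 100 simulations)
of curves from BM and WN traits simulated on the same tree; the envelope
level, simulation count and centering convention are configurable since
no single convention is universal.

## Preseason and sensitivity

The anchor is the rounded multi-year mean phenophase day-of-year,
computed once per series. For L = 1…120 the predictor is the mean of the
daily variable over the L calendar days ending the day **before** the
anchor (windows walk real dates, so they cross year boundaries and handle
leap days naturally). The chosen preseason maximizes |r| rather than
raw r: spring phenology correlates negatively with preseason temperature
(warmer → earlier), and maximizing signed r would systematically pick
spurious positive windows; a flag restores the literal highest-r rule.
Ties go to the smallest L. The sensitivity is the OLS slope of DOY on the
preseason mean, in days/°C or days/mm; the precipitation predictor is the
window **mean** by default (a window-sum option exists; the days/mm units
refer to the mean-daily convention). Years whose 120-day scan window
precedes the climate record are dropped with a warning.

The species filter retains species with at least `min_years` (default 50)
yearly records for both FLD and FFD, and logs every retention/exclusion.
Fast tests use shorter synthetic series and set the threshold
accordingly.

## PGLS

The fit is textbook GLS through a Cholesky factor of V, where V is C
with off-diagonals multiplied by Pagel's λ. The default is fixed λ = 1
(pure Brownian errors); `lambda_mode="ML"` profiles λ over [0, 1] by a
21-point grid plus bounded refinement. Each functional trait is fit as a
separate single-predictor model (intercept + one 0/1 indicator);
reference levels are fixed (shrub, biotic, deciduous), so e.g. later
leaf-out in trees yields a positive life-form coefficient. Standard
errors use σ̂² = RSS_GLS/(n−p); t statistics carry n−p degrees of
freedom and two-sided P-values. With V = I the fit reproduces OLS to
machine precision (tested against statsmodels).

## Synthetic data

The generator produces every input with known ground truth:

- **Trees**: pure-birth (Yule) forward simulation, exactly ultrametric,
  default birth rate 1/unit time; mean height matches the analytic
  Σ_{k=2..n} 1/k expectation.
- **Traits**: multivariate-normal draws under σ²I (WN), σ²C (BM) or the
  OU V above, via Cholesky with a 1e−12 relative jitter.
- **Climate**: daily mean temperature = annual mean (12 °C) + seasonal
  cosine (amplitude 12 °C, period 365.25 d, peak DOY 200) + per-year
  anomaly (sd 0.8 °C) + AR(1) noise (coefficient 0.7, marginal sd 2 °C);
  precipitation is i.i.d. Gamma (shape 0.6, scale 4 mm). Values emulate a
  temperate station; the 365.25-day period deliberately exercises leap
  handling.
- **Phenology**: DOY_y = base + β_T·(T̄_y − mean) + β_P·(P̄_y − mean) +
  N(0, sd), rounded to whole days (phenology is recorded in days, so
  recovery tolerances carry a ±0.5-day quantization floor) and generated
  through the same window-mean operator the estimator uses — noiseless
  recovery is therefore exact by construction, which is the point of the
  generator. Defaults: 1968–2018 records, base FLD 100 / FFD 130, true
  preseason 30 d, β_T = −3 days/°C, β_P = 0, residual sd 2 days.
- **Stations**: per-species baselines = functional-trait offset (trees
  +10 days vs shrubs) + phylogenetic component (default BM, variance 64
  days², 10 % independent noise) ; per-species slopes vary around the
  true values with variance 0.25. Functional traits are independent
  balanced coin flips at the tips.

What the generator does **not** emulate: observation gaps and observer
changes, spatial weather heterogeneity, chilling/photoperiod
co-limitation, trends in the climate series, and correlated functional
traits. Passing tests therefore demonstrate the estimators are correct
and calibrated under the stated generative model, not that real
phenology obeys it.

## Determinism and problem sizes

Every source of randomness is an explicit `numpy.random.default_rng`
seed; the pipeline logs and echoes its configuration and produces
byte-identical artifacts on re-run (the run log line timestamps are the
only exception, so determinism is asserted on the data artifacts).
Simulation-based checks use a 64-tip tree with 200–500 replicates and
50-year climate series — sizes at which the Monte-Carlo error of each
calibration quantity is several times smaller than the acceptance band
it is checked against.

## Known limitations

- Blomberg's K is implemented for continuous traits only; no Pagel's λ
  signal statistic (PGLS's λ is a different use).
- OU fitting requires an ultrametric tree; non-ultrametric trees raise.
- The PGLS design supports one categorical predictor per model by
  default (multi-predictor designs work but are not what the reporting
  tables assume).
- No multiple-testing correction is applied across the six traits in the
  station report; an optional Benjamini–Hochberg column can be added by
  the user from the raw P values.
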