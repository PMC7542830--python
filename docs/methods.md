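# Methods

## The model

All analyses work on log10-transformed species-mean traits. The focal model
is a phylogenetic generalized least-squares (PGLS) regression

    y = X b + e,    e ~ N(0, sigma^2 C(lambda))

where `y` is log10 eye diameter (ED, mm), the design `X` carries an
intercept and log10 body size — either snout–vent length (SVL, mm) or the
cube root of wet mass (RM, g^(1/3)), chosen so that isometry with a length
trait sits at slope 1 — and `C` is the phylogenetic covariance built from a
rooted tree with branch lengths: `C[i, j]` is the depth of the most recent
common ancestor of tips i and j, `C[i, i]` the root-to-tip distance.
Pagel's lambda multiplies the off-diagonal entries only; lambda = 0 removes
phylogenetic signal, lambda = 1 is the Brownian-motion expectation.

A species' *eye investment* is `10^r`, where `r` is its PGLS residual from
the ED ~ RM fit: the factor by which its eye diameter exceeds the allometric
expectation for its mass (a residual of 0.2 is a 10^0.2 ≈ 1.6× eye).
Corneal investment is defined the same way from the CD ~ ED fit.

## Fitting and numerical choices

- **Estimation.** GLS is solved by Cholesky whitening (`L^-1 X`, `L^-1 y`
  then ordinary least squares via `lstsq`), algebraically identical to
  `(X'C^-1X)^-1 X'C^-1 y` but stable. Lambda is estimated by maximum
  likelihood (not REML) on [0, 1]: a 21-point grid brackets the optimum,
  then bounded scalar minimization refines it to an absolute tolerance of
  1e-6. On a star phylogeny the likelihood is flat in lambda; lambda is then
  reported as 0 with a flag. `sigma^2` uses the ML divisor n inside the
  likelihood; standard errors use the residual-df divisor n − p, the mixed
  convention that reproduces conventional t statistics and dfs.
- **R².** 1 − RSS/TSS in the whitened space, TSS about the GLS-estimated
  mean under the same `C(lambda-hat)` (the convention of standard
  comparative-methods software).
- **Outlier screen.** Externally Studentized residuals computed in the
  whitened space; species exceeding |3| are removed one per iteration
  (worst first, ties broken alphabetically) and the model refit with ML
  lambda, stopping before n falls to p + 2. The report records every
  removal and the coefficient drift.
- **Trees.** Pruning collapses degree-2 nodes by summing edge lengths, so
  pairwise tip path lengths are preserved exactly. A tip grafted as a
  polytomous sister copies its sister's terminal branch length (the pair
  stays exchangeable in `C`; this is a convention — the protocol being
  emulated does not fix it — and is logged). Polytomies are resolved by
  seeded random sequential binarization with zero-length internal edges, so
  the covariance is identical for every resolution. Tips made
  indistinguishable by zero-length terminal branches get a diagonal jitter
  of 1e-8 × tree depth, logged.
- **SMA.** Least-squares standardized major axis: |slope| = sd(y)/sd(x),
  signed by the correlation; CI by the standard F-based interval
  (alpha = 0.05). The slope-= b0 test uses the correlation between the
  residual axis `y − b0 x` and fitted axis `y + b0 x`,
  `F = r²(n−2)/(1−r²)` with (1, n−2) df. The robust variant replaces
  locations/scales by Huber M-estimates (c = 1.345, IRLS to 1e-8, max 100
  iterations) on each variable, with the slope sign from the jointly
  down-weighted covariance. Robustness is a per-fit flag, not
  auto-detected.
- **Kruskal–Wallis.** scipy's tie-corrected H with the chi-square
  (k − 1 df) approximation; all-identical samples return H = 0 by
  convention; groups smaller than 5 trigger a warning.
- **Phylogenetic ANCOVA.** PGLS of `size ~ body * trait` with treatment
  contrasts (reference = alphabetically first level) and sequential
  (Type I) sums of squares in formula order — covariate, factor,
  interaction — computed in the whitened space by differencing nested
  residual sums of squares; F against the full-model residual mean square.
  This coding reproduces the (k−1, n−2k) df pattern of a k-level factor
  with interaction. Species missing any involved variable are dropped from
  that model only (per-trait listwise deletion).
- **Lambda for the ANCOVA table.** The returned model fit uses full-model
  ML lambda, but the sequential decomposition whitens under lambda profiled
  on the covariate-only model. Calibration simulations showed why: with the
  full model free to push lambda-hat to the boundary 1 (where very short
  sister branches receive extreme whitening weight), the factor test's
  type-I rate inflated to ~0.12 at n = 80; profiling lambda before the
  factor enters restores the nominal 5% level. This is a deliberate
  departure from the single-shared-lambda convention of some comparative
  packages, made for calibration.

## The synthetic-data generator

The generator produces study-scale datasets with known ground truth:

- **Tree.** Pure-birth (Yule) tree with exactly n tips; waiting times are
  exponential with rate (number of lineages × birth rate) and one final
  waiting time runs all tips to the present, so trees are ultrametric.
  Default n = 220, birth rate 1.
- **Body size.** log10 RM evolves by Brownian motion (one multivariate
  normal draw with covariance `predictor_sigma2 × C(1)`), rate 0.022
  log10² per unit branch about a root value of 0.33 (≈ a 10 g frog),
  giving a realistic ~0.3–0.4 sd of log10 RM across tips.
- **Eye size.** log10 ED = 0.43 + 0.82 × log10 RM + e, with e drawn at
  lambda_true = 0.96 and residual rate chosen so the allometry-only PGLS R²
  targets 0.80 (`sigma2 = b² Vx (1/R² − 1)`; both rates share the tree's
  depth, so the target is scale-free). Intercept 0.43 puts a 10 g frog at
  ≈ 5 mm eyes.
- **Ecology.** Six categorical traits. Adult habitat defaults to i.i.d.
  draws from illustrative frequencies (scansorial .30, ground-dwelling .30,
  semiaquatic .12, subfossorial .12, aquatic .08, fossorial .08) with
  additive log10 offsets equal to the log of the investment factors the
  pipeline is designed to detect (scansorial 1.24× … fossorial 0.65×); a
  continuous-time Markov walk along branches is available instead. The
  other five traits are i.i.d. with no planted effect.
- **Specimens.** 1–7 preserved specimens per species; every length
  measurement carries independent lognormal noise (CV 0.03, left and right
  eyes separately); preserved lengths shrink by 0.97 (mass by its cube). A
  50-species subset contributes 1–2 fresh records each (≈ 70 records) with
  dissected axial length, AL ≈ 0.95 × ED, supporting the ED→AL calibration
  regression. SVL and CD are tied to RM and ED by near-isometric and
  slightly hypoallometric relations with small independent noise.

All randomness flows through numpy's PCG64 `Generator`; a seed regenerates
every dataset bit-for-bit, and the ground truth is echoed in `truth.json`.

**What the generator does not emulate.** Habitat offsets applied to i.i.d.
states add *non-phylogenetic* variance on top of the lambda = 0.96
allometric residual. A full-pipeline fit on the default dataset therefore
shows an attenuated lambda-hat (~0.7) and R² (~0.55–0.6) relative to the
generating allometry — the expected behaviour of the estimator, not a
defect — while the allometry-only simulation recovers slope and lambda
cleanly (coverage ≈ 95%, median lambda-hat ≈ 0.96). Real habitat states are
phylogenetically clustered, real measurement error is not purely
multiplicative, and anatomical covariance beyond simple
proportionality-plus-noise (and any biogeography) is out of scope. Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not field realism.

## Simulation sizes

Monte-Carlo checks use: 200 replicates at n = 220 for slope-CI coverage and
the lambda-hat median; 500 replicates at n = 80 with a 3-level factor for
the ANCOVA type-I calibration; 50 replicates at n = 220 for the
planted-offset (−0.19 log10 on a 20-species state) power check; 500
replicates for the isometry-test null uniformity. These sizes give binomial
standard errors a few times smaller than the margins asserted.

## Known limitations

- Lambda is constrained to [0, 1]; Ornstein–Uhlenbeck and measurement-error
  models are out of scope, as are REML, phylogenetic SMA and major-axis
  variants, and multiple-testing correction across the six traits.
- The ED→AL calibration transform is applied to species means on raw mm;
  whether to apply it per specimen instead is a documented choice.
- RM is the cube root of the species-mean mass (not the mean of
  per-specimen cube roots); configurable.
- The full-model ML lambda-hat is reported with each ANCOVA, but its
  boundary behaviour in small samples is the reason the table itself uses
  the covariate-model lambda (above).
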