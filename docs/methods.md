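# Methods

## Data-generating model

A simulated synergism experiment consists of two arms (reference =
pyrethroid-only, treatment = pyrethroid + PBO), each with `tubes_per_arm`
tubes of `mosquitoes_per_tube` mosquitoes (default 25, the WHO protocol
figure), spread over `days` testing days. Tube-level deaths follow a
hierarchical logit-normal binomial model:

    logit(p_tube) = logit(p_arm) + delta_day + eps_tube,
    delta_day ~ N(0, sigma_b^2),  eps_tube ~ N(0, sigma_w^2),
    n_dead ~ Binomial(n_exposed, p_tube).

Choices that the model leaves open, and how this package resolves them:

- **Scale of the random effects.** Effects act additively on the logit
  scale. This is the scale on which the variance components are defined
  (they are extracted from a binomial-logit GLMM), and it keeps simulated
  probabilities in (0, 1) without truncation. The arm mortality parameter is
  the back-transform of the logit-scale mean, i.e. the *median* tube
  mortality. A truncated additive-on-the-proportion-scale variant was
  examined and discarded: it piles probability mass onto exactly 0/1 and its
  design answers are markedly different and incompatible with the logit
  reading of the variance components.
- **Degenerate arms.** An arm mortality of exactly 0 or 1 has an infinite
  logit; finite random effects cannot move it, so counts are produced
  deterministically (0 or n). This reflects the real boundary behaviour of
  proportion data — a group near 100% mortality has almost no variance,
  which is precisely why boundary comparisons are easy to detect.
- **Day effects and arms.** By default each arm draws its *own* day effects
  (`day_effect_mode="independent"`). Were the day effect shared by both
  arms, it would cancel almost entirely out of the two-arm contrast and
  multi-day designs would cost nothing — contradicting the well-established
  observation that between-day variability erodes the power of split
  designs. Arm-specific day effects encode that the day-to-day drift
  (cohort age structure, rearing batch, handling) need not strike both arms
  equally, and give conservative design guidance. `"shared"` is available
  as an option for sensitivity analysis.
- **Single-day designs** have no day effect at all (delta = 0): running
  everything on one day eliminates between-day variability by design, so
  single-day power depends only on sigma_w.
- **Allocation.** Tubes are spread over days as evenly as possible, with
  remainder tubes on the earliest days (5 tubes over 2 days -> 3 + 2), both
  arms identically.

## Analysis model and test

Each dataset — simulated or real — is analysed with a binomial GLM with a
single fixed effect for treatment arm and *no* random effects (with at most
five day groups, a day random effect is not estimable to any useful
precision). The arm factor saturates the model, so the MLE of each arm's
mortality is its pooled deaths/exposed and the likelihood-ratio statistic
against the intercept-only model has the closed form

    LRT = 2 [ l(p1_hat, p2_hat) - l(p_pooled) ],

the classic two-sample binomial deviance, referred to chi-square with 1 df
(alpha = 0.05, two-sided; no continuity correction). Log-likelihoods use the
binomial kernel with the 0·log 0 = 0 convention, so arms at 0% or 100% are
handled exactly rather than by iterative fitting that stalls on complete
separation. The closed form is verified in the test suite against an
independent binomial log-pmf oracle on every pair of arm totals up to n = 20
(to 1e-9) and against statsmodels' IRLS GLM on representative datasets.

The chi-square reference makes the test approximate on a discrete lattice:
exhaustive enumeration of the null outcome space gives a true size of 0.0560
at 100 mosquitoes/arm and 0.0544 at 250/arm, versus the nominal 0.05. The
calibration tests therefore compare simulated null rejection rates against
the *enumerated exact size*, not against the nominal level.

## Power estimation

Power for one parameter combination is the proportion of `replicates`
simulated experiments with p < alpha, reported with its binomial Monte-Carlo
standard error sqrt(power·(1−power)/replicates). Since the LRT depends on
the data only through arm totals, the engine simulates totals vectorised
across replicates; 10,000 replicates of a 4x4 design take milliseconds.

- **Default replicates: 10,000** (study setting); the acceptance script uses
  20,000 so that first-crossing decisions at the 80% contour sit several
  Monte-Carlo SEs from the boundary.
- **Minimum detectable difference (MDD):** the difference grid runs from 0
  to 50% in 2.5% steps; the MDD is the first grid value whose estimated
  power reaches the target (80% by convention), mirroring how a power curve
  is read against a horizontal 80% line. The scan truncates (with a warning)
  where reference + difference would exceed 1, and returns a sentinel when
  no grid value qualifies.
- **Worst case:** the default reference mortality for MDD/sample-size scans
  is 0.50, the point of maximum binomial uncertainty; power at any other
  reference is higher for the same difference.
- **Minimum tubes:** scans 4–10 tubes per arm (the practical range for the
  assay) and returns the smallest count reaching the target, or a sentinel
  meaning "beyond the range of this framework".
- **Grid cache:** the full default grid (21 differences x 7 tube counts x
  5 day counts x 5 within-day SDs x 5 between-day SDs = 18,375 cells) can be
  precomputed once and cached as CSV + JSON sidecar. Each cell is seeded by
  `base_seed` combined with a CRC-32 hash of its parameters, so runs are
  bit-reproducible, resumable, and any cell can be recomputed in isolation.
  Lookup is exact-match only; the cache never interpolates.
- **Variance defaults:** within-day SD 0.25 and between-day SD 0.60, the
  values characteristic of a PBO-exposed pyrethroid-resistant strain under
  controlled insectary conditions; both are freely settable, and estimates
  from less controlled settings should be expected to be larger.

## Variance-component estimation

`TubeVarianceModel` fits the intercept-only binomial GLMM with a per-day
random intercept (between-day) and an observation-level random intercept
(within-day; tube labels carry no identity across days, so "tube within
day" is an observation-level effect). The marginal likelihood integrates
both effects out: tubes are conditionally independent given the day effect,
so the tube intercept is removed by plain Gauss–Hermite quadrature (31
nodes), and the day effect by **adaptive** Gauss–Hermite quadrature (21
nodes centred at the per-day conditional mode, scaled by the conditional
curvature; a day holding several tubes of 25 mosquitoes has a posterior far
narrower than its prior, where non-adaptive nodes would miss the mass). The
implementation is validated against brute-force nested `scipy.integrate.quad`
(agreement to 1e-6 on small instances) and against lme4's Laplace `glmer`
fit on moderate simulated data.

Maximisation is by L-BFGS-B on (intercept, variance_w, variance_b). The
*variance* parameterisation matters: the likelihood is an even function of
each SD around zero, so the SD-scale gradient vanishes identically at the
boundary and a gradient-based optimizer can report convergence in the zero
corner; on the variance scale the boundary gradient is finite and boundary
estimates are genuine maxima. Estimates at the boundary are reported as 0,
never negative. Standard errors come from a finite-difference Hessian on
the (intercept, SD, SD) scale and are reported as NaN at a boundary (where
the quadratic approximation is invalid). A dataset with a single testing
day raises: the between-day SD is then undefined, not zero.

Descriptive precision statistics follow the bioassay conventions: the
per-day CoV (intra-assay precision) is the sample SD of a day's tube
mortality proportions over their mean; the overall CoV (inter-assay
precision) is the SD of the daily mean mortalities over the grand mean of
daily means (a pooled-tubes variant is exposed as an option). Conditional
R² uses the logistic distribution-specific residual variance pi^2/3.

## What the synthetic data do and do not emulate

The simulator reproduces the dominant stochastic structure of tube bioassay
data: binomial sampling within tubes, logit-scale tube-to-tube
heterogeneity, and systematic day-to-day drift. It does **not** emulate
varying tube occupancy (real tubes range ~20–35 mosquitoes; simulations fix
25), mosquito-level covariates (body weight, wing length), environmental
covariates, declining paper potency across repeated uses, or 60-minute
knockdown. Passing tests therefore certify the statistical machinery under
the stated model, not the biological completeness of that model; variance
estimates fed into the power engine should come from data collected under
conditions comparable to the planned experiment.

## Known limitations

- Power answers are grid-valued (2.5% differences, integer tubes); nothing
  is interpolated.
- The analysis model deliberately ignores day structure (as the real
  analysis of a 1–5 day assay must), so between-day variance appears as
  unmodelled overdispersion: null rejection rates under sigma_b > 0 exceed
  the nominal alpha. This is a property of the assay's standard analysis,
  not a bug in the simulator.
- The GLMM estimator assumes independent Gaussian random effects on the
  logit scale; strong mean-variance coupling or temporal autocorrelation
  across days would violate it.
- Fitting is ML (not REML-like); variance estimates on small day counts are
  biased low, as for any ML variance component.
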