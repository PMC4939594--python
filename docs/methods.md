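# Methods

## Data-generating model

Each simulated trial follows the two-level linear mixed model

    y_ij = beta0 + beta1 * x_j + beta2 * z_j + u_j + e_ij,

for subject `i = 1..n1` in cluster `j = 1..n2`, with treatment indicator
`x_j` (1:1 allocation, exactly `n2/2` intervention clusters), binary
cluster-level covariate `z_j` (exactly `n2/2` covariate-positive clusters),
cluster effects `u_j ~ N(0, sigma_u2)` and residuals `e_ij ~ N(0, sigma_e2)`,
all independent. The total variance is normalized to
`sigma_u2 + sigma_e2 = 1`, so the intraclass correlation is
`rho = sigma_u2` and `beta1`, `beta2` are in outcome-SD units. `beta0`
defaults to 0; every reported quantity is invariant to location shifts.

The covariate configuration is **fixed by the design, not resampled**: a
condition studies the consequences of a *given* degree of imbalance, so each
replicate keeps the same `(x, z)` and redraws only `u` and `e`. Under
complete randomization the covariate-positive count `k` in the intervention
arm would be hypergeometric with population `n2`, `n2/2` successes and
`n2/2` draws (verified by simulation in the test suite); a degree of
imbalance is expressed as a quantile `q` of that distribution, realized as
the smallest `k` with `CDF(k) >= q`. This convention reproduces the two
anchor percentages (70 % at `n2 = 20`, 56 % at `n2 = 200` for `q = 0.95`)
and maps `q = 0.5` to perfect balance `k = n2/4`. The induced
treatment–covariate correlation is `rho_xz = 4k/n2 - 1`, identical to the
Pearson correlation of the realized indicator vectors.

## Planning

The number of clusters for power `1 - beta` against `beta1` at two-sided
level `alpha` is

    n2 = 4 (sigma_e2 + n1 sigma_u2) / (n1 (1 - rho_xz^2))
         * ((z_{1-alpha/2} + z_{1-beta}) / beta1)^2,

using standard normal quantiles. Within the study, planning always assumes
balance (`rho_xz = 0`) — that is precisely the practice whose cost is being
measured. The raw value is rounded **up to the next multiple of 4** so that
each arm holds an even number of clusters and the binary covariate can be
exactly balanced at `q = 0.5`.

A configurable minimum (default `min_n2 = 8`) guards the planning output:
for `n1 = 50, rho = 0.01` the formula yields fewer than 8 clusters, and at
4 clusters the extreme quantiles make `x` and `z` perfectly collinear, so
the adjusted model would be unidentifiable. Whenever the clamp binds it is
recorded in the run's metadata file.

## Estimation

Both models are balanced with purely cluster-level regressors, so the mixed
model collapses onto the cluster means `m_j`, which are independent with
common variance `tau = sigma_u2 + sigma_e2/n1`. Consequences used
throughout:

* GLS for the fixed effects equals OLS on the cluster means, for **any**
  variance values — the estimates need no iteration;
* the restricted likelihood factorizes into a within-cluster part
  (`SSW` on `n2(n1-1)` df, estimating `sigma_e2`) and a cluster-mean
  regression part (`RSS` on `n2 - p` df, estimating `tau`), giving the
  classical ANOVA estimators
  `sigma_e2_hat = SSW / (n2(n1-1))`,
  `sigma_u2_hat = RSS/(n2-p) - sigma_e2_hat/n1`
  as the exact REML solution when the latter is nonnegative;
* when the unconstrained solution is negative, the constrained REML maximum
  sits on the boundary `sigma_u2 = 0` with the two parts pooled:
  `sigma_e2_hat = (SSW + n1 RSS) / (n1 n2 - p)` — the residual variance of
  the individual-level OLS fit. Flooring the between-cluster variance at
  zero *without* re-estimating `sigma_e2` is not the REML solution and was
  measured to inflate the adjusted model's SE bias by almost a percentage
  point in the low-ICC cells; the boundary solution is used instead.

The test suite verifies both regimes against a brute-force numerical REML
(Nelder-Mead over the full `N x N` covariance) to 1e-6 and against
`nlme::lme`.

The model-based standard error of the treatment effect is

    se(beta1_hat)  = sqrt(4 (sigma_e2_hat + n1 sigma_u2_hat)
                          / (n1 n2 (1 - r_xz^2)))     (adjusted, p = 3)
    se(beta1_hat*) = sqrt(4 (sigma_e2_hat* + n1 sigma_u2_hat*) / (n1 n2))
                                                      (unadjusted, p = 2)

which is exactly the GLS variance for 0/1 coding with equal arms — the
factor 4 arises because a 0/1 contrast between two half-samples has
`1/Sxx = 4`. The Wald statistic `beta1_hat / se` is referred to a central t
with `n2 - 3` (adjusted) or `n2 - 2` (unadjusted) degrees of freedom; no
small-sample df corrections (Kenward–Roger, Satterthwaite) are applied.

## Evaluation criteria

Per condition, over `R` replicates:

* **parameter bias %** `= 100 (mean(beta1_hat) - beta1) / beta1`
  (undefined for `beta1 = 0`, and guarded accordingly);
* **SE bias %** `= 100 (mean(se) - sd(beta1_hat)) / sd(beta1_hat)`, with the
  sample SD on `R - 1` degrees of freedom;
* **empirical power %** = percentage of replicates rejecting
  `H0: beta1 = 0` at `alpha = 0.05`, two-sided.

Acceptability thresholds used by the verification report: 10 % absolute
parameter bias, 5 % absolute SE bias.

Closed-form cross-checks: the unadjusted estimator equals the arm-mean
difference, so its bias expectation is
`100 beta2 (2k - n2/2)/(n2/2) / beta1`, exact under fixed imbalance; the
theoretical SE is the `se` formula evaluated at the true components; nominal
power is the normal-approximation value
`100 Phi(beta1/se - z_{1-alpha/2})` at `rho_xz = 0`, which inverts the
planning formula exactly (plugging in the unrounded `n2` returns the target
power). A noncentral-t variant (`nominal_power_pct_t`) is exposed as a
small-sample refinement; the normal version is the reported nominal line,
matching the planning formula it is compared against.

## Study design and problem sizes

The default grid is the full Cartesian product
`n1 x rho x beta2 x q = 3*3*3*7 = 189` conditions with constants
`beta1 = 0.5`, `alpha = 0.05`, power target 0.8. The reference run uses 5000
replicates per condition; the acceptance script runs exactly that (about
30 s on one CPU, since all fits are closed-form and vectorized over
replicates), while the test suite's shared grid run uses 2000 replicates
with proportionally widened Monte-Carlo tolerances.

Seeding: each replicate's generator is seeded with
`SeedSequence((master_seed, condition_index, replicate_index))`, where the
condition index comes from the sorted factor tuple. Results are therefore
reproducible bit-for-bit and independent of execution order; a rerun with
the same seed produces a byte-identical results CSV.

## What the generator does and does not emulate

It reproduces the study conditions faithfully: equal cluster sizes, exactly
half the clusters covariate-positive, fixed imbalance, normal random
effects, unit total variance. Real trials have varying cluster sizes,
covariates with other prevalences and measurement error, multiple covariates
at both levels, and non-normal outcomes — none of which are modelled, so
passing tests demonstrate correctness of the method under its stated
assumptions, not robustness beyond them.

## Numerical choices and known limitations

* Deterministic cluster ordering (intervention first, covariate-positive
  first within arm); the model is exchangeable over clusters, so this is
  bookkeeping only.
* Perfectly collinear adjusted designs raise an error rather than produce
  output; with the default minimum of 8 clusters no grid condition is
  collinear, so per-replicate failure counts are structurally zero (the
  covariate pattern is fixed per condition).
* Quantile inversion guards against floating-point slack in the
  hypergeometric CDF by enforcing `CDF(k) >= q > CDF(k-1)` exactly.
* At `rho = 0.01` the REML boundary (`sigma_u2_hat = 0`) occurs in a large
  fraction of replicates. This truncation lifts the mean model-based SE
  slightly above the empirical SD (SE bias around +5 to +6 % in those
  cells — any REML implementation, including `nlme::lme`, shows it) and
  depresses balanced-cell empirical power about 2 points below the
  noncentral-t approximation. The balanced-power test therefore allows 2.5
  percentage points of systematic slack on top of Monte-Carlo noise.
* The grid-wide extreme of the adjusted model's parameter bias is an extreme
  order statistic of Monte-Carlo noise (each condition's bias has SE around
  0.5–0.8 % at 5000 replicates), so its exact value varies with the master
  seed within roughly ±2 %.
* With planning at `rho_xz = 0`, every `n2 = 12` cell reaches
  `rho_xz = 2/3` at `q = 0.975` (variance inflation 1.8); noncentral-t
  arithmetic then puts adjusted-model power near 51 % against a nominal of
  86 %, a loss of ~35 percentage points — larger than the ~24-point loss the
  normal approximation suggests for the same cell. The simulation reports
  the t-test value.
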