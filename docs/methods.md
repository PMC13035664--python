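# Methods

## The problem

When individuals complete several experimental tasks, the scientific
quantity of interest is often the correlation between their *true* task
performances. Observed scores carry trial-to-trial noise, so the Pearson
correlation of averaged scores is attenuated by the factor

    sigma_1 sigma_2 / ( sqrt(sigma_1^2 + tau_1^2/L) sqrt(sigma_2^2 + tau_2^2/L) )

where `sigma_j` is the between-individual SD, `tau_j` the trial noise SD,
and `L` the number of trials averaged. Hierarchical Bayesian models
disattenuate the estimate by modeling the two noise sources separately:

    Y_ijl | theta_ij ~ N(theta_ij, tau_j^2)          (trials)
    theta_i ~ N_J(mu, Sigma),  Sigma = D(sigma) rho D(sigma)

The package estimates `rho` under three priors on `Sigma` and measures how
robust each is to misspecifying the prior scale, to adding tasks, and to
the shape of the scale prior.

## Priors

* **Inverse Wishart** `Sigma ~ IW(S, v)`. Default `v = J + 1`, `S = s^2 I`
  — the marginal prior on every pairwise correlation is then exactly
  Uniform(-1, 1). Scale and correlation are dependent a priori: small SDs
  push correlations toward 0, large SDs toward +-1, which is the mechanism
  behind the scale-misspecification bias the studies quantify.
* **Scaled inverse Wishart** (mixture form): `alpha_j ~ IG(1/2, 1/s_j^2)`,
  `Sigma | alpha ~ IW(v + J - 1, 2v D(1/alpha))`, default `v = 2`. Marginal
  correlations are uniform for any J; marginal SDs are half-t(2, s_j).
* **LKJ + scale priors**: `rho ~ LKJ(eta)` (default `eta = 1`, uniform over
  correlation matrices) with independent `sigma_j ~ half-t(2, s_j)` (six
  alternative families available, all centered near `s_j`). Correlation and
  scale are independent by construction; the marginal on any single
  correlation is `2 Beta(a, a) - 1` with `a = eta + (J - 2)/2`, so it
  tightens around 0 as tasks are added.

## Samplers

IW and SIW posteriors use fully conjugate Gibbs cycles: multivariate-normal
full conditionals for the true scores `theta_i` (vectorized over
individuals in balanced designs), conjugate normal updates for `mu` (and
per-cell intercepts `alpha_ij` in contrast designs), inverse-gamma updates
for `tau_j^2` and for the SIW mixing scales `alpha_j` (full conditional
`IG((v + J)/2, v (Sigma^{-1})_jj + 1/s_j^2)`, validated against numerical
quadrature), and an inverse-Wishart draw for `Sigma` via a
Bartlett-decomposition sampler (unit-tested against scipy on non-diagonal
scale matrices).

The LKJ posterior has no conjugate `Sigma` update. We use
Metropolis-within-Gibbs: the correlation matrix is parameterized by
unconstrained `y` with `z = tanh(y)` the canonical partial correlations of
a C-vine. Under LKJ(eta) the partial correlations are independent scaled
Betas, so the Metropolis target needs only that factorized prior plus the
tanh Jacobian — no matrix Jacobian. Components of `y` and log-SDs are
updated one coordinate at a time by random-walk proposals with
Robbins-Monro step adaptation toward 44% acceptance (the one-dimensional
random-walk optimum) during burn-in only (frozen afterward, preserving
detailed balance); four Metropolis sweeps run per Gibbs iteration because
they are cheap relative to the conjugate block and keep the correlation
block's effective sample size close to the conjugate samplers'. The correlation matrix assembled
from the vine is identical to the Cholesky cross-product of the equivalent
triangular parameterization.

Hyperpriors left open by the model are set scale-aware but effectively
flat: `mu_j ~ N(0, (100 u)^2)` and `tau_j^2 ~ IG(.01, .01 u^2)` with `u`
the pooled SD of the raw scores. Initialization: `theta` at cell means (or
cell contrasts), `tau` at the pooled within-cell SD, `Sigma` at the
covariance of cell means plus `1e-6 I` jitter, `mu` at grand means.

Every sampler accepts `prior_only=True` (or zero-row data for the manifest
model), which drops all data contributions; the resulting chains must
reproduce the prior marginals, and the test suite checks that they do.

Diagnostics (rank-normalized split R-hat, bulk ESS) are delegated to
arviz behind thin wrappers; a single chain is split into halves first.
Credible intervals are equal-tailed 2.5%/97.5% posterior quantiles.

## Synthetic data

The generator covers three designs with fixed study conditions:

* **two_task**: I=200 individuals, L=20 trials per cell, mu=(.5,.5),
  sigma=(.1,.1), a single free correlation, trial noise tau in
  {.2 (low), .4 (moderate), .5 (high)} depending on the study.
* **four_task**: named coefficients rho_12=.3, rho_13=.5, rho_14=.7. Only
  those three are pinned by the study design; the remaining entries are
  completed as rho_23=.3, rho_24=.5, rho_34=.3 (PSD-checked). Summaries
  flag named vs completed coefficients, and reproductions of the four-task
  tables inherit this approximation.
* **eight_task**: rho_12=.8, all other off-diagonals .2.
* **contrast**: two conditions per task with codes x = -.5/+.5, intercepts
  N(600, 100^2) ms, slope means 60 ms, slope SDs 25 ms, slope correlation
  .5, tau=175 ms, L=150 trials per individual x task x condition —
  typical Stroop-experiment magnitudes.
* **manifest**: one multivariate-normal score per individual; the
  ten-variable preset (target pair correlation .5 among moderately
  correlated background variables, unit SDs) is a synthetic stand-in for
  an anthropometric two-of-ten-variables analysis; it emulates the design
  shape, not real body-measure distributions.

Scores are on the unit scale except the contrast design (milliseconds); no
rescaling happens anywhere. One RNG stream per replicate, seeded
`base_seed + replicate`, makes studies rerunnable piecewise. The generator
emulates balanced, complete, normal data only — no missingness, skew,
outliers, or unequal trial counts — so passing studies demonstrate
estimator behavior under the model's own assumptions, not robustness to
real-data pathologies.

## Study harness and summaries

`run_study` draws fresh data each replicate and submits the identical
dataset to every configured method, including two non-Bayesian references:
the Pearson correlation of the true scores (the best case achievable with
the same individuals) and the averaging baseline with Fisher z intervals.

**RMSE definition.** Tables report the RMSE of each method's point
estimate about the *realized true-score sample correlation* of that
replicate (`reference="sample_r"`), not about the population value. The
distinction matters: at I=200 the sample correlation itself fluctuates
about rho with SD ~(1-rho^2)/sqrt(I), which floors the about-population
RMSE near .064 at rho=.3 — the about-sample-r reading is the one under
which a hierarchical model can approach "as good as knowing the true
scores", and it is the definition our reproduced table cells match.
`reference="population"` is available for the other reading.

Coverage is always of the population truth by the equal-tailed 95%
credible interval. Densities of posterior means across replicates use a
Gaussian KDE with Silverman bandwidth.

## Problem sizes and numerical choices

Replicate sweeps use a single chain of 1000 burn-in + 3000 retained
iterations (the studies' per-run budget); runs feeding R-hat use 4 chains
of the same length. The package's own test suite scales sweeps down to
30-100 replicates with 400-500 burn-in and 1200-1500 retained draws and
two Metropolis scans per iteration — posterior means and intervals are
insensitive to chain length and kernel scan count beyond Monte-Carlo
error, and tolerances there include bootstrap standard errors of the
RMSE. Diagnostic (R-hat) runs always use the full budget and default
kernel. The acceptance script uses the full chain budget with 50
replicates per condition.

Tie-breaks and degenerate inputs: correlation matrices are accepted down
to a minimum eigenvalue of -1e-10; partial correlations are clipped to
+-0.999 before atanh at initialization; zero trial noise is legal (the
trial-variance posterior concentrates near zero and true scores are
recovered exactly); constant MCMC chains yield NaN diagnostics with a
warning rather than an exception; Metropolis blocks whose post-adaptation
acceptance falls below 5% are flagged in the fit's warnings.

## Known limitations

* The LKJ sampler is a random-walk scheme adequate for J <= 8; its
  effective sample size per iteration is several times lower than the
  conjugate samplers', and wall-clock comparisons between priors are out
  of scope.
* The four-task and eight-task ground-truth matrices carry the documented
  completion of their unnamed entries; cells that depend on those entries
  are approximations and are labeled as such in outputs.
* Only normal trial noise and balanced designs are supported; the
  averaging baseline and the attenuation formula assume a common L.
* No closed-form SIW density is provided (sampling-based only).
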