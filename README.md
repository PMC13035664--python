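# hiercorr

Bayesian hierarchical estimation of correlations across experimental
tasks, with a simulation harness for assessing how the choice of
covariance prior affects the estimates.

## The problem

Individual-difference research asks how people covary across tasks: are
those most susceptible to Stroop interference also most susceptible to
Flanker interference? Each task score is estimated from noisy trials, and
trial noise attenuates the Pearson correlation of averaged scores by

    E(rho_hat) ~ [ s1 s2 / sqrt((s1^2 + t1^2/L)(s2^2 + t2^2/L)) ] * rho

(`s` between-individual SDs, `t` trial SDs, `L` trials per score). A
two-level hierarchical model removes this bias by modeling the noise:

    Y_ijl | theta_ij ~ N(theta_ij, tau_j^2)
    theta_i ~ N_J(mu, Sigma),   Sigma = D(sigma) rho D(sigma)

The cost is that the posterior of `rho` now depends on the prior placed on
`Sigma`. This package implements the three standard choices — inverse
Wishart `IW(S, v)`, scaled inverse Wishart `SIW(v, s)` (an inverse-gamma
mixture of inverse Wisharts), and `LKJ(eta)` on the correlation matrix
with separate half-t priors on the SDs — together with native samplers
(conjugate Gibbs for IW/SIW, adaptive Metropolis-within-Gibbs for LKJ),
classical baselines, prior visualization, and replicate-level simulation
studies of parameter recovery, scale robustness, inclusion robustness, and
two-condition contrast (Stroop-style) designs.

## Worked example

Generate a two-task experiment (200 people, 20 noisy trials per task,
true correlation .7, high trial noise) and compare the averaging baseline
with a hierarchical fit:

```python
import numpy as np
import hiercorr as hc

gt = hc.make_ground_truth("two_task", rho_value=0.7, tau_value=0.5)
rng = np.random.default_rng(1)
theta = hc.sample_true_scores(gt, rng)     # latent true scores
data = hc.sample_trials(gt, theta, rng)    # 200 x 2 x 20 trial table

print(round(np.corrcoef(theta.T)[0, 1], 3))        # best case: 0.64
print(round(hc.average_then_correlate(data).r, 3)) # averaging:  0.302

fit = hc.fit_hier(data, hc.default_iw(2, 0.1),
                  hc.ChainConfig(n_burn=1000, n_keep=3000, seed=7))
lo, hi = fit.rho_interval()
print(f"{fit.rho_mean():.3f} [{lo:.3f}, {hi:.3f}]")  # 0.712 [0.450, 0.906]
```

The averaged-score correlation (0.302) is attenuated to less than half
the true value, almost exactly as the formula above predicts (factor
.444); the hierarchical posterior mean (0.712) recovers the realized
true-score correlation (0.64 in this sample) and its 95% credible
interval covers the population value .7.

The numbered scripts under `analysis/` run the full studies (prior
visualization, manifest-model scale sweep, two-/four-task recovery, prior
scale and inclusion robustness, the SD-prior family sweep, and the
contrast design); each writes its tables under `results/` and accepts
`--replicates` and `--seed` flags. A thin CLI mirrors them:
`hiercorr study --id 1 --prior all --rho .3 --tau .5 --out results/s1`,
`hiercorr prior-viz --family iw --J 3 --out results/priors`, and
`hiercorr fit --data trials.csv --prior lkj --out results/fit` for
user-supplied long-format CSVs.

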