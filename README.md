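# bayesmr

Random-effect Bayesian Mendelian randomization for two heterogeneous
studies, with MCMC imputation of completely missing exposures and
divide-and-combine subset-posterior aggregation for large samples.

## The problem

Mendelian randomization (MR) uses genetic variants as instrumental
variables to estimate the causal effect of an exposure X on an outcome Y in
the presence of unobserved confounding.  Often two studies measure the same
instruments but not the same phenotypes: Study A recorded instruments,
exposures and outcomes, while Study B recorded instruments and outcomes
only.  Conventional two-sample MR throws data away (Study B's outcomes in a
one-sample analysis, or Study A's outcomes in a two-sample analysis) and
ignores that the two studies may not be homogeneous.

`bayesmr` instead models both studies jointly.  Two exposures X1, X2 and two
outcomes Y1, Y2 are linked by linear structural equations with a scalar
latent confounder U ~ N(0,1) per individual:

    X1 | Z, U ~ N(alpha1'Z1 + alpha31'Z3 + delta_x1 U, sigma_x1^2)
    Y1 | X1, U ~ N(beta1 X1 + delta_y1 U,              sigma_y1^2)

(symmetrically for X2, Y2; instruments Z1 act on X1, Z2 on X2, Z3 on both).
Study B's equations gain study-level random intercepts V ~ N(0,1) —
the random effects that absorb between-study heterogeneity — and their own
residual scales.  Study B's missing exposures are treated as unknowns and
imputed inside the MCMC that estimates the causal effects beta1, beta2.  For
large studies, the data can be partitioned into J subsets, fitted in
parallel, and the subset posteriors recombined by recentring around the
grand mean of the subset posterior means — with mean error O_p(1/q) in the
subset size q and variance error o_p(1/n) in the total size n.

A two-sample inverse-variance weighted (IVW) estimator is included as the
conventional benchmark, and a simulation harness reproduces the full
evaluation grid (missing rate x instrument strength x effect size) with the
four metrics mean, sd, coverage and power.

Intended users: biostatisticians and genetic epidemiologists who have
individual-level data from two studies with this missingness pattern, and
methodologists studying Bayesian MR or embarrassingly parallel MCMC.

See `docs/methods.md` for the sampler (an exact conjugate Gibbs scheme with
dedicated moves along the model's non-identified directions), prior choices,
and validation against an independent MCMC engine.

## Worked example

```python
from bayesmr import (SimulationConfig, simulate_combined, fit,
                     MCMCSettings, ivw_for_pair)

cfg = SimulationConfig(n_total=400, missing_rate=0.5,
                       alpha_level=0.3, beta_level=0.3, seed=7)
data, truth = simulate_combined(cfg, replicate_index=0)
print(f"n_A={data.study_a.n}, n_B={data.study_b.n}")

draws = fit(data, settings=MCMCSettings(chains=4, seed=1))
print(draws.summary().loc[["beta1", "beta2", "v_y1", "v_y2"]].round(3))

for pair in (1, 2):
    est = ivw_for_pair(data, pair)
    print(f"IVW pair {pair}: beta_hat={est.beta_hat:.3f}  se={est.se:.3f}")
```

Output:

```
n_A=200, n_B=200
        mean     sd  lower  median  upper   rhat
beta1  0.303  0.006  0.291   0.302  0.314  1.061
beta2  0.301  0.006  0.290   0.301  0.313  1.057
v_y1   0.121  0.308 -0.491   0.124  0.715  1.000
v_y2   0.153  0.302 -0.446   0.153  0.759  1.001
IVW pair 1: beta_hat=0.144  se=0.106
IVW pair 2: beta_hat=0.295  se=0.098
```

Both true causal effects are 0.3 here, with half the sample missing its
exposures.  The Bayesian posterior means recover them to within ~0.003 with
posterior sd 0.006 and split R-hat near 1; the outcome-equation random
intercepts v_y1, v_y2 are estimated with honest uncertainty (their true
values in this replicate were 0.09 and 0.37).  The IVW benchmark, which uses
only Study A for instrument-exposure and only Study B for
instrument-outcome associations, is an order of magnitude noisier
(se ~ 0.1) and attenuated for pair 1 in this replicate — the behaviour the
replicate studies quantify systematically.

Partitioning a large dataset:

```python
from bayesmr import partition, aggregate, kde2d

subsets, plan = partition(data, J=2, seed=0)        # stratified by study
fits = [fit(s, settings=MCMCSettings(chains=2, seed=j))
        for j, s in enumerate(subsets)]             # independent -> parallel
agg = aggregate(fits)                               # recentred mixture
x, y, density = kde2d(agg.pooled("beta1"), agg.pooled("beta2"))
```

A `bayesmr` command-line interface wraps the same functions (`simulate`,
`fit`, `ivw`, `partition`, `study-small`); datasets travel as CSV tables
with columns `study, Z1_1..Z1_L, Z2_1..Z2_K, Z3_1..Z3_M, X1, X2, Y1, Y2`
(empty exposure fields for Study B).

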