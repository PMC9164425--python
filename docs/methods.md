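# Methods

## Model

`bayesmr` estimates the causal effects of two exposures (X1, X2) on two
outcomes (Y1, Y2) from two independent studies that genotyped the same
instruments but differ in what else they measured:

* **Study A** observed instruments, exposures and outcomes;
* **Study B** observed instruments and outcomes only — its exposures are
  entirely missing.

Instruments come in three mutually independent dosage blocks: Z1 (L variants,
instruments X1), Z2 (K variants, instruments X2) and Z3 (M variants, shared
by both exposures).  A scalar latent confounder U ~ N(0, 1) per individual
summarises everything unobserved that affects both exposures and outcomes.
The structural equations are linear with Gaussian residuals; for Study A

    X1 | Z, U ~ N(alpha1'Z1 + alpha31'Z3 + delta_x1 U, sigma_x1A^2)
    Y1 | X1, U ~ N(beta1 X1 + delta_y1 U,              sigma_y1A^2)

(and symmetrically for X2, Y2), while each Study-B equation gains a
study-level random intercept V_* and its own residual scale sigma_*B.  The
V's capture between-study heterogeneity: shifts in the level of exposures or
outcomes that a homogeneous two-sample analysis would silently absorb into
bias.  Genotypes are fixed covariates (no likelihood term on Z); there are no
direct Z-to-Y paths (no pleiotropy) and no cross effects X1-to-Y2 or
X2-to-Y1.

Priors follow the simulation-calibrated choices: every instrument-strength
component alpha ~ N(0, 0.3^2) (individual variants explain little exposure
variance), beta1, beta2 ~ N(0, 10^2), each residual sd sigma ~
Inv-Gamma(3, 2) *on the sd itself*, and each V ~ N(0, 1).  The confounder
loadings delta carry no stated prior in the source material; we use N(0, 1),
matching the scale of the V prior and weakly informative on the scale of the
simulated loadings (delta = 1).  All prior scales are adjustable through
`PriorSpec`.

The "standardised variables" phrasing of the model statement is treated as an
assumption about scale, not a preprocessing step: the generator simulates on
the raw scale of the stated coefficients and no standardisation is applied
before fitting, because the evaluation recovers beta on that raw scale.

## Posterior computation

Missing exposures are unknowns: the posterior is over the structural
parameters, every individual's U, and the Study-B exposures X1*, X2*.
Because the model is linear-Gaussian throughout, `fit` uses an authored Gibbs
data-augmentation sampler with exact conditional draws — imputation and
estimation happen inside one Markov chain:

1. **Study-B exposure scales, marginally.**  sigma_x1B (and sigma_x2B) is
   updated by univariate slice sampling of its conditional with X*
   integrated out: marginally, the Study-B outcome residuals have variance
   beta^2 sigma_xB^2 + sigma_yB^2, which is the only way the data inform
   sigma_xB.  Conditioning on the imputed X* instead creates a feedback loop
   (sigma drives the spread of the imputations that drive sigma) that mixes
   arbitrarily slowly and not at all when beta = 0, where sigma_xB is purely
   prior-identified.
2. **Imputation.**  X1*, X2* are drawn from their normal full conditionals
   (each exposure is the response of its own regression and a covariate of
   the matching outcome regression).
3. **Coefficient blocks.**  Each regression's coefficients — instrument
   strengths, confounder loading and Study-B intercept together — are drawn
   from the conjugate multivariate normal given the residual scales, with
   per-row weights distinguishing the two studies.
4. **Remaining scales.**  The other six sigmas are slice-sampled on
   log(sigma); the Inv-Gamma prior on the sd is not conjugate, and slice
   sampling is tuning-free and exact.
5. **Confounders.**  All U are drawn from their independent normal full
   conditionals.

Two exact non-identified directions of this model defeat coordinate-wise
Gibbs and receive dedicated moves each scan:

* **Latent-level ridge.**  Shifting every X1* by a constant c while moving
  v_x1 to v_x1 + c and v_y1 to v_y1 - beta1 c leaves the likelihood exactly
  unchanged (Study B never observes X1), so only the N(0, V_sd^2) priors tie
  the level down.  The shift c is drawn from its exact Gaussian conditional
  (likewise for the X2 side, and for a joint location shift of the Study-B
  U's with the matching intercept adjustments).  Without these moves the
  chains wander the ridge for thousands of iterations — an external
  cross-check (see below) exhibits exactly this pathology.
* **Sign reflection.**  Negating all four deltas and every U jointly leaves
  the likelihood invariant, so the posterior of the loadings is an exactly
  symmetric two-mode mixture.  A reflection move applies the flip with
  probability 1/2 per scan; each chain then traverses both modes and the
  split R-hat of the deltas reflects real mixing rather than mode
  assignment.  The causal effects beta, the intercepts V and the imputed X*
  are invariant under the reflection; the reported delta posterior is the
  honest symmetric mixture, whose mean is ~0 by construction (the
  identifiable quantity is the magnitude and relative sign pattern).

Defaults: 4 chains, 1000 warmup + 1000 kept iterations, chains seeded from
independent streams of one seed.  Initial values are prior draws shrunk
toward zero by `init_scale` (= 0.1; sigmas jittered around the prior mean on
the log scale), and X* starts at the least-squares prediction from the
instruments fitted on Study A.  Convergence is monitored with the plain
split-chain potential-scale-reduction statistic computed for every
structural parameter, and for the latent U and X* from running split-half
moments (their full trajectories are not stored by default).  Equal-tailed
95% credible intervals use empirical quantiles of the pooled post-warmup
draws.  Chains with zero variance return R-hat 1 by convention.

**Validation.**  The sampler is cross-checked against an independent engine
(JAGS via rjags, which imputes NA responses natively) on a shared simulated
dataset: the test suite asserts that posterior means and sds of the causal
effects and residual scales agree within Monte-Carlo error.  The one
expected disagreement is diagnostic: JAGS's coordinatewise sampler sticks on
the latent-level ridge described above and can report a spuriously tight
intercept posterior, which is precisely the pathology the dedicated ridge
moves remove.

## The IVW comparator

The benchmark is the classic two-sample inverse-variance weighted estimator:
per-instrument exposure associations (gamma_i) from Study A, per-instrument
outcome associations (Gamma_i) from Study B, combined as

    beta_hat = sum_i gamma_i Gamma_i / se(Gamma_i)^2
               / sum_i gamma_i^2 / se(Gamma_i)^2,
    se = (sum_i gamma_i^2 / se(Gamma_i)^2)^(-1/2),

i.e. fixed-effect IVW with first-order weights and a normal-theory CI.  Two
design details were fixed by reproducing the published comparison tables
(all 96 printed IVW metric values match within Monte-Carlo error only under
this combination): each pair uses **its own instrument block only** (Z1 for
pair 1, Z2 for pair 2 — the shared block Z3 is excluded), and the stage
regressions are **marginal**, one simple regression per variant, exactly as
when only GWAS summary statistics are available.  Both choices are exposed:
`include_shared=True` adds Z3 (a valid instrument for either pair in this
model), and `joint=True` uses one multivariable regression per stage, which
conditions each instrument on the others, strengthens stage 1 and visibly
reduces weak-instrument attenuation.  Instruments with constant dosage in
either study are dropped with a logged warning.

## Divide and combine

For large n, the data are randomly split into J subsets, stratified by study
so every subset keeps the full data's missing rate (both study sizes must be
divisible by J; subsets are disjoint, exhaustive and equal-sized).  Each
subset is fitted independently — seeds are derived per subset, so fits can
run serially or in parallel with identical results — and the full-data
posterior is approximated by pooling the subset draws recentred around the
grand mean of the subset posterior means, with each draw's deviation from
its subset mean shrunk by 1/sqrt(J).  The shrinkage is what makes the
aggregate match the full-data posterior in spread as well as location: a
subset sees only q = n/J observations, so its posterior deviations are
~sqrt(J) times the full-data ones, and without the correction the pooled
spread would grow like sqrt(J) — visibly contradicting the theory this
aggregation rests on (mean error O_p(1/q), variance error o_p(1/n)) and the
observed behaviour that partitioned and full-data density contours have the
same size.  The pooled mean equals the grand mean identically, the
aggregate is invariant to subset order, and `scale_correction=False`
recovers the plain recentred mixture.  The correction is first-order exact
for likelihood-identified parameters; the prior-dominated Study-B
intercepts V (whose posterior spread does not shrink with sample size) come
out too narrow in the aggregate, so aggregation is intended for the
structural parameters of interest, above all beta1, beta2.  Each subset fit
estimates its own V; the interaction between study-level intercepts and
partitioning is not otherwise modelled.  Partitioning therefore mainly
risks bias when subsets get small (weak instruments and high missing rates
are the stress case), not extra variance.

Joint posteriors of (beta1, beta2) are visualised with a two-dimensional
Gaussian product-kernel density estimate; per-dimension bandwidths default to
Scott's rule (n^(-1/6) times the draw sd) and are overridable.  The grid
spans the draws padded by three bandwidths, over which the density
integrates to ~1.

## Synthetic data

The generator reproduces the evaluation design: L = K = 15, M = 5; dosages
i.i.d. Binomial(2, 0.3); all alphas share one magnitude (0.1 or 0.3); beta1 =
beta2 in {0, 0.3}; all deltas 1; all sigmas 0.1; V drawn fresh per replicate
from Uniform(-0.5, 0.5), independently for each of the four equations; total
n split as n_B = round(n * missing_rate) (round half up; configurations whose
rounding moves the missing rate by more than 1% are rejected).  Replicates
use counter-based substreams of one base seed, so generation is
order-independent and reproducible.  Closed-form checks pin the generator to
the model: e.g. Var(X1) = 20 * 0.3^2 * 0.42 + 1 + 0.01 = 1.766 and
Cov(X1, Y1) = beta1 Var(X1) + 1 at the strong-instrument settings.

What the generator does *not* emulate about real genetic data: linkage
disequilibrium (instruments are independent), realistic allele-frequency
spectra (one common frequency), pleiotropy, non-Gaussian residuals,
case-control sampling, and missingness mechanisms other than
missing-completely-at-random by study.  Passing tests therefore demonstrate
correctness of the machinery under the stated model, not robustness to these
violations.

## Evaluation harness

`run_small_study` scores estimators over a 12-configuration grid (three
missing rates 20/50/80%, two instrument strengths, zero and non-zero effects)
by four metrics: mean and sd of the point estimates (posterior mean for the
Bayesian fit), coverage of the 95% intervals at the true effect, and power
(fraction of intervals excluding zero), the latter only when the true effect
is non-zero.  Intervals are closed at the endpoints; ties have probability
zero under continuous posteriors.  A replicate whose structural R-hat
exceeds 1.1 is refitted once with doubled iterations and excluded (with a
logged count) if still above.  Reduced replicate counts are first-class for
smoke testing; published-scale runs use 200 replicates.

`run_large_study` simulates a single large dataset, fits the full data and
J-way partitions, and returns the aggregated posteriors and KDE grids per J.

## Problem sizes used by the shipped checks

The test suite and the acceptance script keep single-CPU runtimes modest by
scaled-down but statistically meaningful designs, chosen as the package's
own defaults: the IVW table reproduction runs the full 200 replicates per
configuration (the comparator is cheap); Bayesian replicate checks use 40
replicates at the headline configurations with 2 chains of 500 + 1000
iterations; the convergence gate and the acceptance script fit one dataset
per configuration with 4 chains of 1000 + 2500; the partition-consistency
surrogate uses n = 2,000 with J in {2, 10} over five seeds; and the
partition-concordance check uses n = 5,000 with J in {1, 5, 50} instead of
the full-size n = 50,000.

## Known limitations

* The delta loadings are reported as their symmetric two-mode mixture (mean
  ~0); users wanting a one-mode summary should fold the draws by the sign of
  one loading.
* The Study-B intercepts V are weakly identified (for the exposure equations,
  prior-dominated along the latent-level ridge); their posteriors are honest
  but wide, and only the combinations beta v_x + v_y are sharply informed.
* With sigma values (0.1) deep in the tail of the Inv-Gamma(3, 2) prior, the
  residual-scale posteriors are pulled upward at n = 400; credible intervals
  for beta can be slightly anticonservative at the highest missing rate.
* Fixed-effect IVW assumes no pleiotropy and homogeneous per-instrument
  effects; no MR-Egger or median-based estimators are provided.
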