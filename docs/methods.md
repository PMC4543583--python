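# Methods

## Model

`multinmix` fits hierarchical N-mixture models to community point-count
data in which every detected individual has a capture history: a binary
record of detection/nondetection in each of the `J` observation
intervals of a survey.  Under a constant per-interval detection
probability `p_ik` for species `k` in survey `i`, the sufficient
summary of these histories is the detection-frequency vector
`Y_ik = (Y_ik1..Y_ikJ)`, the number of individuals detected exactly
`j = 1..J` times; conditional on the latent abundance `N_ik` it is
multinomial with binomial cell probabilities
`pi_ikj = C(J,j) p_ik^j (1-p_ik)^(J-j)`.  The `j = 0` cell is
unobservable.

The ecological layer places a multivariate lognormal mixture on the
Poisson rates: `eps_i ~ MVN(0, Sigma)` with unrestricted `K x K`
covariance, and `N_ik ~ Poisson(exp(beta_k' x_ik + eps_ik))`.
Off-diagonal elements of `Sigma` induce positive or negative
cross-species covariance after adjusting for the measured covariates;
they absorb both biological interactions and unmeasured habitat, and
the model cannot distinguish the two.  Covariate sets may differ by
species in both layers.

Marginal moments (used throughout as oracles): with
`tau_ik = exp(mu_ik + sigma_k^2/2)`,

```
E(N_ik)        = tau_ik
Var(N_ik)      = tau_ik + tau_ik^2 (exp(sigma_k^2) - 1)
Cov(N_ik,N_il) = tau_ik tau_il (exp(rho_kl sigma_k sigma_l) - 1)
```

A species with `sigma_k = 0` is purely Poisson and carries no estimable
variance or correlation; setting these parameters to zero would make
`Sigma` singular.  Hence the two-step procedure: only species whose
counts are overdispersed relative to the single-species Poisson
N-mixture enter the multispecies fit.

## Single-species likelihood and fitting

Marginalizing `N` in the single-species (Poisson, no lognormal term)
model factorizes the observed cells into independent Poisson variates
with means `lambda_i pi_ij` (Poisson thinning).  This closed form is
the fitting path; a truncated direct sum over `N` (from `D` to
`D + max(200, lambda + 10 sqrt(lambda))`, extended until the tail term
falls below 1e-12 of the running sum) is kept as an independent route
and the two are cross-checked to 1e-10 in the tests.

Maximum likelihood uses BFGS with the analytic gradient, 5 seeded
random restarts by default (a multimodality guard), and a damped-Newton
polish on a finite-difference Hessian because BFGS occasionally stops
on precision loss a little above the gradient tolerance (sup-norm
1e-6).  A dataset with zero detections sits on the `lambda -> 0`
boundary and is returned flagged instead of optimized.  BIC uses
`n = number of surveys with capture histories` as the sample size; the
observational unit is the survey.

Covariate selection is exhaustive best-subset over the candidate
abundance terms crossed with the detection candidates (`time_block`
counts as one searchable unit of two indicator columns; `day_of_year`
enters linearly after centering and scaling to unit variance).
Exhaustive search removes the path-dependence of stepwise procedures;
with the default pool of 8 abundance scores and 2 detection units it is
1,024 fits per species.  Ties in BIC break toward fewer parameters,
then lexicographic term order.  Non-converged candidates are excluded
and reported.

## Overdispersion screen

The goodness-of-fit statistic is Pearson chi-square over the `J` pooled
detection-frequency cells plus the counts of surveys with total
detections 0, 1, 2 and 3+, with expectations from the fitted model.
The null distribution comes from a parametric bootstrap: each replicate
is simulated from the fitted model and the model is *refitted* to it
(warm-started at the data fit) before the statistic is computed, so
that the null statistics carry the same estimation noise as the
observed one.  Without refitting the screen is anti-conservative.  The
p-value uses the `(1 + #{t* >= t}) / (n_boot + 1)` convention.  The
statistic is a documented, swappable choice; the screen's type-I
calibration at the 5% level is verified by simulation in the acceptance
suite.

## MCMC sampler

Metropolis-within-Gibbs sweep: discrete ±1/±2 random-walk on each
`N_ik` truncated at the observed count `D_ik` (all cells vectorized;
they are conditionally independent); per-survey random-walk on `eps_i`
preconditioned by `chol(Sigma)`; adaptive random-walk Metropolis on
each species' `beta` and `alpha` blocks; and a conjugate
inverse-Wishart Gibbs draw `Sigma | eps ~ IW(nu0 + I, S0 + eps'eps)`.
Two exact reductions keep updates cheap: the `N`-dependent part of the
cell density collapses to
`N log(lambda) - lgamma(N - D + 1) + (N - D) J log(1-p)`, and given `N`
the detection likelihood is `T_ik ~ Binomial(J N_ik, p_ik)` with
`T_ik` the total number of detection events.

Priors: `Normal(0, 10^2)` on every regression coefficient and
`IW(K + 1, identity)` on `Sigma`; both configurable.  Proposal scales
adapt toward ~30% acceptance during burn-in only and are frozen
afterwards.  Initialization: `N = D + 1`, `eps = 0`, `Sigma = I`,
coefficients at zero or at the single-species MLEs (the pipeline passes
the MLEs).  Chains derive their seeds from one master seed via
`SeedSequence` spawning, so runs are bit-reproducible.  Split R-hat and
ESS (arviz) are attached; any R-hat above 1.1 flags the result
non-converged, which is reported, not discarded.

Posterior correlation summaries give, per species pair, the posterior
mean of `rho_kl`, a Monte Carlo standard error by non-overlapping batch
means with batch size `floor(sqrt(n_draws))`, an equal-tailed credible
interval, and a significance flag set when the interval excludes zero
(the Bayesian reading of a 5% two-sided test at the default 95% level).

## Simulator

The simulator draws the full generative chain — covariates, `eps`, `N`,
and per-individual Bernoulli interval histories — and drops undetected
individuals from the observed layer while keeping them in the truth
record.  Defaults emulate the structure of repeated point-count
surveys: abundance covariates are i.i.d. standard-normal PC-like scores
attached to survey locations (real PCA scores are standardized and
mutually uncorrelated), day of year is uniform over a 52-day
breeding-season window, time of day uniform over three morning blocks,
and surveys are the cross product of locations and `n_dates = 3` visit
dates with `J = 4` intervals.  What it deliberately does not emulate:
spatial autocorrelation of habitat, temporal dynamics in abundance
between visits, heaping/recording errors, and misidentification.
Passing tests therefore certify the estimators under the model's own
assumptions, not robustness to these violations.

## Ingest conventions

Input is a three-file CSV layout (observations of individual birds with
interval columns `h1..hJ`, a per-location habitat table, a species-code
list) with a user-editable schema mapping for column names.  Survey
slots are the cross product of locations and dates; rows with a blank
species field mark surveys with no detections.  Surveys lacking
interval-level histories are retained and flagged but excluded from all
likelihood computation, since the model is defined on capture
histories.  Abundance covariates are principal-component scores of the
correlation matrices of the landscape and vegetation measurements
(2 and 6 leading components by default); using correlation rather than
covariance matrices makes the scores invariant to measurement units,
and each component is oriented so its largest-magnitude loading is
positive — a deterministic convention, since eigenvector signs are
otherwise arbitrary.  Time-of-day blocks are half-open `[lo, hi)` with
boundary times assigned to the later block.  Missing covariate values
are refused rather than imputed.

## Pipeline dispositions

Every species ends in exactly one of: `single_species_adequate` (screen
not rejected), `multispecies` (rejected and dense enough to inform a
covariance), or `unfittable_sparse` (rejected but with at most one
individual per survey and detections in fewer than 5% of surveys — such
counts cannot support a covariance estimate; both thresholds are
configurable).  If no species advance, the report completes with an
empty correlation table and an explanatory note.

## Validation study sizes

The acceptance suite and `scripts/acceptance.py` use simulation sizes
chosen to keep each study a few minutes on one core while leaving the
Monte Carlo error well below the decision margins: 1,000 random
likelihood instances; a 3x3x3 grid of `(mu, sigma^2, rho)` at
I = 10,000 for the moment identities, judged against *closed-form*
Monte Carlo SEs (plug-in SE estimates of a variance are biased low
under the heavy-tailed lognormal mixture, exactly when the estimate
itself is low); I = 5,000 for the Poisson limit; 20 replicates of a
K = 3, I = 300 community with 2 chains of 2,500 iterations (1,000
burn-in, thin 2) for correlation CI coverage, scored as the fraction of
all pair-by-replicate intervals covering the truth; 200 Poisson-truth
replicates at I = 245 with 100 bootstrap refits for the screen's type-I
rate; and 50 replicates at 500 surveys with a 5-covariate pool (32
models each, detection fixed at intercept) for BIC selection accuracy.

## Known limitations

- The multispecies sampler is plain random-walk Metropolis within
  Gibbs; for large K or strongly informative data, mixing of `Sigma`
  through `eps` can be slow, and the default chain lengths should be
  increased.
- Frequentist coverage of the correlation credible intervals at
  moderate I runs slightly below nominal (~92-95% at I = 300); exact
  nominal coverage is a posterior, not a sampling, guarantee.
- The Pearson-cell GOF statistic is a stand-in for a fully specified
  omnibus test; its cells pool over surveys and may have low power
  against covariate-dependent misfit.
- The single-file ingest assumes one clock time per survey and ISO
  dates; no geospatial processing or covariate imputation is provided.
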