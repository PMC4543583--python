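# multinmix

Multispecies N-mixture models of correlated abundances for community
point-count surveys with individual capture histories.

## The problem

In a community-level point-count survey an observer records, for every
individual bird detected, which of the J observation intervals of the
survey it was detected in — a per-individual *capture history*.
Abundance inference from such data must deal with two things at once:
individuals are detected imperfectly, and the abundances of different
species may covary (because of biological interactions or habitat
features nobody measured).  `multinmix` is written for quantitative
ecologists who want to estimate habitat effects, detection
probabilities, and a full cross-species correlation matrix from exactly
this kind of data.

## The model

For survey `i = 1..I` and species `k = 1..K`, with `J` intervals per
survey:

- Ecological layer (multivariate Poisson-lognormal):
  `eps_i ~ MVN(0, Sigma)` with an unrestricted `K x K` covariance
  `Sigma` (variances `sigma_k^2`, correlations `rho_kl`, positive *or*
  negative), and `N_ik | eps_i ~ Poisson(lambda_ik)` with
  `log lambda_ik = mu_ik + eps_ik`, `mu_ik = beta_k' x_ik`.
- Observation layer: the detection frequencies
  `Y_ik = (Y_ik1..Y_ikJ)` (number of individuals of species `k`
  detected exactly `j` times in survey `i`) are
  `Multinomial(N_ik, pi_ik1..pi_ikJ)` with binomial cell probabilities
  `pi_ikj = C(J,j) p_ik^j (1-p_ik)^(J-j)` and
  `logit p_ik = alpha_k' w_ik`.

Marginally `E(N_ik) = tau_ik`, `Var(N_ik) = tau_ik + tau_ik^2
(exp(sigma_k^2) - 1)` and `Cov(N_ik, N_il) = tau_ik tau_il
(exp(rho_kl sigma_k sigma_l) - 1)` with `tau_ik = exp(mu_ik +
sigma_k^2/2)` — so a species without extra-Poisson variation carries no
estimable correlation, which motivates the package's two-step analysis:

1. Fit single-species Poisson N-mixture models, choosing abundance
   (PCA-score) and detection (day-of-year, time-of-day) covariates by
   exhaustive BIC search, and screen each species' selected model for
   overdispersion with a parametric bootstrap.
2. Fit the species that fail the screen (and are not too sparse)
   jointly with the multispecies model by MCMC, and summarize the
   posterior of the correlation matrix (mean, Monte Carlo standard
   error by batch means, credible interval, significance flag).

## Worked example

Simulate a 5-species community in which two species share strong
lognormal noise (correlation 0.7) while three are effectively Poisson,
then run the full pipeline:

```python
import numpy as np
from multinmix import SimulationConfig, simulate, write_fixture, run_pipeline

Sigma = np.diag([1.0, 1.0, 1e-4, 1e-4, 1e-4])
Sigma[0, 1] = Sigma[1, 0] = 0.7
cfg = SimulationConfig(n_locations=50, n_dates=3, K=5, J=4,
                       beta=[[0.8]] * 5, alpha=[[0.0]] * 5,
                       Sigma=Sigma, n_covariates=1, seed=31)
paths = write_fixture(simulate(cfg), "example_data")

report = run_pipeline(dict(
    observations=str(paths["observations"]), habitat=str(paths["habitat"]),
    species=str(paths["species"]), covariate_mode="direct",
    direct_cols=["X1"], candidate_detection_terms=[], n_restarts=2,
    n_boot=100, mcmc_chains=2, mcmc_iter=800, mcmc_burn=400, mcmc_thin=2,
    seed=0))
print(report.disposition_counts())
print(report.correlation_table[["species_a", "species_b", "mean", "mcse",
                                "significant"]])
```

prints

```
{'single_species_adequate': 3, 'multispecies': 2}
  species_a species_b      mean      mcse  significant
0      SP01      SP02  0.591597  0.009603         True
```

i.e. the three Poisson species are adequately described by their
single-species models, the two noisy species advance to the joint fit,
and the posterior mean of their abundance correlation (0.59, MCSE
0.010) recovers the generating value 0.7 with a credible interval that
excludes zero.

The same steps are available from a shell via the `multinmix` command
(`simulate`, `ingest`, `fit-single`, `fit-multi`, `run-all`).

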