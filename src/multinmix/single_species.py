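"""Single-species N-mixture model on detection frequencies.

The model: latent abundance N_i ~ Poisson(lambda_i) with
log(lambda_i) = beta' x_i, and, conditional on N_i, the detection
frequencies Y_i1..Y_iJ (number of individuals detected exactly j times)
are Multinomial(N_i, pi_1..pi_J) with binomial cell probabilities
pi_j = C(J, j) p_i^j (1-p_i)^(J-j) and logit(p_i) = alpha' w_i.

Marginalizing N by Poisson thinning, the observed cells are independent
Poisson variates with means lambda_i * pi_j — the closed form used for
fitting.  A truncated direct summation over N is provided as a second,
independent route to the same likelihood.

This Poisson (no lognormal residual) model is the step-1 null of the
two-step procedure: species whose counts it fits adequately stop here;
species it rejects for overdispersion advance to the multispecies
Poisson-lognormal model, which is only identifiable in the presence of
extra-Poisson variation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import binom, poisson

__all__ = [
    "cell_probability",
    "survey_loglik",
    "build_design",
    "FitResult",
    "fit_mle",
    "SelectedModel",
    "bic_select",
    "GofResult",
    "gof_overdispersion",
    "pearson_statistic",
    "simulate_frequencies",
]

_LOG_EPS = 1e-300


def cell_probability(p: float, J: int, j: int) -> float:
    """Binomial probability that one individual is detected exactly j of J times."""
    if not 0 <= j <= J:
        raise ValueError(f"detection frequency j={j} outside 0..J={J}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("per-interval detection probability must lie in [0, 1]")
    return float(binom.pmf(j, J, p))


def _cell_probs(p, J):
    """pi_0..pi_J for scalar or vector p; shape (..., J+1)."""
    p = np.asarray(p, dtype=float)
    j = np.arange(J + 1)
    return binom.pmf(j, J, p[..., None])


def survey_loglik(y_row, lam: float, p: float, J: int | None = None,
                  method: str = "thinning") -> float:
    """Marginal log-likelihood of one survey's detection-frequency row.

    ``method="thinning"`` uses the exact closed form (independent Poisson
    cells with means lambda*pi_j); ``method="truncated"`` sums the
    Poisson(N) x Multinomial(Y | N) joint over N >= D directly, extending
    the truncation point until the tail is negligible.  The two must
    agree to ~1e-10; the sum serves as the independent check.
    """
    y = np.asarray(y_row)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y_row, dtype=float)
        if not np.allclose(yf, np.round(yf)):
            raise TypeError("detection frequencies must be integers")
        y = np.round(yf).astype(np.int64)
    if J is None:
        J = len(y)
    if len(y) != J:
        raise ValueError("frequency row length must equal J")
    if (y < 0).any():
        raise ValueError("detection frequencies must be non-negative")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    pi = _cell_probs(p, J)  # pi[0..J]
    D = int(y.sum())
    if lam == 0:
        return 0.0 if D == 0 else -np.inf

    if method == "thinning":
        mu = lam * pi[1:]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(y > 0, y * np.log(np.maximum(mu, _LOG_EPS)), 0.0)
        if ((y > 0) & (mu == 0)).any():
            return -np.inf
        return float(terms.sum() - mu.sum() - gammaln(y + 1).sum())

    if method != "truncated":
        raise ValueError(f"unknown method {method!r}")

    # log Multinomial coefficient pieces independent of N
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
    if ((y > 0) & (pi[1:] == 0)).any():
        return -np.inf
    base = float((y * np.where(y > 0, log_pi[1:], 0.0)).sum() - gammaln(y + 1).sum())
    n_hi = D + max(200, int(np.ceil(lam + 10 * np.sqrt(lam))))
    log_terms = []
    running = -np.inf
    n = D
    while True:
        m = n - D
        if pi[0] == 0.0:
            lp0 = 0.0 if m == 0 else -np.inf
        else:
            lp0 = m * log_pi[0]
        lt = (poisson.logpmf(n, lam) + gammaln(n + 1) - gammaln(m + 1) + lp0 + base)
        log_terms.append(lt)
        running = np.logaddexp(running, lt)
        n += 1
        if n > n_hi:
            # extend until the next term is < 1e-12 of the running sum
            if lt - running < np.log(1e-12):
                break
    return float(logsumexp(log_terms))


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def build_design(covariates: pd.DataFrame, terms) -> np.ndarray:
    """Intercept-first design matrix from named covariate columns.

    ``"time_block"`` expands to two indicators (middle, late) treated as
    one unit in model search; every other term is a single numeric
    column.  The result must be full rank.
    """
    cols = [np.ones(len(covariates))]
    for t in terms:
        if t == "time_block":
            tb = covariates["time_block"].astype(str)
            cols.append((tb == "middle").to_numpy(float))
            cols.append((tb == "late").to_numpy(float))
        else:
            cols.append(covariates[t].to_numpy(float))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design for terms {list(terms)}")
    return X


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

def _nll_and_grad(theta, Y, X, W, J):
    """Negative marginal log-likelihood and analytic gradient.

    Uses the thinning form: Y_ij ~ indep Poisson(lambda_i pi_ij).
    """
    nb = X.shape[1]
    beta, alpha = theta[:nb], theta[nb:]
    eta = np.clip(X @ beta, -30, 30)
    lam = np.exp(eta)
    p = expit(np.clip(W @ alpha, -30, 30))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    pi = _cell_probs(p, J)  # (I, J+1)
    mu = lam[:, None] * pi[:, 1:]
    ll = (np.where(Y > 0, Y * np.log(np.maximum(mu, _LOG_EPS)), 0.0).sum()
          - mu.sum() - gammaln(Y + 1).sum())
    D = Y.sum(axis=1)
    q = 1.0 - pi[:, 0]  # detected-at-least-once probability
    grad_beta = X.T @ (D - lam * q)
    j = np.arange(1, J + 1)
    score_p = (Y * (j[None, :] / p[:, None] - (J - j)[None, :] / (1 - p[:, None]))).sum(axis=1)
    score_p -= lam * J * (1 - p) ** (J - 1)
    grad_alpha = W.T @ (score_p * p * (1 - p))
    g = np.concatenate([grad_beta, grad_alpha])
    return -ll, -g


def _newton_polish(x, f, g, Y, X, W, J, tol: float = 1e-8, max_iter: int = 10):
    """Sharpen a BFGS solution with damped Newton steps.

    BFGS occasionally stops on precision loss with a gradient a few
    orders above the convergence tolerance; a handful of Newton steps
    on a finite-difference Hessian of the analytic gradient fixes that.
    """
    n = x.size
    for _ in range(max_iter):
        if np.max(np.abs(g)) < tol:
            break
        H = np.empty((n, n))
        h = 1e-6
        for m in range(n):
            xp = x.copy()
            xp[m] += h
            H[:, m] = (_nll_and_grad(xp, Y, X, W, J)[1] - g) / h
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(n), -g)
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1):
            f2, g2 = _nll_and_grad(x + damp * step, Y, X, W, J)
            if f2 <= f + 1e-12:
                x, f, g = x + damp * step, f2, g2
                improved = True
                break
        if not improved:
            break
    return x, f, g


@dataclass
class FitResult:
    """Maximum-likelihood fit of the single-species Poisson N-mixture model."""

    beta: np.ndarray
    alpha: np.ndarray
    abundance_terms: tuple
    detection_terms: tuple
    loglik: float
    n_params: int
    n_surveys: int
    converged: bool
    bic: float
    boundary: bool = False
    grad_norm: float = np.nan

    @property
    def estimates(self) -> dict:
        return {"beta": self.beta.tolist(), "alpha": self.alpha.tolist()}


def fit_mle(Y: np.ndarray, X: np.ndarray, W: np.ndarray, J: int | None = None,
            abundance_terms=(), detection_terms=(), n_restarts: int = 5,
            seed: int = 0, grad_tol: float = 1e-6) -> FitResult:
    """Fit by quasi-Newton maximization with seeded random restarts.

    ``Y`` is the (I, J) frequency matrix of one species; ``X``/``W`` the
    intercept-first abundance and detection designs.  A dataset with no
    detections at all sits on the lambda -> 0 boundary and is returned
    flagged rather than optimized.
    """
    Y = np.asarray(Y)
    I, Jc = Y.shape
    if J is None:
        J = Jc
    n_params = X.shape[1] + W.shape[1]
    if Y.sum() == 0:
        # MLE on the boundary: lambda-hat -> 0, loglik -> 0
        return FitResult(beta=np.full(X.shape[1], -np.inf), alpha=np.zeros(W.shape[1]),
                         abundance_terms=tuple(abundance_terms),
                         detection_terms=tuple(detection_terms),
                         loglik=0.0, n_params=n_params, n_surveys=I,
                         converged=False, bic=np.inf, boundary=True)
    rng = np.random.default_rng(seed)
    D = Y.sum(axis=1)
    j = np.arange(1, J + 1)
    # moment-style start: detection rate from mean per-individual frequency
    mean_freq = (Y * j).sum() / max(Y.sum(), 1)
    p0 = np.clip(mean_freq / J, 0.05, 0.95)
    lam0 = max(D.mean() / (1 - (1 - p0) ** J), 1e-3)
    start = np.zeros(n_params)
    start[0] = np.log(lam0)
    start[X.shape[1]] = np.log(p0 / (1 - p0))

    best = None
    for r in range(max(1, n_restarts)):
        x0 = start if r == 0 else start + rng.normal(scale=0.5, size=n_params)
        res = minimize(_nll_and_grad, x0, args=(Y, X, W, J), jac=True,
                       method="BFGS", options={"gtol": 1e-9, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    x, f, g = _newton_polish(best.x, best.fun, best.jac, Y, X, W, J)
    best.x, best.fun, best.jac = x, f, g
    gnorm = float(np.max(np.abs(best.jac)))
    converged = bool(np.isfinite(best.fun)) and gnorm < grad_tol
    ll = -float(best.fun)
    bic = -2.0 * ll + n_params * np.log(I)
    nb = X.shape[1]
    return FitResult(beta=best.x[:nb], alpha=best.x[nb:],
                     abundance_terms=tuple(abundance_terms),
                     detection_terms=tuple(detection_terms),
                     loglik=ll, n_params=n_params, n_surveys=I,
                     converged=converged, bic=bic, grad_norm=gnorm)


def fitted_rates(fit: FitResult, X: np.ndarray, W: np.ndarray):
    """(lambda_i, p_i) implied by a fit."""
    lam = np.exp(np.clip(X @ fit.beta, -300, 30))
    p = expit(W @ fit.alpha)
    return lam, p


# ---------------------------------------------------------------------------
# BIC best-subset selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedModel:
    abundance_terms: tuple
    detection_terms: tuple
    fit: FitResult
    table: pd.DataFrame  # one row per candidate: terms, bic, loglik, converged
    excluded: list = field(default_factory=list)  # non-converged candidates


def bic_select(Y: np.ndarray, covariates: pd.DataFrame,
               candidate_abundance_terms, candidate_detection_terms=("day_of_year", "time_block"),
               J: int | None = None, n_restarts: int = 5, seed: int = 0) -> SelectedModel:
    """Exhaustive best-subset search minimizing BIC.

    Every subset of the abundance candidates is crossed with every
    subset of the detection candidates (``time_block`` counting as one
    searchable unit of two indicator columns).  Non-converged fits are
    excluded from the comparison and reported.  Ties are broken by fewer
    parameters, then lexicographic term order.
    """
    cand_a = list(candidate_abundance_terms)
    cand_d = list(candidate_detection_terms)
    rows = []
    fits = {}
    excluded = []
    for ra in range(len(cand_a) + 1):
        for sub_a in itertools.combinations(cand_a, ra):
            X = build_design(covariates, sub_a)
            for rd in range(len(cand_d) + 1):
                for sub_d in itertools.combinations(cand_d, rd):
                    W = build_design(covariates, sub_d)
                    fit = fit_mle(Y, X, W, J=J, abundance_terms=sub_a,
                                  detection_terms=sub_d, n_restarts=n_restarts,
                                  seed=seed)
                    key = (sub_a, sub_d)
                    fits[key] = fit
                    rows.append({"abundance_terms": sub_a, "detection_terms": sub_d,
                                 "n_params": fit.n_params, "loglik": fit.loglik,
                                 "bic": fit.bic, "converged": fit.converged})
                    if not fit.converged:
                        excluded.append(key)
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate model converged")
    ok = ok.sort_values(
        by=["bic", "n_params", "abundance_terms", "detection_terms"],
        key=lambda s: s.map(str) if s.dtype == object else s,
    )
    top = ok.iloc[0]
    key = (tuple(top["abundance_terms"]), tuple(top["detection_terms"]))
    return SelectedModel(abundance_terms=key[0], detection_terms=key[1],
                         fit=fits[key], table=table, excluded=excluded)


# ---------------------------------------------------------------------------
# Goodness of fit / overdispersion screen
# ---------------------------------------------------------------------------

def simulate_frequencies(lam, p, J: int, rng) -> np.ndarray:
    """Draw an (I, J) frequency matrix from the fitted thinning model."""
    lam = np.asarray(lam, dtype=float)
    p = np.asarray(p, dtype=float)
    pi = _cell_probs(p, J)[:, 1:]
    return rng.poisson(lam[:, None] * pi)


def pearson_statistic(Y: np.ndarray, lam, p, J: int) -> float:
    """Pearson chi-square on pooled frequency cells plus survey-total cells.

    Cells: the J pooled detection-frequency counts (number of individuals
    detected exactly j times, summed over surveys), plus the counts of
    surveys whose total detections are 0, 1, 2, and 3+.  Expected values
    come from the fitted model; cells with negligible expectation are
    skipped.
    """
    lam = np.asarray(lam, dtype=float)
    p = np.asarray(p, dtype=float)
    pi = _cell_probs(p, J)
    mu = lam[:, None] * pi[:, 1:]
    obs_j = Y.sum(axis=0).astype(float)
    exp_j = mu.sum(axis=0)
    D = Y.sum(axis=1)
    rate = lam * (1 - pi[:, 0])  # D_i ~ Poisson(rate_i)
    exp_d = np.empty(4)
    pmf01 = [poisson.pmf(c, rate) for c in (0, 1, 2)]
    exp_d[0] = pmf01[0].sum()
    exp_d[1] = pmf01[1].sum()
    exp_d[2] = pmf01[2].sum()
    exp_d[3] = (1 - pmf01[0] - pmf01[1] - pmf01[2]).sum()
    obs_d = np.array([(D == 0).sum(), (D == 1).sum(), (D == 2).sum(),
                      (D >= 3).sum()], dtype=float)
    O = np.concatenate([obs_j, obs_d])
    E = np.concatenate([exp_j, exp_d])
    keep = E > 1e-8
    return float((((O - E) ** 2) / E)[keep].sum())


@dataclass
class GofResult:
    statistic_observed: float
    statistic_null: np.ndarray
    p_value: float
    overdispersed: bool
    level: float


def gof_overdispersion(fit: FitResult, Y: np.ndarray, X: np.ndarray, W: np.ndarray,
                       J: int | None = None, n_boot: int = 100, seed: int = 0,
                       level: float = 0.05, refit: bool = True) -> GofResult:
    """Parametric-bootstrap goodness-of-fit screen for overdispersion.

    Simulates ``n_boot`` datasets from the fitted model, refits the model
    to each replicate (warm-started at the data fit, so the null
    statistic has the same estimation noise as the observed one), and
    compares Pearson statistics.  ``p_value`` is the upper-tail
    proportion with the +1 continuity correction; the species is flagged
    overdispersed when it falls below ``level``.
    """
    import warnings

    if not fit.converged:
        raise ValueError("goodness-of-fit screen requires a converged fit")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse bootstrap p-value", stacklevel=2)
    Y = np.asarray(Y)
    if J is None:
        J = Y.shape[1]
    rng = np.random.default_rng(seed)
    lam, p = fitted_rates(fit, X, W)
    t_obs = pearson_statistic(Y, lam, p, J)
    t_null = np.empty(n_boot)
    warm = np.concatenate([fit.beta, fit.alpha])
    for b in range(n_boot):
        Yb = simulate_frequencies(lam, p, J, rng)
        if refit and Yb.sum() > 0:
            res = minimize(_nll_and_grad, warm, args=(Yb, X, W, J), jac=True,
                           method="BFGS", options={"gtol": 1e-9, "maxiter": 300})
            nb = X.shape[1]
            lam_b = np.exp(np.clip(X @ res.x[:nb], -300, 30))
            p_b = expit(W @ res.x[nb:])
        else:
            lam_b, p_b = lam, p
        t_null[b] = pearson_statistic(Yb, lam_b, p_b, J)
    p_value = (1.0 + (t_null >= t_obs).sum()) / (n_boot + 1.0)
    return GofResult(statistic_observed=t_obs, statistic_null=t_null,
                     p_value=float(p_value), overdispersed=bool(p_value < level),
                     level=level)
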