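"""Stochastic frontier regression of DEA input slacks on environment.

Stage 2 of the improved three-stage DEA: each input's slack vector is
regressed on the environmental variables with the composed error
``eps = v + u`` of a cost frontier, where ``v ~ N(0, sigma_v^2)`` is
symmetric statistical noise and ``u ~ N+(0, sigma_u^2)`` is one-sided
managerial inefficiency. The variance share ``gamma = sigma_u^2 /
(sigma_u^2 + sigma_v^2)`` measures how much of the composed error is
inefficiency. After maximum-likelihood estimation, the JLMS conditional
expectation ``E[u | eps]`` separates inefficiency from noise, and each
DMU's inputs are raised to the footing of the worst observed environment
and worst observed luck, so that stage-3 scores reflect management alone.

Parameterisation: the likelihood is maximised over ``(beta, log sigma^2,
logit gamma)`` from multiple starts seeded at the OLS solution, because
half-normal frontier likelihoods can be flat or multimodal at small n.
The Gaussian OLS fit is the exact ``gamma -> 0`` limit and is always kept
as a candidate, so the reported log-likelihood never falls below the OLS
log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["SlackRegressionData", "SFAFit", "JLMSEstimates", "LRTestResult",
           "fit_sfa_halfnormal", "jlms_inefficiency", "lr_test_gamma",
           "adjust_inputs"]

_LOGIT_CAP = 16.0  # keeps gamma in (7e-8, 1 - 7e-8) during optimisation


@dataclass(frozen=True)
class SlackRegressionData:
    """Slacks of one input across DMUs plus the environment design matrix.

    ``Z`` must include the intercept column. Stage-1 slacks are
    non-negative by construction; the likelihood itself places no sign
    restriction on the dependent variable.
    """

    S: np.ndarray
    Z: np.ndarray
    input_label: str = ""

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "Z", Z)
        n, k = Z.shape
        if S.shape != (n,):
            raise ValueError("S and Z row counts disagree")


@dataclass(frozen=True)
class SFAFit:
    beta: np.ndarray
    sigma2: float
    gamma: float
    loglik: float
    ols_loglik: float
    converged: bool
    input_label: str = ""

    @property
    def sigma_u(self) -> float:
        return math.sqrt(self.gamma * self.sigma2)

    @property
    def sigma_v(self) -> float:
        return math.sqrt((1.0 - self.gamma) * self.sigma2)


@dataclass(frozen=True)
class JLMSEstimates:
    u_hat: np.ndarray
    v_hat: np.ndarray
    eps: np.ndarray


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    critical_value: float
    p_value: float
    reject: bool
    level: float


def _ols(S, Z):
    beta, *_ = np.linalg.lstsq(Z, S, rcond=None)
    resid = S - Z @ beta
    n = S.size
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        raise ValueError("slack vector has zero variance: frontier degenerate")
    loglik = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
    return beta, sigma2, loglik


def _negloglik(theta, S, Z):
    """Negative log-likelihood of the half-normal cost frontier.

    For eps = v + u:  ln L = sum[ ln 2 - ln sigma + ln phi(eps/sigma)
                                  + ln Phi(eps * lam / sigma) ].
    """
    k = Z.shape[1]
    beta = theta[:k]
    sigma2 = math.exp(min(theta[k], 60.0))
    zg = min(max(theta[k + 1], -_LOGIT_CAP), _LOGIT_CAP)
    gamma = special.expit(zg)
    lam = math.sqrt(gamma / (1.0 - gamma))
    sigma = math.sqrt(sigma2)
    eps = S - Z @ beta
    z = eps / sigma
    ll = (S.size * (math.log(2.0) - math.log(sigma) - 0.5 * math.log(2.0 * math.pi))
          - 0.5 * float(z @ z)
          + float(np.sum(special.log_ndtr(lam * z))))
    return -ll


def fit_sfa_halfnormal(data: SlackRegressionData) -> SFAFit:
    """Maximum-likelihood fit of the half-normal slack frontier.

    Multi-start over gamma in {0.1, 0.5, 0.9} from the OLS solution (with
    the intercept shifted by the implied mean inefficiency
    ``sigma_u sqrt(2/pi)``), plus the OLS (gamma = 0) candidate itself.
    """
    S, Z = data.S, data.Z
    n, k = Z.shape
    if n <= k + 2:
        raise ValueError(f"n = {n} observations cannot identify {k} "
                         "coefficients plus two variance parameters")
    beta_ols, s2_ols, ll_ols = _ols(S, Z)
    # identify the intercept column, if any, to absorb E[u]
    const_cols = [j for j in range(k) if np.ptp(Z[:, j]) == 0 and Z[0, j] != 0]

    best = None
    best_converged = False
    for g0 in (0.1, 0.5, 0.9):
        # method-of-moments style start: match the OLS residual variance
        s2_0 = s2_ols / (1.0 - g0 * 2.0 / math.pi)
        beta0 = beta_ols.copy()
        mean_u = math.sqrt(g0 * s2_0) * math.sqrt(2.0 / math.pi)
        if const_cols:
            beta0[const_cols[0]] -= mean_u / Z[0, const_cols[0]]
        theta0 = np.concatenate([beta0, [math.log(s2_0), special.logit(g0)]])
        res = optimize.minimize(_negloglik, theta0, args=(S, Z), method="BFGS",
                                options={"maxiter": 500})
        res2 = optimize.minimize(
            _negloglik, res.x, args=(S, Z), method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-9},
        )
        cand, ok = (res2, res2.success) if res2.fun <= res.fun else (res, res.success)
        if best is None or cand.fun < best.fun:
            best, best_converged = cand, bool(ok)

    ll_best = -best.fun
    if ll_best <= ll_ols:  # boundary solution: no evidence of inefficiency
        return SFAFit(beta=beta_ols, sigma2=s2_ols, gamma=0.0,
                      loglik=ll_ols, ols_loglik=ll_ols, converged=True,
                      input_label=data.input_label)
    beta = best.x[:k]
    sigma2 = float(math.exp(best.x[k]))
    gamma = float(special.expit(min(max(best.x[k + 1], -_LOGIT_CAP), _LOGIT_CAP)))
    return SFAFit(beta=beta, sigma2=sigma2, gamma=gamma, loglik=float(ll_best),
                  ols_loglik=float(ll_ols), converged=best_converged,
                  input_label=data.input_label)


def jlms_inefficiency(fit: SFAFit, data: SlackRegressionData) -> JLMSEstimates:
    """JLMS conditional inefficiency ``E[u | eps]`` per DMU.

    With ``sigma = sqrt(sigma_u^2 + sigma_v^2)`` and
    ``lam = sigma_u / sigma_v``:

        E[u | eps] = (lam sigma / (1 + lam^2)) [phi(z)/Phi(z) + z],
        z = eps lam / sigma.

    The Mills ratio ``phi/Phi`` is evaluated through ``log_ndtr`` so the
    formula stays finite for arbitrarily negative ``z``. The noise part
    is recovered as ``v_hat = eps - u_hat``.
    """
    eps = data.S - data.Z @ fit.beta
    if fit.gamma <= 0.0:
        return JLMSEstimates(u_hat=np.zeros_like(eps), v_hat=eps.copy(), eps=eps)
    sigma = math.sqrt(fit.sigma2)
    lam = fit.sigma_u / fit.sigma_v
    z = eps * lam / sigma
    mills = np.exp(stats.norm.logpdf(z) - special.log_ndtr(z))
    u_hat = (lam * sigma / (1.0 + lam ** 2)) * (mills + z)
    u_hat = np.maximum(u_hat, 0.0)
    return JLMSEstimates(u_hat=u_hat, v_hat=eps - u_hat, eps=eps)


def lr_test_gamma(fit: SFAFit, level: float = 0.01) -> LRTestResult:
    """Likelihood-ratio test of gamma = 0 (no one-sided inefficiency).

    Because gamma = 0 lies on the boundary of the parameter space, the
    statistic ``LR = 2 (lnL - lnL_OLS)`` follows the equal mixture
    ``(1/2) chi2_0 + (1/2) chi2_1`` under the null, so the critical value
    at level alpha is the upper-2*alpha quantile of chi2_1.
    """
    lr = max(2.0 * (fit.loglik - fit.ols_loglik), 0.0)
    crit = float(stats.chi2.isf(2.0 * level, df=1))
    p = 0.5 * float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return LRTestResult(statistic=lr, critical_value=crit, p_value=p,
                        reject=lr > crit, level=level)


def adjust_inputs(X: np.ndarray, fits: list, datasets: list,
                  jlms: list) -> np.ndarray:
    """Raise every DMU's inputs to the worst environment and worst luck.

    For input *i* and DMU *j*:

        X^A_ij = X_ij + [max_j f(Z_j; beta_i) - f(Z_j; beta_i)]
                       + [max_j v_ij - v_ij]

    with ``f(Z; beta) = Z beta`` the fitted environmental slack and
    ``v`` the JLMS noise estimate. Both brackets are non-negative, so
    adjusted inputs never fall below observed inputs; the DMU facing the
    worst environment and worst luck is left untouched. An entry of
    ``None`` in ``fits`` carries that input through unadjusted (used when
    the slack regression is degenerate).
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if not (len(fits) == len(jlms) == len(datasets) == m):
        raise ValueError("need one fit/dataset/JLMS per input row")
    XA = X.copy()
    for i in range(m):
        if fits[i] is None:
            continue
        f = datasets[i].Z @ fits[i].beta
        v = jlms[i].v_hat
        XA[i] = X[i] + (f.max() - f) + (v.max() - v)
    return XA
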