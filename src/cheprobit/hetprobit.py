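"""Weighted maximum-likelihood probit and multiplicative heteroskedastic probit.

The homoscedastic probit models a binary outcome ``c`` as

    Pr(c_i = 1) = Phi(y_i' beta)

with ``Phi`` the standard-normal CDF.  The multiplicative heteroskedastic
(location-scale) probit relaxes the unit-variance assumption by letting the
latent error's standard deviation vary across observations as

    sigma_i = exp(x_i' tau),     Pr(c_i = 1) = Phi(y_i' beta / exp(x_i' tau)),

where ``x_i`` is a vector of variance covariates *without* an intercept
(exp(0) = 1 pins the scale and identifies ``beta``).  Both models are fitted
by maximizing the sampling-weighted log-likelihood

    lnL = sum_{c_i=1} w_i ln Phi(z_i) + sum_{c_i=0} w_i ln(1 - Phi(z_i)),

z_i = y_i' beta / exp(x_i' tau), with an analytic gradient and a quasi-Newton
optimizer followed by Newton polishing on the exact first-order conditions.
The coefficient covariance is the inverse observed information by default; a
Huber sandwich estimator is available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "FitResult",
    "EstimationError",
    "ConfigurationError",
    "build_design",
    "predict_prob",
    "loglik",
    "score",
    "hessian",
    "fit_probit",
    "fit_hetprobit",
    "sandwich_vcov",
]

logger = logging.getLogger("cheprobit")

INTERCEPT = "intercept"

#: convergence bound on the weight-normalized score (gradient of lnL / sum w)
SCORE_TOL = 1e-6
#: relative log-likelihood change bound between Newton polish steps
LOGLIK_RTOL = 1e-10
MAX_ITER = 200
#: |index| beyond which one outcome class is treated as perfectly predicted
SEPARATION_INDEX = 30.0


class EstimationError(RuntimeError):
    """Raised when a model cannot be estimated (degenerate outcome, separation...)."""


class ConfigurationError(ValueError):
    """Raised when a model specification refers to data that does not exist."""


@dataclass(frozen=True)
class ModelSpec:
    """Names of the outcome, mean covariates, variance covariates and weight column.

    The intercept is prepended to the mean equation automatically and must not
    be listed.  The variance equation carries no intercept (identification).
    Variance covariates may overlap mean covariates; in the motivating
    application total expenditure enters both.
    """

    outcome: str
    mean_covariates: tuple[str, ...]
    variance_covariates: tuple[str, ...] = ()
    weight: str | None = None

    def __post_init__(self) -> None:
        covs = set(self.mean_covariates) | set(self.variance_covariates)
        if self.outcome in covs:
            raise ConfigurationError(
                f"outcome {self.outcome!r} also appears among the covariates"
            )
        if len(set(self.mean_covariates)) != len(self.mean_covariates):
            raise ConfigurationError("duplicate mean covariate names")
        if len(set(self.variance_covariates)) != len(self.variance_covariates):
            raise ConfigurationError("duplicate variance covariate names")


@dataclass
class DesignMatrices:
    """Numeric design for one fit: mean design Y (intercept first), variance
    design X (possibly zero columns), binary outcome c and positive weights w."""

    Y: np.ndarray
    X: np.ndarray
    c: np.ndarray
    w: np.ndarray
    mean_names: tuple[str, ...]
    var_names: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.Y.shape[0]

    @property
    def k(self) -> int:
        return self.Y.shape[1]

    @property
    def m(self) -> int:
        return self.X.shape[1]


@dataclass
class FitResult:
    """Maximum-likelihood estimates with covariance and convergence metadata.

    ``vcov`` stacks the parameters as (beta, tau); ``se`` is its diagonal
    square root in the same order.
    """

    beta: np.ndarray
    tau: np.ndarray
    loglik: float
    vcov: np.ndarray
    converged: bool
    n_obs: int
    n_iterations: int
    model_kind: str  # "probit" | "hetprobit"
    mean_names: tuple[str, ...] = ()
    var_names: tuple[str, ...] = ()
    message: str = ""

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.tau])

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.vcov), 0.0, None))

    def to_dict(self) -> dict:
        names = list(self.mean_names) + [f"ln_sigma:{v}" for v in self.var_names]
        se = self.se
        return {
            "model": self.model_kind,
            "coefficients": {n: float(v) for n, v in zip(names, self.params)},
            "standard_errors": {n: float(v) for n, v in zip(names, se)},
            "loglik": float(self.loglik),
            "vcov": self.vcov.tolist(),
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
            "n_iterations": int(self.n_iterations),
        }


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(data: pd.DataFrame, spec: ModelSpec) -> DesignMatrices:
    """Assemble :class:`DesignMatrices` from a table per a :class:`ModelSpec`.

    Rows with any missing value among the used columns are dropped with a
    logged count.  The outcome must contain both classes; the intercept column
    is prepended to the mean design.
    """
    used = [spec.outcome, *spec.mean_covariates, *spec.variance_covariates]
    if spec.weight is not None:
        used.append(spec.weight)
    missing_cols = [c for c in dict.fromkeys(used) if c not in data.columns]
    if missing_cols:
        raise ConfigurationError(f"columns not found in data: {missing_cols}")

    sub = data[list(dict.fromkeys(used))]
    keep = ~sub.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing values", n_dropped)
    sub = sub.loc[keep]

    c = np.asarray(sub[spec.outcome], dtype=float)
    if not np.isin(c, (0.0, 1.0)).all():
        raise ConfigurationError(f"outcome {spec.outcome!r} is not binary 0/1")
    if c.min() == c.max():
        raise EstimationError(
            f"outcome {spec.outcome!r} is constant ({c[0]:g}); cannot fit"
        )

    n = len(sub)
    Y = np.column_stack(
        [np.ones(n)] + [np.asarray(sub[v], dtype=float) for v in spec.mean_covariates]
    )
    X = (
        np.column_stack([np.asarray(sub[v], dtype=float) for v in spec.variance_covariates])
        if spec.variance_covariates
        else np.empty((n, 0))
    )
    for name, col in zip(spec.mean_covariates, Y.T[1:]):
        if col.std() == 0.0:
            raise ConfigurationError(f"mean covariate {name!r} is constant")
    if spec.weight is not None:
        w = np.asarray(sub[spec.weight], dtype=float)
        if (w <= 0).any():
            raise ConfigurationError("non-positive sampling weights")
    else:
        w = np.ones(n)

    return DesignMatrices(
        Y=Y, X=X, c=c, w=w,
        mean_names=(INTERCEPT, *spec.mean_covariates),
        var_names=tuple(spec.variance_covariates),
    )


# ---------------------------------------------------------------------------
# likelihood, score, Hessian
# ---------------------------------------------------------------------------

def _index(beta: np.ndarray, tau: np.ndarray, Y: np.ndarray, X: np.ndarray):
    """Latent index z = Y beta / exp(X tau) and the scale sigma = exp(X tau)."""
    lin = Y @ beta
    log_sigma = X @ tau if X.shape[1] else np.zeros(Y.shape[0])
    # keep the index finite when an optimizer probes extreme scale regions;
    # |z| = 1e7 already carries an astronomically bad likelihood
    sigma = np.exp(np.clip(log_sigma, -600.0, 600.0))
    return np.clip(lin / sigma, -1e7, 1e7), sigma


def predict_prob(
    beta: np.ndarray, tau: np.ndarray, Y: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Outcome probability Phi(y'beta / exp(x'tau)) per row, strictly in (0,1)."""
    beta = np.asarray(beta, dtype=float)
    tau = np.asarray(tau, dtype=float)
    z, _ = _index(beta, tau, Y, X)
    if not np.isfinite(z).all():
        bad = int(np.flatnonzero(~np.isfinite(z))[0])
        raise FloatingPointError(f"non-finite linear predictor at row {bad}")
    p = special.ndtr(z)
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)


def loglik(beta: np.ndarray, tau: np.ndarray, D: DesignMatrices) -> float:
    """Weighted log-likelihood; uses log-CDF so extreme indices stay finite."""
    z, _ = _index(np.asarray(beta, float), np.asarray(tau, float), D.Y, D.X)
    # log Phi(z) for successes, log Phi(-z) = log(1 - Phi(z)) for failures
    contrib = np.where(D.c > 0, special.log_ndtr(z), special.log_ndtr(-z))
    return float(np.sum(D.w * contrib))


def score(beta: np.ndarray, tau: np.ndarray, D: DesignMatrices) -> np.ndarray:
    """Analytic gradient of :func:`loglik` in the stacked (beta, tau).

    With z_i = y_i'beta / sigma_i and sigma_i = exp(x_i'tau):

        d lnL / d beta = sum_i w_i lambda_i y_i / sigma_i
        d lnL / d tau  = sum_i w_i lambda_i (-z_i) x_i

    where lambda_i = phi(z_i)/Phi(z_i) for successes and
    -phi(z_i)/(1-Phi(z_i)) for failures (computed in log space for stability).
    """
    beta = np.asarray(beta, float)
    tau = np.asarray(tau, float)
    z, sigma = _index(beta, tau, D.Y, D.X)
    logpdf = -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
    lam = np.where(
        D.c > 0,
        np.exp(logpdf - special.log_ndtr(z)),
        -np.exp(logpdf - special.log_ndtr(-z)),
    )
    g_beta = D.Y.T @ (D.w * lam / sigma)
    if D.m:
        g_tau = D.X.T @ (D.w * lam * (-z))
    else:
        g_tau = np.empty(0)
    return np.concatenate([g_beta, g_tau])


def hessian(beta: np.ndarray, tau: np.ndarray, D: DesignMatrices) -> np.ndarray:
    """Hessian of :func:`loglik` by central differences of the analytic score."""
    theta = np.concatenate([np.asarray(beta, float), np.asarray(tau, float)])
    k = len(beta)
    p = len(theta)
    H = np.empty((p, p))
    for j in range(p):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (score(tp[:k], tp[k:], D) - score(tm[:k], tm[k:], D)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _per_obs_score(beta, tau, D: DesignMatrices) -> np.ndarray:
    """n x (k+m) matrix of per-observation weighted score contributions."""
    z, sigma = _index(beta, tau, D.Y, D.X)
    logpdf = -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
    lam = np.where(
        D.c > 0,
        np.exp(logpdf - special.log_ndtr(z)),
        -np.exp(logpdf - special.log_ndtr(-z)),
    )
    S_beta = D.Y * (D.w * lam / sigma)[:, None]
    if D.m:
        S_tau = D.X * (D.w * lam * (-z))[:, None]
        return np.hstack([S_beta, S_tau])
    return S_beta


def sandwich_vcov(fit: FitResult, D: DesignMatrices) -> np.ndarray:
    """Huber sandwich covariance A^-1 B A^-1 (A = -Hessian, B = sum s_i s_i')."""
    A = -hessian(fit.beta, fit.tau, D)
    S = _per_obs_score(fit.beta, fit.tau, D)
    B = S.T @ S
    Ainv = np.linalg.pinv(A)
    return Ainv @ B @ Ainv


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _check_separation(beta, tau, D: DesignMatrices) -> None:
    z, _ = _index(beta, tau, D.Y, D.X)
    ones, zeros = D.c > 0, D.c <= 0
    # either one class is pushed beyond any plausible index, or the fit
    # classifies every observation essentially perfectly (the likelihood has
    # no interior maximum in both cases)
    p_observed = special.ndtr(np.where(ones, z, -z))
    if (
        (z[ones] > SEPARATION_INDEX).all()
        or (z[zeros] < -SEPARATION_INDEX).all()
        or p_observed.min() > 0.999
    ):
        # name the covariates with the largest standardized coefficients
        sd = D.Y[:, 1:].std(axis=0)
        scaled = np.abs(beta[1:]) * np.where(sd > 0, sd, 1.0)
        order = np.argsort(scaled)[::-1][:3]
        names = [D.mean_names[1:][i] for i in order]
        raise EstimationError(
            f"perfect separation suspected; largest standardized coefficients: {names}"
        )


def _maximize(theta0: np.ndarray, D: DesignMatrices, k: int, seed: int = 0):
    """Quasi-Newton maximization of the weight-normalized log-likelihood with
    analytic gradient, one jittered restart on failure, then Newton polish."""
    wsum = float(D.w.sum())

    def negll(theta):
        return -loglik(theta[:k], theta[k:], D) / wsum

    def grad(theta):
        return -score(theta[:k], theta[k:], D) / wsum

    res = optimize.minimize(
        negll, theta0, jac=grad, method="BFGS",
        options={"gtol": SCORE_TOL / 10, "maxiter": MAX_ITER},
    )
    n_iter = int(res.nit)
    theta = res.x
    if np.max(np.abs(grad(theta))) > SCORE_TOL:
        rng = np.random.default_rng(seed + 12345)
        jitter = theta0 + rng.normal(scale=0.1, size=theta0.shape)
        logger.warning("optimizer restart from jittered start values")
        res2 = optimize.minimize(
            negll, jitter, jac=grad, method="BFGS",
            options={"gtol": SCORE_TOL / 10, "maxiter": MAX_ITER},
        )
        n_iter += int(res2.nit)
        if res2.fun < res.fun:
            theta = res2.x

    # Newton polish: drive the exact first-order conditions to tolerance
    ll_prev = -negll(theta) * wsum
    for _ in range(25):
        g = score(theta[:k], theta[k:], D)
        if np.max(np.abs(g)) / wsum < SCORE_TOL / 100:
            break
        H = hessian(theta[:k], theta[k:], D)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        cand = theta - step
        ll_cand = loglik(cand[:k], cand[k:], D)
        # halve until the step improves (or give up)
        tries = 0
        while ll_cand < ll_prev - 1e-12 * abs(ll_prev) and tries < 20:
            step *= 0.5
            cand = theta - step
            ll_cand = loglik(cand[:k], cand[k:], D)
            tries += 1
        if ll_cand < ll_prev - 1e-12 * abs(ll_prev):
            break
        theta, converged_change = cand, abs(ll_cand - ll_prev) <= LOGLIK_RTOL * max(1.0, abs(ll_cand))
        ll_prev = ll_cand
        n_iter += 1
        if converged_change and np.max(np.abs(score(theta[:k], theta[k:], D))) / wsum < SCORE_TOL:
            break

    gmax = np.max(np.abs(score(theta[:k], theta[k:], D))) / wsum
    return theta, n_iter, gmax < SCORE_TOL


def _vcov_from_hessian(theta, D: DesignMatrices, k: int):
    H = hessian(theta[:k], theta[k:], D)
    A = -H
    try:
        vcov = np.linalg.inv(A)
        flagged = False
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(A)
        flagged = True
        logger.warning("Hessian not invertible at optimum; pseudo-inverse vcov")
    return vcov, flagged


def fit_probit(D: DesignMatrices, vcov_kind: str = "observed") -> FitResult:
    """Weighted-MLE homoscedastic probit (tau empty).

    The intercept-only model has the closed form beta0 = Phi^-1(weighted mean);
    that solution is used as the start and, in the intercept-only case, is the
    exact optimum up to the polish tolerance.
    """
    if D.c.min() == D.c.max():
        raise EstimationError("outcome is constant; likelihood is unbounded")
    Dp = DesignMatrices(
        Y=D.Y, X=np.empty((D.n_obs, 0)), c=D.c, w=D.w,
        mean_names=D.mean_names, var_names=(),
    )
    k = Dp.k
    pbar = float(np.average(Dp.c, weights=Dp.w))
    theta0 = np.zeros(k)
    theta0[0] = special.ndtri(pbar)
    theta, n_iter, converged = _maximize(theta0, Dp, k)
    _check_separation(theta, np.empty(0), Dp)
    vcov, flagged = _vcov_from_hessian(theta, Dp, k)
    return FitResult(
        beta=theta, tau=np.empty(0), loglik=loglik(theta, np.empty(0), Dp),
        vcov=vcov, converged=converged and not flagged, n_obs=Dp.n_obs,
        n_iterations=n_iter, model_kind="probit",
        mean_names=D.mean_names, var_names=(),
    )


def fit_hetprobit(
    D: DesignMatrices,
    init: np.ndarray | None = None,
    vcov_kind: str = "observed",
) -> FitResult:
    """Joint weighted MLE of (beta, tau) for the multiplicative heteroskedastic
    probit.  Default start: beta from :func:`fit_probit`, tau = 0.  With zero
    variance covariates this reduces exactly to the plain probit fit.

    Raises :class:`EstimationError` if the variance design contains a constant
    column (the model is then unidentified: a constant in x'tau is
    indistinguishable from rescaling beta).
    """
    for j, name in enumerate(D.var_names):
        if D.X[:, j].std() == 0.0:
            raise EstimationError(
                f"variance covariate {name!r} is constant; scale is unidentified"
            )
    if D.m == 0:
        fit = fit_probit(D, vcov_kind=vcov_kind)
        fit.model_kind = "hetprobit"
        return fit
    k, m = D.k, D.m
    if init is not None:
        theta0 = np.asarray(init, dtype=float)
        if theta0.shape != (k + m,):
            raise ConfigurationError(f"init must have length {k + m}")
    else:
        probit = fit_probit(D)
        theta0 = np.concatenate([probit.beta, np.zeros(m)])
    theta, n_iter, converged = _maximize(theta0, D, k)
    _check_separation(theta[:k], theta[k:], D)
    vcov, flagged = _vcov_from_hessian(theta, D, k)
    if vcov_kind == "sandwich":
        tmp = FitResult(theta[:k], theta[k:], 0.0, vcov, True, D.n_obs, 0, "hetprobit")
        vcov = sandwich_vcov(tmp, D)
    return FitResult(
        beta=theta[:k], tau=theta[k:], loglik=loglik(theta[:k], theta[k:], D),
        vcov=vcov, converged=converged and not flagged, n_obs=D.n_obs,
        n_iterations=n_iter, model_kind="hetprobit",
        mean_names=D.mean_names, var_names=D.var_names,
    )
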