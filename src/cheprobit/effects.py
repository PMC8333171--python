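"""Marginal effects, delta-method standard errors, likelihood-ratio tests and
fit statistics for (heteroskedastic) probit fits.

For a continuous covariate ``w_z`` with mean-equation coefficient ``beta_z``
and variance-equation coefficient ``g_z`` (zero when the covariate is absent
from the variance design), the per-observation effect on Pr(c=1) is

    phi(z_i) * (beta_z - (y_i'beta) g_z) / exp(x_i'tau),
    z_i = y_i'beta / exp(x_i'tau).

The second term is the route by which a covariate shared between the mean and
variance equations can flip the sign of its effect relative to beta_z.  For a
dummy covariate the effect is the exact probability difference with the dummy
toggled in *both* designs.  Averages are sampling-weighted (AME) by default;
effects at the weighted covariate means are available as an option.

Standard errors propagate the coefficient covariance through the averaged
effect via the delta method with a numeric Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .hetprobit import DesignMatrices, FitResult, predict_prob

__all__ = [
    "TestResult",
    "me_continuous",
    "me_dummy",
    "delta_method_se",
    "marginal_effects",
    "lr_test",
    "fit_stats",
    "is_dummy",
]

#: finite-difference step for the delta-method Jacobian in parameter space
DELTA_STEP = 1e-6


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: int
    p_value: float


def is_dummy(values: np.ndarray) -> bool:
    """A covariate is a dummy iff its observed support is exactly {0, 1}.

    Proportions strictly inside [0, 1] are treated as continuous.
    """
    u = np.unique(np.asarray(values, dtype=float))
    return u.size == 2 and u[0] == 0.0 and u[1] == 1.0


def _variance_view(tau: np.ndarray, D: DesignMatrices) -> DesignMatrices:
    """A homoscedastic fit (empty tau) evaluated on a design that carries
    variance columns ignores them: view the design with a zero-column X."""
    if len(tau) == D.m:
        return D
    if len(tau) == 0:
        return DesignMatrices(
            Y=D.Y, X=np.empty((D.Y.shape[0], 0)), c=D.c, w=D.w,
            mean_names=D.mean_names, var_names=(),
        )
    raise ValueError("tau length does not match the variance design")


def _positions(D: DesignMatrices, variable: str) -> tuple[int, int | None]:
    if variable not in D.mean_names:
        raise ValueError(
            f"{variable!r} is not a mean covariate; effects for variables "
            "appearing only in the variance equation are not defined here"
        )
    jy = D.mean_names.index(variable)
    jx = D.var_names.index(variable) if variable in D.var_names else None
    return jy, jx


def _me_continuous_at(beta, tau, D: DesignMatrices, variable: str) -> np.ndarray:
    D = _variance_view(tau, D)
    jy, jx = _positions(D, variable)
    lin = D.Y @ beta
    log_sigma = D.X @ tau if D.m else np.zeros(D.n_obs)
    sigma = np.exp(log_sigma)
    z = lin / sigma
    g_z = tau[jx] if jx is not None else 0.0
    return stats.norm.pdf(z) * (beta[jy] - lin * g_z) / sigma


def _me_dummy_at(beta, tau, D: DesignMatrices, variable: str) -> np.ndarray:
    D = _variance_view(tau, D)
    jy, jx = _positions(D, variable)
    Y1, Y0 = D.Y.copy(), D.Y.copy()
    Y1[:, jy], Y0[:, jy] = 1.0, 0.0
    X1, X0 = D.X.copy(), D.X.copy()
    if jx is not None:
        X1[:, jx], X0[:, jx] = 1.0, 0.0
    return predict_prob(beta, tau, Y1, X1) - predict_prob(beta, tau, Y0, X0)


def me_continuous(
    fit: FitResult, D: DesignMatrices, variable: str
) -> tuple[np.ndarray, float]:
    """Per-observation continuous marginal effect and its weighted average."""
    per_obs = _me_continuous_at(fit.beta, fit.tau, D, variable)
    return per_obs, float(np.average(per_obs, weights=D.w))


def me_dummy(
    fit: FitResult, D: DesignMatrices, variable: str
) -> tuple[np.ndarray, float]:
    """Per-observation toggled probability difference and its weighted average."""
    jy, _ = _positions(D, variable)
    if not is_dummy(D.Y[:, jy]):
        raise ValueError(f"{variable!r} is not binary 0/1 in the data")
    per_obs = _me_dummy_at(fit.beta, fit.tau, D, variable)
    return per_obs, float(np.average(per_obs, weights=D.w))


def _ame_of_theta(theta, D: DesignMatrices, variable: str, kind: str, k: int) -> float:
    beta, tau = theta[:k], theta[k:]
    if kind == "dummy":
        per = _me_dummy_at(beta, tau, D, variable)
    else:
        per = _me_continuous_at(beta, tau, D, variable)
    return float(np.average(per, weights=D.w))


def delta_method_se(
    fit: FitResult, D: DesignMatrices, variable: str, kind: str
) -> float:
    """Delta-method SE of the weighted-average marginal effect.

    sqrt(J V J') with J the central-difference Jacobian of the averaged effect
    in the stacked (beta, tau).  If the quadratic form comes out negative at
    tolerance scale, the Jacobian is recomputed with Richardson extrapolation
    before reporting an error.
    """
    if kind not in ("continuous", "dummy"):
        raise ValueError(f"unknown effect kind {kind!r}")
    theta = fit.params
    k = len(fit.beta)

    def jac(step: float) -> np.ndarray:
        J = np.empty(len(theta))
        for j in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += step
            tm[j] -= step
            J[j] = (
                _ame_of_theta(tp, D, variable, kind, k)
                - _ame_of_theta(tm, D, variable, kind, k)
            ) / (2.0 * step)
        return J

    J = jac(DELTA_STEP)
    var = float(J @ fit.vcov @ J)
    if var < 0.0:
        # Richardson: (4 f(h/2) - f(h)) / 3 cancels the O(h^2) error
        J = (4.0 * jac(DELTA_STEP / 2.0) - J) / 3.0
        var = float(J @ fit.vcov @ J)
        if var < -1e-12:
            raise FloatingPointError(
                f"negative delta-method variance for {variable!r}: {var:g}"
            )
        var = max(var, 0.0)
    return float(np.sqrt(var))


def marginal_effects(
    fit: FitResult, D: DesignMatrices, averaging: str = "AME"
) -> pd.DataFrame:
    """Marginal-effect table for every non-intercept mean covariate.

    Columns: variable, kind, estimate, se, z, p, averaging.  ``averaging`` is
    "AME" (weighted average of per-observation effects, the default) or
    "at-means" (effects evaluated at the weighted covariate means; dummies are
    still toggled 0 -> 1).
    """
    if averaging not in ("AME", "at-means"):
        raise ValueError(f"unknown averaging convention {averaging!r}")
    Deff = D
    if averaging == "at-means":
        ybar = np.average(D.Y, axis=0, weights=D.w)[None, :]
        xbar = np.average(D.X, axis=0, weights=D.w)[None, :] if D.m else np.empty((1, 0))
        Deff = DesignMatrices(
            Y=ybar, X=xbar, c=np.ones(1), w=np.ones(1),
            mean_names=D.mean_names, var_names=D.var_names,
        )
    rows = []
    for j, name in enumerate(D.mean_names):
        if name == D.mean_names[0] and j == 0:  # intercept
            continue
        kind = "dummy" if is_dummy(D.Y[:, j]) else "continuous"
        if kind == "dummy":
            per = _me_dummy_at(fit.beta, fit.tau, Deff, name)
        else:
            per = _me_continuous_at(fit.beta, fit.tau, Deff, name)
        est = float(np.average(per, weights=Deff.w))
        se = delta_method_se(fit, Deff, name, kind)
        z = est / se if se > 0 else np.nan
        p = 2.0 * special.ndtr(-abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            dict(variable=name, kind=kind, estimate=est, se=se, z=z, p=p,
                 averaging=averaging)
        )
    return pd.DataFrame(rows)


def lr_test(
    restricted: FitResult, unrestricted: FitResult, df: int, name: str = "LR test"
) -> TestResult:
    """Likelihood-ratio test: 2 (lnL_u - lnL_r) against chi-square(df).

    Used both for the overall-model test (null = intercept-only probit) and
    the heteroskedasticity test (null = homoscedastic probit, df = number of
    variance covariates).
    """
    gap = unrestricted.loglik - restricted.loglik
    if gap < -1e-6:
        raise RuntimeError(
            f"unrestricted loglik {unrestricted.loglik:.6f} below restricted "
            f"{restricted.loglik:.6f}; optimizer failure in the nested pair"
        )
    statistic = max(2.0 * gap, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return TestResult(name=name, statistic=float(statistic), df=df, p_value=p)


def fit_stats(fit: FitResult, null_loglik: float) -> dict:
    """AIC, BIC and McFadden pseudo R-squared.

    k counts all free parameters (mean and variance coefficients); the null
    log-likelihood comes from the intercept-only probit on the same data.
    """
    if null_loglik == 0.0:
        raise ValueError("null log-likelihood of zero; degenerate null model")
    k = len(fit.beta) + len(fit.tau)
    return {
        "aic": 2.0 * k - 2.0 * fit.loglik,
        "bic": k * np.log(fit.n_obs) - 2.0 * fit.loglik,
        "mcfadden_r2": 1.0 - fit.loglik / null_loglik,
        "k": k,
    }
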