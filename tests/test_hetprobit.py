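"""Likelihood, score, and maximum-likelihood fitting of the probit and
multiplicative heteroskedastic probit, including the naive-transcription and
finite-difference oracles and the reduction/invariance contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import ndtri

from cheprobit import (
    EstimationError,
    ModelSpec,
    build_design,
    fit_hetprobit,
    fit_probit,
    hessian,
    loglik,
    predict_prob,
    score,
)
from cheprobit.hetprobit import ConfigurationError

from conftest import make_design


def naive_loglik(beta, tau, D):
    """Literal term-by-term transcription of the weighted log-likelihood."""
    total = 0.0
    for i in range(D.n_obs):
        z = float(D.Y[i] @ beta) / np.exp(float(D.X[i] @ tau) if D.m else 0.0)
        p = stats.norm.cdf(z)
        total += D.w[i] * (np.log(p) if D.c[i] != 0 else np.log(1.0 - p))
    return total


def _random_design(rng, n=6, k=3, m=2):
    Y = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    X = rng.normal(size=(n, m))
    c = rng.integers(0, 2, size=n).astype(float)
    c[0], c[1] = 0.0, 1.0  # both classes
    w = rng.uniform(0.5, 2.0, size=n)
    return make_design(Y, X, c, w)


# ---------------------------------------------------------------------------
# model spec / design construction
# ---------------------------------------------------------------------------

def test_build_design_shapes_and_missing_rows():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(
        {
            "che": rng.integers(0, 2, 10).astype(float),
            "a": rng.normal(size=10),
            "b": rng.normal(size=10),
            "w": np.ones(10),
        }
    )
    df.loc[3, "a"] = np.nan
    spec = ModelSpec("che", ("a", "b"), ("a",), "w")
    D = build_design(df, spec)
    assert D.Y.shape == (9, 3)
    assert D.X.shape == (9, 1)
    assert (D.Y[:, 0] == 1.0).all()
    assert D.mean_names == ("intercept", "a", "b")


def test_build_design_errors():
    df = pd.DataFrame({"che": [1.0, 1.0, 1.0], "a": [1.0, 2.0, 3.0], "w": [1.0] * 3})
    with pytest.raises(EstimationError):
        build_design(df, ModelSpec("che", ("a",), (), "w"))
    with pytest.raises(ConfigurationError):
        build_design(df, ModelSpec("che", ("missing",), (), "w"))
    with pytest.raises(ConfigurationError):
        ModelSpec("che", ("che",))


# ---------------------------------------------------------------------------
# probability, likelihood, score
# ---------------------------------------------------------------------------

def test_predict_prob_reference_points():
    Y = np.ones((3, 1))
    X = np.ones((3, 1))
    # y'beta = 0 -> 0.5 regardless of tau
    assert predict_prob([0.0], [2.0], Y, X)[0] == pytest.approx(0.5)
    # y'beta = 1.959964 = Phi^-1(0.975), tau = 0
    assert predict_prob([1.959964], [0.0], Y, X)[0] == pytest.approx(0.975, abs=1e-6)
    # y'beta = 1, x'tau = ln 2 halves the index -> Phi(0.5)
    assert predict_prob([1.0], [np.log(2.0)], Y, X)[0] == pytest.approx(
        0.691462, abs=1e-6
    )


def test_loglik_single_points():
    D1 = make_design(np.ones((1, 1)), np.empty((1, 0)), [1.0], [1.0])
    assert loglik([0.0], [], D1) == pytest.approx(np.log(0.5))
    D2 = make_design(np.ones((2, 1)), np.empty((2, 0)), [1.0, 0.0], [1.0, 1.0])
    assert loglik([0.0], [], D2) == pytest.approx(2 * np.log(0.5))


def test_loglik_matches_naive_transcription():
    rng = np.random.default_rng(123)
    D = _random_design(rng)
    beta = rng.normal(scale=0.5, size=3)
    tau = rng.normal(scale=0.3, size=2)
    assert loglik(beta, tau, D) == pytest.approx(naive_loglik(beta, tau, D), rel=1e-9)


def test_score_matches_finite_differences(rng):
    D = _random_design(rng)
    theta = np.concatenate([rng.normal(size=3), rng.normal(scale=0.5, size=2)])
    g = score(theta[:3], theta[3:], D)
    h = 1e-6
    for j in range(5):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        fd = (loglik(tp[:3], tp[3:], D) - loglik(tm[:3], tm[3:], D)) / (2 * h)
        assert g[j] == pytest.approx(fd, rel=1e-6, abs=1e-8)


def test_score_linear_in_weights(rng):
    D = _random_design(rng)
    beta, tau = np.array([0.2, -0.4, 0.6]), np.array([0.1, -0.2])
    g1 = score(beta, tau, D)
    D2 = make_design(D.Y, D.X, D.c, 2.0 * D.w)
    np.testing.assert_allclose(score(beta, tau, D2), 2.0 * g1, rtol=1e-12)


def test_score_zero_at_probit_mle(rng):
    D = _random_design(rng, n=200, m=0)
    fit = fit_probit(D)
    g = score(fit.beta, np.empty(0), D)
    assert np.max(np.abs(g)) / D.w.sum() < 1e-6


# ---------------------------------------------------------------------------
# probit fitting
# ---------------------------------------------------------------------------

def test_probit_intercept_only_closed_form():
    rng = np.random.default_rng(7)
    n = 50
    c = rng.integers(0, 2, n).astype(float)
    w = rng.uniform(0.5, 3.0, n)
    D = make_design(np.ones((n, 1)), np.empty((n, 0)), c, w)
    fit = fit_probit(D)
    pbar = np.average(c, weights=w)
    assert fit.beta[0] == pytest.approx(ndtri(pbar), abs=1e-8)


def test_probit_balanced_intercept_only():
    c = np.array([0.0, 1.0] * 25)
    D = make_design(np.ones((50, 1)), np.empty((50, 0)), c, np.ones(50))
    fit = fit_probit(D)
    assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
    assert fit.loglik == pytest.approx(50 * np.log(0.5))


def test_probit_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    n = 200
    Y = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
    beta_true = np.array([0.3, -0.7, 0.5])
    c = (Y @ beta_true + rng.normal(size=n) > 0).astype(float)
    D = make_design(Y, np.empty((n, 0)), c, np.ones(n))
    fit = fit_probit(D)
    ref = sm.Probit(c, Y).fit(disp=0)
    np.testing.assert_allclose(fit.beta, ref.params, atol=1e-5)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-3)


def test_probit_refuses_constant_outcome():
    D = make_design(np.ones((5, 1)), np.empty((5, 0)), np.ones(5), np.ones(5))
    with pytest.raises(EstimationError):
        fit_probit(D)


def test_probit_detects_separation():
    x = np.linspace(-2, 2, 40)
    c = (x > 0).astype(float)
    Y = np.column_stack([np.ones(40), x])
    D = make_design(Y, np.empty((40, 0)), c, np.ones(40))
    with pytest.raises(EstimationError, match="separation"):
        fit_probit(D)


# ---------------------------------------------------------------------------
# heteroskedastic probit fitting
# ---------------------------------------------------------------------------

def test_hetprobit_rejects_constant_variance_column():
    rng = np.random.default_rng(3)
    n = 30
    c = rng.integers(0, 2, n).astype(float)
    D = make_design(np.ones((n, 1)), np.zeros((n, 1)), c, np.ones(n))
    with pytest.raises(EstimationError, match="constant"):
        fit_hetprobit(D)


def test_hetprobit_reduces_to_probit_without_variance_covariates(rng):
    D = _random_design(rng, n=300, m=0)
    probit = fit_probit(D)
    het = fit_hetprobit(D)
    np.testing.assert_allclose(het.beta, probit.beta, atol=1e-6)
    assert het.loglik == pytest.approx(probit.loglik, abs=1e-8)


def test_hetprobit_loglik_dominates_probit(rng):
    D = _random_design(rng, n=500, k=3, m=1)
    probit = fit_probit(D)
    het = fit_hetprobit(D)
    assert het.loglik >= probit.loglik - 1e-8


def test_hetprobit_tau_near_zero_under_homoscedastic_dgp():
    rng = np.random.default_rng(42)
    n = 5000
    x = rng.normal(size=n)
    Y = np.column_stack([np.ones(n), x])
    c = (Y @ np.array([0.2, 0.6]) + rng.normal(size=n) > 0).astype(float)
    D = make_design(Y, x, c, np.ones(n))
    het = fit_hetprobit(D)
    tau_se = het.se[2]
    assert abs(het.tau[0]) < 3 * tau_se
    probit = fit_probit(D)
    assert 2 * (het.loglik - probit.loglik) < 6.0


def test_integer_weights_equal_row_replication(rng):
    n = 40
    x = rng.normal(size=n)
    Y = np.column_stack([np.ones(n), x])
    c = (x + rng.normal(size=n) > 0).astype(float)
    w = rng.integers(1, 4, size=n).astype(float)
    D = make_design(Y, x, c, w)
    rep = np.repeat(np.arange(n), w.astype(int))
    Drep = make_design(Y[rep], x[rep], c[rep], np.ones(len(rep)))
    f1, f2 = fit_hetprobit(D), fit_hetprobit(Drep)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
    np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)
    np.testing.assert_allclose(f1.tau, f2.tau, atol=1e-6)


def test_rescaling_mean_covariate_rescales_beta(rng):
    n = 400
    x = rng.normal(size=n)
    Y = np.column_stack([np.ones(n), x])
    c = (0.3 + 0.8 * x + rng.normal(size=n) > 0).astype(float)
    D = make_design(Y, np.empty((n, 0)), c, np.ones(n))
    f1 = fit_probit(D)
    Y2 = Y.copy()
    Y2[:, 1] *= 10.0
    f2 = fit_probit(make_design(Y2, np.empty((n, 0)), c, np.ones(n)))
    assert f2.beta[1] == pytest.approx(f1.beta[1] / 10.0, rel=1e-5)
    assert f2.loglik == pytest.approx(f1.loglik, abs=1e-7)


def test_shifting_variance_covariate_is_not_invariant(rng):
    """No variance-equation intercept: adding a constant to a variance
    covariate rescales all fitted scales and changes tau -- a documented
    behavioral contract, not a bug."""
    n = 1500
    x = rng.normal(size=n)
    Y = np.column_stack([np.ones(n), x])
    c = (0.3 + 0.6 * x + np.exp(0.4 * x) * rng.normal(size=n) > 0).astype(float)
    D = make_design(Y, x, c, np.ones(n))
    f1 = fit_hetprobit(D)
    f2 = fit_hetprobit(make_design(Y, x + 1.0, c, np.ones(n)))
    # same tau slope maximizes both (shift absorbed into beta scale) ...
    assert f2.tau[0] == pytest.approx(f1.tau[0], abs=0.05)
    # ... but the mean coefficients differ by roughly the factor exp(tau)
    assert not np.allclose(f2.beta, f1.beta, atol=1e-3)
    assert f2.beta[1] / f1.beta[1] == pytest.approx(np.exp(f1.tau[0]), rel=0.05)


def test_concavity_at_optimum():
    rng = np.random.default_rng(99)
    n = 800
    v = rng.normal(size=n)
    Y = np.column_stack([np.ones(n), v])
    c = (0.3 + 0.7 * v + np.exp(0.4 * v) * rng.normal(size=n) > 0).astype(float)
    D = make_design(Y, v, c, rng.uniform(0.5, 2.0, size=n))
    het = fit_hetprobit(D)
    assert het.converged
    H = hessian(het.beta, het.tau, D)
    eigvals = np.linalg.eigvalsh(-H)
    assert (eigvals > 0).all()
    # vcov agrees with the inverse negative Hessian and is symmetric PSD
    np.testing.assert_allclose(het.vcov, np.linalg.inv(-H), rtol=1e-6, atol=1e-10)
    assert (np.linalg.eigvalsh(het.vcov) > 0).all()
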