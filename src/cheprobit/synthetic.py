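"""Synthetic household-survey generator.

Produces microdata with the statistical structure the CHE analysis assumes,
in two modes:

* **structural** — draws right-skewed (log-normal) total expenditure, an
  Engel-curve food share (logistic in log total expenditure, so larger
  budgets devote smaller shares to food), household size, sampling weights
  and an out-of-pocket health expenditure whose log-scale grows with log
  total expenditure (richer households face more variable health spending).
  No outcome column is written: the CHE indicator is produced downstream by
  the measurement pipeline.

* **latent_index** — draws covariates and then the CHE outcome directly from
  the heteroskedastic probit law, Bernoulli(Phi(y'beta / exp(x'tau))).  This
  mode exists for clean parameter recovery: the fitted model is exactly the
  data-generating process.

Reproducibility contract: every column is drawn from its own child random
stream keyed by (seed, column name), in a fixed order, so adding a covariate
to a configuration never perturbs the draws of existing columns.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "CovariateSpec",
    "GeneratorConfig",
    "generate",
    "write_fixture",
    "default_structural_config",
    "default_latent_config",
]

RESERVED = ("weight", "total_exp", "food_exp", "oop", "hh_size", "che", "household_id")


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: name, distribution family and parameters.

    Supported families: ``bernoulli`` (p), ``normal`` (mean, sd), ``beta``
    (a, b; a proportion on [0,1]), ``lognormal`` (log_mean, log_sd),
    ``uniform`` (low, high).
    """

    name: str
    dist: str
    params: dict

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.dist == "bernoulli":
            return rng.binomial(1, p["p"], size=n).astype(float)
        if self.dist == "normal":
            return rng.normal(p["mean"], p["sd"], size=n)
        if self.dist == "beta":
            return rng.beta(p["a"], p["b"], size=n)
        if self.dist == "lognormal":
            return rng.lognormal(p["log_mean"], p["log_sd"], size=n)
        if self.dist == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        raise GeneratorConfigError(f"unknown distribution {self.dist!r} for {self.name!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic survey.

    ``true_beta`` maps mean-equation covariate names (plus "intercept") to
    coefficients; ``true_tau`` maps variance-equation covariate names to
    coefficients.  Both are used only in latent_index mode.  ``food_engel``
    is (a, b, noise_sd) of food_share = logistic(a + b ln total_exp + eps);
    ``oop_spec`` is (log_mean_const, log_mean_slope, log_sd_const,
    log_sd_slope, p_zero) with the log-mean and log-sd of OOP linear in
    ln total_exp and a point mass of zero-spending households.
    """

    n_households: int
    seed: int
    mode: str  # "structural" | "latent_index"
    covariate_spec: tuple[CovariateSpec, ...] = ()
    true_beta: dict = field(default_factory=dict)
    true_tau: dict = field(default_factory=dict)
    weight_spec: dict = field(
        default_factory=lambda: {"shift": 0.25, "shape": 2.25, "scale": 1 / 3}
    )
    total_exp_spec: dict = field(
        default_factory=lambda: {"log_mean": 10.2, "log_sd": 0.8}
    )
    food_engel: dict = field(
        default_factory=lambda: {"a": 3.37, "b": -0.35, "noise_sd": 0.30}
    )
    oop_spec: dict = field(
        default_factory=lambda: {
            "log_mean_const": -2.6,
            "log_mean_slope": 1.0,
            "log_sd_const": -0.5,
            "log_sd_slope": 0.15,
            "p_zero": 0.03,
        }
    )
    hh_size_spec: dict = field(default_factory=lambda: {"mean_extra": 4.0})

    def validate(self) -> None:
        if self.n_households < 1:
            raise GeneratorConfigError("n_households must be at least 1")
        if self.mode not in ("structural", "latent_index"):
            raise GeneratorConfigError(f"unknown mode {self.mode!r}")
        names = {c.name for c in self.covariate_spec}
        if len(names) != len(self.covariate_spec):
            raise GeneratorConfigError("duplicate covariate names")
        clash = names & set(RESERVED)
        if clash:
            raise GeneratorConfigError(f"covariate names clash with reserved columns: {clash}")
        if self.mode == "latent_index":
            for coef_map, label in ((self.true_beta, "true_beta"), (self.true_tau, "true_tau")):
                for name in coef_map:
                    if name == "intercept" and label == "true_beta":
                        continue
                    if name not in names:
                        raise GeneratorConfigError(
                            f"{label} refers to unknown covariate {name!r}"
                        )


def _stream(seed: int, name: str) -> np.random.Generator:
    """Child generator keyed by (seed, column name); stable across runs and
    across unrelated configuration changes."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    )


def _draw_weights(cfg: GeneratorConfig, n: int) -> np.ndarray:
    ws = cfg.weight_spec
    rng = _stream(cfg.seed, "weight")
    return ws["shift"] + rng.gamma(ws["shape"], ws["scale"], size=n)


def _draw_hh_size(cfg: GeneratorConfig, n: int) -> np.ndarray:
    rng = _stream(cfg.seed, "hh_size")
    return 1 + rng.poisson(cfg.hh_size_spec["mean_extra"], size=n)


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the household table; a pure function of (config, seed)."""
    config.validate()
    n = config.n_households
    cols: dict[str, np.ndarray] = {"household_id": np.arange(n)}

    # covariates first, each from its own named stream
    for cov in config.covariate_spec:
        cols[cov.name] = cov.draw(_stream(config.seed, f"cov:{cov.name}"), n)

    cols["weight"] = _draw_weights(config, n)
    cols["hh_size"] = _draw_hh_size(config, n)

    if config.mode == "structural":
        ts = config.total_exp_spec
        total = _stream(config.seed, "total_exp").lognormal(
            ts["log_mean"], ts["log_sd"], size=n
        )
        fe = config.food_engel
        eps = _stream(config.seed, "food_share").normal(0.0, fe["noise_sd"], size=n)
        share = special.expit(fe["a"] + fe["b"] * np.log(total) + eps)
        os_ = config.oop_spec
        rng_oop = _stream(config.seed, "oop")
        log_total = np.log(total)
        log_sd = np.maximum(os_["log_sd_const"] + os_["log_sd_slope"] * log_total, 0.05)
        oop = rng_oop.lognormal(
            os_["log_mean_const"] + os_["log_mean_slope"] * log_total, log_sd
        )
        zero = rng_oop.random(n) < os_["p_zero"]
        oop[zero] = 0.0
        cols["total_exp"] = total
        cols["food_exp"] = share * total
        cols["oop"] = oop
    else:  # latent_index
        index = np.full(n, config.true_beta.get("intercept", 0.0))
        for name, coef in config.true_beta.items():
            if name != "intercept":
                index = index + coef * cols[name]
        log_sigma = np.zeros(n)
        for name, coef in config.true_tau.items():
            log_sigma = log_sigma + coef * cols[name]
        prob = special.ndtr(index / np.exp(log_sigma))
        u = _stream(config.seed, "che").random(n)
        cols["che"] = (u < prob).astype(int)

    return pd.DataFrame(cols)


def write_fixture(records: pd.DataFrame, path) -> None:
    """Write a household table to CSV, round-trippable at full float precision."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty household table")
    records.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# study-condition defaults
# ---------------------------------------------------------------------------

def default_structural_config(n_households: int = 6000, seed: int = 0) -> GeneratorConfig:
    """Structural survey mimicking a rural household-expenditure sample:
    strongly right-skewed annual budgets, food shares near one half that fall
    with the budget, OOP health spending around a tenth of the budget with a
    dispersion that grows with the budget, and household/head covariates with
    rural prevalences."""
    covs = (
        CovariateSpec("male_head", "bernoulli", {"p": 0.8}),
        CovariateSpec("head_illiterate", "bernoulli", {"p": 0.34}),
        CovariateSpec("insured", "bernoulli", {"p": 0.32}),
        CovariateSpec("chronic", "bernoulli", {"p": 0.73}),
        CovariateSpec("prop_female", "beta", {"a": 5.0, "b": 5.0}),
        CovariateSpec("prop_elderly", "beta", {"a": 1.0, "b": 9.0}),
    )
    return GeneratorConfig(
        n_households=n_households, seed=seed, mode="structural", covariate_spec=covs
    )


def default_latent_config(
    n_households: int = 20000, seed: int = 0
) -> GeneratorConfig:
    """Latent-index survey for parameter recovery: four mean covariates, one
    of which (a standard-normal log-expenditure proxy) also drives the latent
    scale, as in a model with total expenditure in both equations."""
    covs = (
        CovariateSpec("log_exp_std", "normal", {"mean": 0.0, "sd": 1.0}),
        CovariateSpec("head_dummy", "bernoulli", {"p": 0.4}),
        CovariateSpec("prop_member", "beta", {"a": 2.0, "b": 3.0}),
        CovariateSpec("z_cov", "normal", {"mean": 0.0, "sd": 1.0}),
    )
    return GeneratorConfig(
        n_households=n_households,
        seed=seed,
        mode="latent_index",
        covariate_spec=covs,
        true_beta={
            "intercept": -0.8,
            "log_exp_std": 0.5,
            "head_dummy": 0.4,
            "prop_member": -0.6,
            "z_cov": 0.3,
        },
        true_tau={"log_exp_std": 0.3},
    )
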