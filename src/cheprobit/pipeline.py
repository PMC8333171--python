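"""End-to-end analysis pipeline: read household data, construct the CHE
outcome, fit the homoscedastic and heteroskedastic probit models, and emit a
side-by-side comparison table with marginal effects, likelihood-ratio tests
and fit statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .measurement import CheParameters, run_che_pipeline
from .hetprobit import (
    ModelSpec,
    build_design,
    fit_hetprobit,
    fit_probit,
)
from .effects import fit_stats, lr_test, marginal_effects

__all__ = ["PipelineConfig", "read_households", "run_full_analysis", "format_table"]

logger = logging.getLogger("cheprobit")

STANDARD_COLUMNS = ("weight", "total_exp", "food_exp", "oop", "hh_size")
#: name of the derived scaled-expenditure column available to the model spec
SCALED_EXP = "total_exp_scaled"


@dataclass
class PipelineConfig:
    """Everything one full run needs.

    ``column_mapping`` maps the standard roles (weight, total_exp, food_exp,
    oop, hh_size) to column names in the input file; identity by default.
    ``exp_divisor`` rescales total expenditure into the derived column
    ``total_exp_scaled`` (units of 10,000 by default) before it enters either
    equation, protecting exp(x'tau) from raw-currency magnitudes.
    """

    input_path: str | None = None
    column_mapping: dict = field(default_factory=dict)
    che: CheParameters = field(default_factory=CheParameters)
    mean_covariates: tuple[str, ...] = ()
    variance_covariates: tuple[str, ...] = (SCALED_EXP,)
    exp_divisor: float = 10_000.0
    output_dir: str | None = None
    seed: int = 0
    verbosity: int = 1

    def model_spec(self) -> ModelSpec:
        return ModelSpec(
            outcome="che",
            mean_covariates=tuple(self.mean_covariates),
            variance_covariates=tuple(self.variance_covariates),
            weight="weight",
        )


def read_households(path, column_mapping: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Read and validate a household CSV.

    Returns the table of valid records (standard column names) and a manifest
    of rejected rows with reasons.  Rejection rules: non-positive weight or
    total expenditure, negative food or OOP spending, food above total,
    household size below one, or any missing standard field.
    """
    mapping = dict(column_mapping or {})
    raw = pd.read_csv(path)
    if len(raw) == 0:
        raise ValueError(f"no data rows in {path}")
    rename = {src: dst for dst, src in mapping.items() if src != dst}
    missing = [mapping.get(c, c) for c in STANDARD_COLUMNS if mapping.get(c, c) not in raw.columns]
    if missing:
        raise KeyError(f"mapped columns absent from {path}: {missing}")
    df = raw.rename(columns=rename)

    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, why):
        nonlocal reasons
        mask = mask.fillna(False) if hasattr(mask, "fillna") else mask
        reasons[mask & (reasons == "")] = why

    flag(df[list(STANDARD_COLUMNS)].isna().any(axis=1), "missing standard field")
    flag(df["weight"] <= 0, "non-positive weight")
    flag(df["total_exp"] <= 0, "non-positive total expenditure")
    flag(df["food_exp"] < 0, "negative food expenditure")
    flag(df["food_exp"] > df["total_exp"], "food expenditure above total")
    flag(df["oop"] < 0, "negative OOP expenditure")
    flag(df["hh_size"] < 1, "household size below 1")

    bad = reasons != ""
    manifest = {
        "n_read": int(len(df)),
        "n_valid": int((~bad).sum()),
        "rejected": [
            {"row": int(i), "reason": r} for i, r in reasons[bad].items()
        ],
    }
    if bad.any():
        logger.warning("read_households: rejected %d of %d rows", int(bad.sum()), len(df))
    return df[~bad].reset_index(drop=True), manifest


STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, s in STAR_LEVELS:
        if p < level:
            return s
    return ""


def _model_block(fit, me: pd.DataFrame) -> pd.DataFrame:
    from scipy import special

    names = list(fit.mean_names) + [f"ln_sigma:{v}" for v in fit.var_names]
    se = fit.se
    coefs = fit.params
    z = np.divide(coefs, se, out=np.full_like(coefs, np.nan), where=se > 0)
    p = 2.0 * special.ndtr(-np.abs(z))
    block = pd.DataFrame(
        {"variable": names, "coef": coefs, "coef_se": se, "coef_p": p}
    )
    me_cols = me.set_index("variable")[["estimate", "se", "p", "kind"]]
    me_cols.columns = ["me", "me_se", "me_p", "kind"]
    return block.join(me_cols, on="variable")


def run_full_analysis(
    config: PipelineConfig, data: pd.DataFrame | None = None
) -> dict:
    """Execute the full pipeline and return (and optionally write) the bundle.

    Stages: CHE measurement -> design build -> probit fit -> heteroskedastic
    probit fit -> marginal effects -> LR tests and fit statistics.  If the
    input table already carries a ``che`` column (latent-index fixtures), the
    measurement stage is skipped.  When ``config.output_dir`` is set the
    bundle is serialized there (CSV + JSON + manifest + log).
    """
    manifest: dict = {"config": _config_dict(config), "package_version": __version__}
    if data is None:
        if config.input_path is None:
            raise ValueError("either data or config.input_path is required")
        data, read_manifest = read_households(config.input_path, config.column_mapping)
        manifest["read"] = read_manifest

    bundle: dict = {}
    n_read = len(data)

    if "che" in data.columns:
        logger.info("input carries a che column; skipping measurement stage")
        modeled = data.copy()
        incidence = {
            "incidence": float(np.average(modeled["che"], weights=modeled["weight"])),
            "n_households": n_read,
            "n_flagged": 0,
            "n_modeled": n_read,
        }
        che_table = None
    else:
        che_table, incidence = run_che_pipeline(data, config.che)
        keep = ~che_table["flagged"].to_numpy()
        modeled = data.loc[keep].copy()
        modeled["che"] = che_table.loc[keep, "che"].to_numpy()
    bundle["incidence"] = incidence
    bundle["che_table"] = che_table

    if "total_exp" in modeled.columns and SCALED_EXP not in modeled.columns:
        modeled[SCALED_EXP] = modeled["total_exp"] / config.exp_divisor

    spec = config.model_spec()
    D = build_design(modeled, spec)
    logger.info("design: n=%d, k=%d mean, m=%d variance", D.n_obs, D.k, D.m)

    probit = fit_probit(D)
    het = fit_hetprobit(D)
    me_probit = marginal_effects(probit, D)
    me_het = marginal_effects(het, D)

    null_spec = ModelSpec(outcome="che", mean_covariates=(), weight="weight")
    null_fit = fit_probit(build_design(modeled, null_spec))

    het_test = lr_test(probit, het, df=D.m, name="heteroskedasticity LR test")
    lr_probit = lr_test(null_fit, probit, df=D.k - 1, name="overall LR test (probit)")
    lr_het = lr_test(null_fit, het, df=D.k - 1 + D.m, name="overall LR test (hetprobit)")

    footer = {
        "probit": {
            "loglik": probit.loglik,
            "lr_overall": lr_probit.statistic,
            "lr_overall_p": lr_probit.p_value,
            **fit_stats(probit, null_fit.loglik),
            "n_iterations": probit.n_iterations,
            "n": probit.n_obs,
        },
        "hetprobit": {
            "loglik": het.loglik,
            "lr_overall": lr_het.statistic,
            "lr_overall_p": lr_het.p_value,
            "het_test_chi2": het_test.statistic,
            "het_test_df": het_test.df,
            "het_test_p": het_test.p_value,
            **fit_stats(het, null_fit.loglik),
            "n_iterations": het.n_iterations,
            "n": het.n_obs,
        },
    }

    table = pd.merge(
        _model_block(probit, me_probit),
        _model_block(het, me_het),
        on="variable",
        how="outer",
        suffixes=("_probit", "_het"),
    )
    order = list(het.mean_names) + [f"ln_sigma:{v}" for v in het.var_names]
    table = table.set_index("variable").reindex(order).reset_index()
    bundle.update(
        probit=probit, hetprobit=het, me_probit=me_probit, me_het=me_het,
        het_test=het_test, lr_overall_probit=lr_probit, lr_overall_het=lr_het,
        footer=footer, table=table, null_loglik=null_fit.loglik,
    )
    manifest["counts"] = {
        "read": n_read,
        "modeled": int(D.n_obs),
        "flagged": int(incidence.get("n_flagged", 0)),
    }
    manifest["seed"] = config.seed
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    bundle["manifest"] = manifest

    if config.output_dir is not None:
        _write_bundle(bundle, Path(config.output_dir))
    return bundle


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["che"] = asdict(config.che) if not isinstance(config.che, dict) else config.che
    return d


def format_table(bundle: dict, decimals: int = 3) -> str:
    """Human-readable side-by-side model table with significance stars
    (* p<0.05, ** p<0.01, *** p<0.001)."""
    table = bundle["table"]
    lines = [
        f"{'variable':<24}{'probit coef':>16}{'probit ME':>16}"
        f"{'het coef':>16}{'het ME':>16}"
    ]

    def cell(est, se, p):
        if pd.isna(est):
            return ""
        s = _stars(p) if pd.notna(p) else ""
        return f"{est:.{decimals}f}{s} ({se:.{decimals}f})" if pd.notna(se) else f"{est:.{decimals}f}"

    for _, r in table.iterrows():
        lines.append(
            f"{r['variable']:<24}"
            f"{cell(r.get('coef_probit'), r.get('coef_se_probit'), r.get('coef_p_probit')):>16}"
            f"{cell(r.get('me_probit'), r.get('me_se_probit'), r.get('me_p_probit')):>16}"
            f"{cell(r.get('coef_het'), r.get('coef_se_het'), r.get('coef_p_het')):>16}"
            f"{cell(r.get('me_het'), r.get('me_se_het'), r.get('me_p_het')):>16}"
        )
    f = bundle["footer"]
    lines.append("-" * 88)
    lines.append(
        f"LogL: probit {f['probit']['loglik']:.{decimals}f}   "
        f"hetprobit {f['hetprobit']['loglik']:.{decimals}f}"
    )
    lines.append(
        f"Het-test chi2({f['hetprobit']['het_test_df']}) = "
        f"{f['hetprobit']['het_test_chi2']:.{decimals}f}"
        f"{_stars(f['hetprobit']['het_test_p'])}"
    )
    lines.append(
        f"AIC: {f['probit']['aic']:.{decimals}f} / {f['hetprobit']['aic']:.{decimals}f}   "
        f"BIC: {f['probit']['bic']:.{decimals}f} / {f['hetprobit']['bic']:.{decimals}f}   "
        f"McFadden R2: {f['probit']['mcfadden_r2']:.{decimals}f} / "
        f"{f['hetprobit']['mcfadden_r2']:.{decimals}f}"
    )
    lines.append(f"N = {f['hetprobit']['n']}")
    return "\n".join(lines)


def _write_bundle(bundle: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["table"].to_csv(outdir / "results_table.csv", index=False)
    with open(outdir / "results_table.json", "w") as fh:
        json.dump(
            {
                "table": bundle["table"].to_dict(orient="records"),
                "footer": bundle["footer"],
                "probit": bundle["probit"].to_dict(),
                "hetprobit": bundle["hetprobit"].to_dict(),
            },
            fh,
            indent=2,
            default=float,
        )
    incidence = {k: v for k, v in bundle["incidence"].items()}
    if "incidence_by_quintile" in incidence:
        incidence["incidence_by_quintile"] = {
            str(k): v for k, v in incidence["incidence_by_quintile"].items()
        }
    with open(outdir / "incidence.json", "w") as fh:
        json.dump(incidence, fh, indent=2, default=float)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, default=str)
    if bundle.get("che_table") is not None:
        bundle["che_table"].to_csv(outdir / "che_results.csv", index=False)
    with open(outdir / "results_table.txt", "w") as fh:
        fh.write(format_table(bundle) + "\n")
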