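"""Catastrophic health expenditure (CHE) measurement from expenditure microdata.

Implements the capacity-to-pay construction of Xu et al.: a household's
subsistence (food poverty) spending is the weighted average equivalized food
expenditure of households whose food share of total expenditure lies between
the 45th and 55th weighted percentiles; capacity to pay is total expenditure
net of subsistence spending (or net of actual food spending for households
eating below the subsistence line); out-of-pocket health spending is
catastrophic when it reaches 40% of capacity to pay.  Household size is
equivalized as size**0.56 to reflect consumption sharing.

All aggregation respects sampling weights.  The construction is invariant to
rescaling the currency and to rescaling the weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HouseholdRecord",
    "CheParameters",
    "food_share",
    "weighted_quantile",
    "subsistence_line",
    "household_subsistence",
    "capacity_to_pay",
    "che_indicator",
    "run_che_pipeline",
    "weighted_quintile_labels",
]

logger = logging.getLogger("cheprobit")


@dataclass
class HouseholdRecord:
    """One household's expenditures, health spending, size, weight, covariates."""

    household_id: object
    weight: float
    total_exp: float
    food_exp: float
    oop: float
    hh_size: int
    covariates: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.total_exp <= 0:
            raise ValueError("total expenditure must be positive")
        if not (0 <= self.food_exp <= self.total_exp):
            raise ValueError("food expenditure must lie in [0, total expenditure]")
        if self.oop < 0:
            raise ValueError("OOP health expenditure must be non-negative")
        if self.hh_size < 1:
            raise ValueError("household size must be at least 1")


@dataclass(frozen=True)
class CheParameters:
    """Thresholds of the CHE construction.

    threshold: catastrophic fraction of capacity to pay (0.40).
    eq_scale: equivalence-scale exponent on household size (0.56).
    percentile_window: weighted food-share percentile window selecting the
        households whose food spending defines the subsistence line.
    strict: if True the catastrophe rule is oop/ctp > threshold instead of
        >= (with threshold=1 this recovers the literal "health spending
        exceeds capacity to pay" rule).
    """

    threshold: float = 0.40
    eq_scale: float = 0.56
    percentile_window: tuple[float, float] = (0.45, 0.55)
    strict: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.percentile_window
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if not (0 < self.eq_scale <= 1):
            raise ValueError("equivalence-scale exponent must be in (0, 1]")
        if not (0 <= lo < hi <= 1):
            raise ValueError("percentile window must satisfy 0 <= lo < hi <= 1")


def food_share(food_exp, total_exp):
    """Food expenditure as a fraction of total expenditure (scalar or array)."""
    total = np.asarray(total_exp, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total expenditure must be positive")
    share = np.asarray(food_exp, dtype=float) / total
    return float(share) if share.ndim == 0 else share


def weighted_quantile(values, weights, q: float) -> float:
    """Weighted quantile by CDF inversion with midpoint interpolation.

    Ties in ``values`` are pooled (their weights summed) before the
    cumulative-weight midpoints p_j = (C_j - w_j/2) / W are interpolated
    linearly; q below the first midpoint (above the last) returns the minimum
    (maximum).  Pooling makes the convention exactly equivalent to replicating
    each observation ``w`` times when the weights are integers, and with
    uniform weights it reduces to the unweighted midpoint-interpolation
    quantile.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    uniq, inverse = np.unique(v, return_inverse=True)
    wsum = np.bincount(inverse, weights=w)
    cum = np.cumsum(wsum)
    mid = (cum - wsum / 2.0) / cum[-1]
    return float(np.interp(q, mid, uniq))


def subsistence_line(data: pd.DataFrame, params: CheParameters) -> float:
    """Subsistence spending per equivalent adult.

    Selects households whose food share lies in the closed weighted-percentile
    window (default [p45, p55]) and returns the weighted mean of their
    equivalized food expenditure food_exp / hh_size**eq_scale.
    """
    shares = food_share(data["food_exp"], data["total_exp"])
    w = np.asarray(data["weight"], dtype=float)
    lo_q, hi_q = params.percentile_window
    p_lo = weighted_quantile(shares, w, lo_q)
    p_hi = weighted_quantile(shares, w, hi_q)
    sel = (shares >= p_lo) & (shares <= p_hi)
    if not sel.any():
        raise RuntimeError(
            f"no households with food share in [{p_lo:.4f}, {p_hi:.4f}]"
        )
    eq_food = (
        np.asarray(data["food_exp"], dtype=float)[sel]
        / np.asarray(data["hh_size"], dtype=float)[sel] ** params.eq_scale
    )
    return float(np.average(eq_food, weights=w[sel]))


def household_subsistence(hh_size, line: float, params: CheParameters):
    """Household subsistence spending: line x size**eq_scale."""
    if line <= 0:
        raise ValueError("subsistence line must be positive")
    return line * np.asarray(hh_size, dtype=float) ** params.eq_scale


def capacity_to_pay(total_exp, food_exp, se_h):
    """Total expenditure net of subsistence spending, with the actual-food
    fallback: households whose food spending is below the subsistence line
    have their actual food expenditure deducted instead."""
    total = np.asarray(total_exp, dtype=float)
    food = np.asarray(food_exp, dtype=float)
    se = np.asarray(se_h, dtype=float)
    ctp = np.where(food >= se, total - se, total - food)
    return float(ctp) if ctp.ndim == 0 else ctp


def che_indicator(oop, ctp, params: CheParameters):
    """1 iff OOP health spending reaches ``threshold`` of capacity to pay."""
    ctp_arr = np.asarray(ctp, dtype=float)
    if np.any(ctp_arr <= 0):
        raise ValueError("capacity to pay must be positive (flag upstream)")
    ratio = np.asarray(oop, dtype=float) / ctp_arr
    che = (ratio > params.threshold) if params.strict else (ratio >= params.threshold)
    che = che.astype(int)
    return int(che) if che.ndim == 0 else che


def weighted_quintile_labels(values, weights) -> np.ndarray:
    """Quintile labels 1..5 by weighted-CDF cutpoints; ties go to the lower
    quintile (a value exactly at a cutpoint stays below it)."""
    v = np.asarray(values, dtype=float)
    cuts = [weighted_quantile(v, weights, q) for q in (0.2, 0.4, 0.6, 0.8)]
    labels = np.ones(v.shape, dtype=int)
    for cut in cuts:
        labels += (v > cut).astype(int)
    return labels


def run_che_pipeline(
    data: pd.DataFrame, params: CheParameters | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full CHE construction on a household table.

    Returns a per-household result table (household_id, eq_size, food_share,
    subsistence, capacity_to_pay, oop_share_of_ctp, che, flagged) and a
    summary dict with the subsistence line, weighted incidence overall and by
    weighted quintile of total expenditure, and the flagged-household count.
    Households with non-positive capacity to pay are flagged (che = NA) and
    excluded from the incidence and from downstream modelling.
    """
    params = params or CheParameters()
    line = subsistence_line(data, params)
    size = np.asarray(data["hh_size"], dtype=float)
    total = np.asarray(data["total_exp"], dtype=float)
    food = np.asarray(data["food_exp"], dtype=float)
    oop = np.asarray(data["oop"], dtype=float)
    w = np.asarray(data["weight"], dtype=float)

    eq_size = size ** params.eq_scale
    se_h = household_subsistence(size, line, params)
    ctp = capacity_to_pay(total, food, se_h)
    flagged = ctp <= 0
    n_flagged = int(flagged.sum())
    if n_flagged:
        logger.warning(
            "run_che_pipeline: %d households with non-positive capacity to pay "
            "flagged and excluded", n_flagged,
        )

    oop_share = np.full_like(ctp, np.nan)
    oop_share[~flagged] = oop[~flagged] / ctp[~flagged]
    che = np.full(len(data), np.nan)
    if (~flagged).any():
        che[~flagged] = che_indicator(oop[~flagged], ctp[~flagged], params)

    ids = (
        data["household_id"]
        if "household_id" in data.columns
        else pd.RangeIndex(len(data))
    )
    result = pd.DataFrame(
        {
            "household_id": np.asarray(ids),
            "eq_size": eq_size,
            "food_share": food_share(food, total),
            "subsistence": se_h,
            "capacity_to_pay": ctp,
            "oop_share_of_ctp": oop_share,
            "che": che,
            "flagged": flagged,
        }
    )

    ok = ~flagged
    incidence = float(np.average(che[ok], weights=w[ok]))
    quint = weighted_quintile_labels(total, w)
    by_quintile = {}
    for qlab in range(1, 6):
        sel = ok & (quint == qlab)
        by_quintile[qlab] = (
            float(np.average(che[sel], weights=w[sel])) if sel.any() else float("nan")
        )
    summary = {
        "subsistence_line": line,
        "incidence": incidence,
        "incidence_by_quintile": by_quintile,
        "n_households": int(len(data)),
        "n_flagged": n_flagged,
        "n_modeled": int(ok.sum()),
    }
    return result, summary
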