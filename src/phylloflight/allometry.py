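"""Allometric log-log scaling fits, isometry tests, wing/disc loading, and
the power-available vs power-required scaling chain.

Scaling fits regress a log10-transformed trait on log10 body length per
sex, with a sequential (type-I) ANOVA for size, sex and their interaction.
Isometry (geometric similarity) predicts slopes of 1 for lengths, 2 for
areas and 3 for masses; a verdict compares the 95% CI of each slope to
that expectation.

The power chain uses momentum-jet theory for slow flight: the power
required P_r scales as W_B * DL^(1/2) with W_B body weight and DL the
wing disc loading W_B / (2 pi L_w^2 theta/360); under isometry W_B ~ BL^3
and DL ~ BL, so P_r ~ BL^3.5.  The power available P_a is muscle work
(~BL^3) times flapping frequency (~BL^-1), hence ~BL^2.  An empirical
disc-loading exponent beta_DL maps to beta_Pr = 3 + beta_DL/2, an exact
affine transform through which CI endpoints propagate unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "GroupSlope",
    "ScalingFit",
    "PowerScaling",
    "fit_allometry",
    "isometry_verdict",
    "interval_verdict",
    "wing_loading",
    "disc_loading",
    "power_scaling",
    "dimorphism_summary",
]


@dataclass
class GroupSlope:
    slope: float
    se: float
    ci: tuple[float, float]
    intercept: float
    n: int


@dataclass
class ScalingFit:
    """Per-group log-log slopes with 95% CIs and sequential tests."""

    response: str
    predictor: str
    log_base: float
    groups: dict[str, GroupSlope]
    anova: pd.DataFrame | None   # sequential (type I) tests: predictor, group, interaction
    notes: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(g.n for g in self.groups.values())


def fit_allometry(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    group: str | None = "sex",
    log_base: float = 10.0,
) -> ScalingFit:
    """Ordinary least-squares log-log scaling fit, optionally per group.

    Slopes, standard errors and 95% CIs are estimated per group by OLS on
    the log-transformed data.  When a grouping column with two or more
    levels is present, sequential (type-I) ANOVA tests for the predictor,
    group and their interaction are reported in that order; with a single
    level the group/interaction tests are skipped with a notice.  Rows
    with non-positive response or predictor values are an error (log
    domain), listing the offending rows.
    """
    cols = [response, predictor] + ([group] if group else [])
    df = table[cols].dropna().copy()
    if len(df) < 3:
        raise ValueError(f"need at least 3 rows per group (table has {len(df)})")
    bad = df.index[(df[response] <= 0) | (df[predictor] <= 0)].tolist()
    if bad:
        raise ValueError(f"non-positive values in log-log fit at rows {bad}")
    logf = lambda v: np.log(v) / np.log(log_base)
    df["_ly"] = logf(df[response].to_numpy(float))
    df["_lx"] = logf(df[predictor].to_numpy(float))

    notes: list[str] = []
    if group:
        levels = list(pd.unique(df[group]))
    else:
        levels = ["all"]
        df["_grp"] = "all"
        group_col = "_grp"
    group_col = group if group else "_grp"

    groups: dict[str, GroupSlope] = {}
    for lev in levels:
        sub = df[df[group_col] == lev]
        if len(sub) < 3:
            raise ValueError(f"need at least 3 rows per group (group {lev!r} has {len(sub)})")
        X = sm.add_constant(sub["_lx"].to_numpy())
        fit = sm.OLS(sub["_ly"].to_numpy(), X).fit()
        lo, hi = fit.conf_int(alpha=0.05)[1]
        groups[str(lev)] = GroupSlope(
            slope=float(fit.params[1]), se=float(fit.bse[1]),
            ci=(float(lo), float(hi)), intercept=float(fit.params[0]), n=len(sub),
        )

    anova = None
    if group and len(levels) >= 2:
        # numeric dummies keep the term order predictor -> group ->
        # interaction, so the sequential (type I) decomposition tests the
        # effects in that order
        dummies = []
        for j, lev in enumerate(levels[1:], start=1):
            col = f"_g{j}"
            df[col] = (df[group_col] == lev).astype(float)
            dummies.append(col)
        main = " + ".join(dummies)
        inter = " + ".join(f"_lx:{d}" for d in dummies)
        full = smf.ols(f"_ly ~ _lx + {main} + {inter}", data=df).fit()
        anova = sm.stats.anova_lm(full, typ=1)
        anova.index = (["predictor"] + ["group"] * len(dummies)
                       + ["interaction"] * len(dummies) + ["Residual"])
    elif group:
        notes.append(f"single level in group column {group!r}: group and interaction tests skipped")

    return ScalingFit(response=response, predictor=predictor, log_base=log_base,
                      groups=groups, anova=anova, notes=notes)


def interval_verdict(ci_lo: float, ci_hi: float, expected: float) -> str:
    """Isometry verdict for one closed 95% CI against the expected slope."""
    if ci_lo <= expected <= ci_hi:
        return "consistent"
    return "departs (below)" if ci_hi < expected else "departs (above)"


def isometry_verdict(fit: ScalingFit, expected_slope: float) -> dict[str, str]:
    """Per-group isometry verdict: does the slope CI bracket the expected value?

    The CI is treated as closed: an endpoint exactly equal to the
    expectation counts as consistent.
    """
    return {g: interval_verdict(s.ci[0], s.ci[1], expected_slope)
            for g, s in fit.groups.items()}


def wing_loading(mass_g: float, wing_area_mm2: float, g: float = 9.81) -> float:
    """Wing loading (N/m^2): body weight over total wing area."""
    if wing_area_mm2 <= 0:
        raise ValueError("wing area must be positive")
    return (mass_g / 1000.0) * g / (wing_area_mm2 * 1e-6)


def disc_loading(W_B: float, L_w: float, theta: float) -> float:
    """Wing disc loading DL = W_B / (2 pi L_w^2 theta/360), N/m^2.

    The wing disc area is the annular sector of radius L_w (wing length, m)
    swept through the stroke amplitude theta (degrees) by the two wings.
    """
    if L_w <= 0:
        raise ValueError("wing length must be positive")
    if not 0.0 < theta <= 360.0:
        raise ValueError("stroke amplitude must lie in (0, 360] degrees")
    return W_B / (2.0 * math.pi * L_w**2 * theta / 360.0)


@dataclass
class PowerScaling:
    beta_Pa: float
    beta_DL: float
    beta_DL_ci: tuple[float, float] | None
    beta_Pr: float
    beta_Pr_ci: tuple[float, float] | None
    beta_Pr_isometric: float
    delta_trend: str


def power_scaling(
    beta_DL: float,
    beta_DL_ci: tuple[float, float] | None = None,
    beta_W: float = 3.0,
    beta_work: float = 3.0,
    beta_freq: float = -1.0,
) -> PowerScaling:
    """Map a disc-loading exponent to power-required/available exponents.

    beta_Pa = beta_work + beta_freq (2 at defaults); beta_Pr = beta_W +
    beta_DL/2 with CI endpoints mapped through the same affine transform
    (exact, no resampling); the isometric expectation is beta_W + 1/2 =
    3.5.  The power margin ΔP = P_a - P_r declines faster than isometry
    predicts when beta_Pr exceeds both its isometric value and beta_Pa.
    """
    if not np.isfinite(beta_DL):
        raise ValueError("beta_DL must be finite")
    beta_Pa = beta_work + beta_freq
    beta_Pr = beta_W + beta_DL / 2.0
    ci = None
    if beta_DL_ci is not None:
        ci = (beta_W + beta_DL_ci[0] / 2.0, beta_W + beta_DL_ci[1] / 2.0)
    iso = beta_W + 0.5
    if beta_Pr > iso and beta_Pr > beta_Pa:
        trend = "faster-than-isometric decline of ΔP"
    else:
        trend = "ΔP decline not faster than isometric"
    return PowerScaling(beta_Pa=beta_Pa, beta_DL=beta_DL, beta_DL_ci=beta_DL_ci,
                        beta_Pr=beta_Pr, beta_Pr_ci=ci, beta_Pr_isometric=iso,
                        delta_trend=trend)


def dimorphism_summary(table: pd.DataFrame, trait: str, sex_col: str = "sex") -> tuple[float, float]:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum test of a trait between sexes.

    Returns (U statistic, p value).  Exact p values are used for small
    tie-free samples, the normal approximation otherwise.
    """
    sexes = pd.unique(table[sex_col])
    if len(sexes) < 2:
        raise ValueError("both sexes must be present for a dimorphism test")
    a = table.loc[table[sex_col] == sexes[0], trait].dropna().to_numpy(float)
    b = table.loc[table[sex_col] == sexes[1], trait].dropna().to_numpy(float)
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (no_ties and max(len(a), len(b)) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
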