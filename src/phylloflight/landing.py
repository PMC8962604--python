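"""Landing-impact model on a cantilever leaf, with safety factors.

A landing platform (leaf plus petiole) is idealized as a uniform,
initially horizontal cantilever beam of length L and flexural stiffness
EI, point-loaded at the tip by the insect's weight.  The small-deflection
tip deflection is delta = m g L^3 / (3 EI); the landing impact force
follows from the work-energy principle, F_i = m g + m v^2 / (2 delta).
Safety factors compare attachment forces with the loads: the static
safety factor is attachment force over body weight; the dynamic safety
factor is friction force over the total landing load F_i (which already
contains the weight term).  Values below one predict slippage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LeafSpec",
    "LandingSpeedModel",
    "SMALL_LEAF",
    "LARGE_LEAF",
    "G_LANDING",
    "leaf_deflection",
    "impact_force",
    "static_safety_factor",
    "dynamic_safety_factor",
    "fit_landing_speed_model",
    "landing_sweep",
]

#: Gravitational acceleration used throughout the landing model (m/s^2).
G_LANDING = 9.81


@dataclass(frozen=True)
class LeafSpec:
    """Cantilever-leaf mechanical model: length L (m), flexural stiffness EI (N m^2)."""

    L: float
    EI: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.L <= 0 or self.EI <= 0:
            raise ValueError("leaf length and flexural stiffness must be positive")


# The two published leaf parameter pairs spanning compliant-small to stiff-large.
SMALL_LEAF = LeafSpec(L=0.23, EI=2.67e-3, label="small")
LARGE_LEAF = LeafSpec(L=0.86, EI=28.48e-3, label="large")


def leaf_deflection(m: float, leaf: LeafSpec, g: float = G_LANDING) -> tuple[float, float, bool]:
    """Tip deflection of the loaded leaf.

    Returns (delta in m, tip slope angle in degrees, small-deflection
    validity flag).  delta = m g L^3 / (3 EI); the tip slope angle of a
    tip-loaded cantilever is atan(m g L^2 / (2 EI)) = atan(3 delta / 2L),
    and the linear beam theory used here is flagged valid below 5 degrees.
    """
    if m < 0:
        raise ValueError("mass must be non-negative")
    if leaf.EI <= 0:
        raise ValueError("flexural stiffness must be positive")
    delta = m * g * leaf.L**3 / (3.0 * leaf.EI)
    angle = math.degrees(math.atan(m * g * leaf.L**2 / (2.0 * leaf.EI)))
    return delta, angle, angle < 5.0


def impact_force(m: float, v: float, delta: float, g: float = G_LANDING) -> float:
    """Landing impact force F_i = m g + m v^2 / (2 delta) (work-energy principle).

    The first term is the static weight load, the second the kinetic energy
    dissipated over the leaf deflection.  A rigid substrate (delta = 0)
    with nonzero landing speed is a singularity and raises.
    """
    if m < 0:
        raise ValueError("mass must be non-negative")
    if v == 0:
        return m * g
    if delta <= 0:
        raise ValueError("delta must be positive when landing speed is nonzero "
                         "(rigid-substrate singularity)")
    return m * g + m * v**2 / (2.0 * delta)


def static_safety_factor(F_att: float, m: float, g: float = G_LANDING) -> float:
    """Static safety factor: attachment force / body weight."""
    if m <= 0:
        raise ValueError("mass must be positive")
    return F_att / (m * g)


def dynamic_safety_factor(F_friction: float, F_i: float, m: float = 0.0,
                          g: float = G_LANDING, double_count_weight: bool = False) -> float:
    """Dynamic safety factor: friction force / total landing load.

    The denominator is the work-energy impact force F_i = mg + mv^2/(2 delta),
    which already contains the weight — weight is counted once.  Setting
    ``double_count_weight`` adds mg again (sensitivity variant for the
    alternative reading of the load as "impact + weight").
    """
    if F_i <= 0:
        raise ValueError("impact force must be positive")
    denom = F_i + (m * g if double_count_weight else 0.0)
    return F_friction / denom


@dataclass
class LandingSpeedModel:
    """Linear predictor of landing speed (m/s) from body mass (kg)."""

    intercept: float
    slope: float           # (m/s) per kg
    n_individuals: int
    slope_ci: tuple[float, float]
    slope_se: float

    def predict(self, mass_kg):
        return self.intercept + self.slope * np.asarray(mass_kg, dtype=float)


def fit_landing_speed_model(trials: pd.DataFrame) -> LandingSpeedModel:
    """Fit landing speed vs body mass on repeated trials per individual.

    ``trials`` needs columns ``individual_id``, ``mass_kg``,
    ``landing_speed_m_s``.  Repeated measures are collapsed to
    per-individual means, then ordinary least squares gives the
    fixed-effect intercept and slope (the pair downstream predictions
    consume); the slope 95% CI comes from the OLS fit.
    """
    req = {"individual_id", "mass_kg", "landing_speed_m_s"}
    missing = req - set(trials.columns)
    if missing:
        raise ValueError(f"trials table missing columns: {sorted(missing)}")
    per = trials.groupby("individual_id", sort=True).agg(
        mass_kg=("mass_kg", "mean"), landing_speed_m_s=("landing_speed_m_s", "mean")
    )
    if len(per) < 3:
        raise ValueError("need at least 3 individuals to fit the landing-speed model")
    m = per["mass_kg"].to_numpy(float)
    if np.ptp(m) == 0:
        raise ValueError("all masses identical: slope unidentifiable")
    y = per["landing_speed_m_s"].to_numpy(float)
    X = sm.add_constant(m)
    fit = sm.OLS(y, X).fit()
    lo, hi = fit.conf_int(alpha=0.05)[1]
    return LandingSpeedModel(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        n_individuals=len(per),
        slope_ci=(float(lo), float(hi)),
        slope_se=float(fit.bse[1]),
    )


def landing_sweep(
    table: pd.DataFrame,
    leaves: list[LeafSpec],
    model: LandingSpeedModel,
    g: float = G_LANDING,
    double_count_weight: bool = False,
) -> pd.DataFrame:
    """Predicted landing loads and dynamic safety factors per individual x leaf.

    ``table`` needs columns ``id``, ``mass_g``, ``friction_mN``.  For each
    row and leaf, landing speed is predicted from mass, then deflection,
    impact force and SF_dynamic are computed.  Rows lacking a friction
    force are skipped with a warning.  log10 columns of mass, total load
    and safety factor are appended for downstream scaling fits.
    """
    out = []
    for _, row in table.iterrows():
        if "friction_mN" not in row or pd.isna(row["friction_mN"]):
            warnings.warn(f"individual {row.get('id', '?')} has no friction force; skipped",
                          stacklevel=2)
            continue
        m = float(row["mass_g"]) / 1000.0
        v = float(model.predict(m))
        for leaf in leaves:
            delta, angle, valid = leaf_deflection(m, leaf, g=g)
            fi = impact_force(m, v, delta, g=g)
            sf = dynamic_safety_factor(row["friction_mN"] / 1000.0, fi, m=m, g=g,
                                       double_count_weight=double_count_weight)
            out.append({
                "id": row["id"],
                "leaf": leaf.label or f"L={leaf.L}",
                "mass_g": row["mass_g"],
                "mass_kg": m,
                "landing_speed_m_s": v,
                "delta_m": delta,
                "tip_slope_deg": angle,
                "small_deflection_valid": valid,
                "F_i_N": fi,
                "SF_dynamic": sf,
            })
    df = pd.DataFrame(out, columns=["id", "leaf", "mass_g", "mass_kg", "landing_speed_m_s",
                                    "delta_m", "tip_slope_deg", "small_deflection_valid",
                                    "F_i_N", "SF_dynamic"])
    if len(df):
        df = df.sort_values(["leaf", "mass_g"], kind="stable").reset_index(drop=True)
        df["log10_mass_g"] = np.log10(df["mass_g"])
        df["log10_load_mN"] = np.log10(df["F_i_N"] * 1000.0)
        df["log10_SF_dynamic"] = np.log10(df["SF_dynamic"])
    return df
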