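"""Aerodynamic-coefficient post-processing of external CFD force tables.

Drag and lift coefficients referenced to the projected frontal area A:
C_D = 2 F_drag / (rho v^2 A), C_L = 2 F_lift / (rho v^2 A); forces are
also expressed relative to body weight.  Includes the Reynolds number,
the Morrison single-formula sphere-drag correlation used to sanity-check
simulations, and the shape-modified model-weight estimate built from a
linear male mass-vs-body-length regression plus an abdominal areal
density for added or removed 'leaf-like' lobes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AeroForceRecord",
    "AeroCoefficients",
    "MassLengthModel",
    "RHO_CFD",
    "RHO_MISSOULA",
    "MU_AIR_20C",
    "aero_coefficients",
    "reynolds",
    "sphere_drag_morrison",
    "fit_mass_length",
    "model_weight",
    "process_aero_table",
]

#: Air density used for coefficient work (CFD default air, kg/m^3).
RHO_CFD = 1.20473
#: Air density at the flight-experiment site (978 m elevation), kg/m^3.
RHO_MISSOULA = 1.07
#: Dynamic viscosity of air at 20 C, Pa s.
MU_AIR_20C = 1.82e-5


@dataclass(frozen=True)
class AeroForceRecord:
    """One body model's CFD output row."""

    model_id: str
    BL_mm: float
    aspect_ratio: float
    frontal_area_m2: float
    F_drag_N: float
    F_lift_N: float
    rho: float = RHO_CFD
    v: float = 1.57

    def __post_init__(self) -> None:
        if self.frontal_area_m2 <= 0 or self.v <= 0 or self.rho <= 0:
            raise ValueError("frontal area, speed and density must be positive")


@dataclass(frozen=True)
class AeroCoefficients:
    C_D: float
    C_L: float
    L_over_D: float
    rel_drag: float
    rel_lift: float


def aero_coefficients(rec: AeroForceRecord, weight: float) -> AeroCoefficients:
    """Coefficients and weight-relative forces for one record.

    ``weight`` is the model's body weight in newtons; relative forces are
    F/weight.  L/D is C_L/C_D (equivalently F_lift/F_drag).
    """
    q = 0.5 * rec.rho * rec.v**2 * rec.frontal_area_m2
    if q <= 0:
        raise ValueError("zero dynamic pressure")
    if weight <= 0:
        raise ValueError("weight must be positive for relative forces")
    cd = rec.F_drag_N / q
    cl = rec.F_lift_N / q
    return AeroCoefficients(
        C_D=cd, C_L=cl,
        L_over_D=cl / cd if cd != 0 else float("nan"),
        rel_drag=rec.F_drag_N / weight,
        rel_lift=rec.F_lift_N / weight,
    )


def reynolds(rho: float, v: float, L_char: float, mu: float = MU_AIR_20C) -> float:
    """Reynolds number Re = rho v L / mu; L_char defaults to body length in use."""
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    if rho <= 0 or v <= 0 or L_char <= 0:
        raise ValueError("density, speed and length must be positive")
    return rho * v * L_char / mu


def sphere_drag_morrison(Re):
    """Morrison's single-formula sphere-drag correlation C_D(Re).

    C_D = 24/Re + 2.6 (Re/5) / (1 + (Re/5)^1.52)
        + 0.411 (Re/263000)^(-7.94) / (1 + (Re/263000)^(-8.00))
        + 0.25 (Re/1e6) / (1 + Re/1e6)

    Valid across the laminar range up to the drag crisis; reduces to the
    Stokes law 24/Re as Re -> 0.  Accepts scalars or arrays.  The third
    term is evaluated in the algebraically equivalent overflow-safe form
    0.411 / (x^7.94 + x^-0.06) with x = Re/263000.
    """
    Re = np.asarray(Re, dtype=float)
    if np.any(Re <= 0):
        raise ValueError("Re must be positive")
    x5 = Re / 5.0
    x263 = Re / 263000.0
    cd = (24.0 / Re
          + 2.6 * x5 / (1.0 + x5**1.52)
          + 0.411 / (x263**7.94 + x263**-0.06)
          + 0.25 * (Re / 1e6) / (1.0 + Re / 1e6))
    return float(cd) if cd.ndim == 0 else cd


@dataclass
class MassLengthModel:
    """Linear regression of male body mass (g) on body length (mm)."""

    intercept: float
    slope: float           # g per mm
    bl_range: tuple[float, float]
    n: int

    def predict_g(self, BL_mm):
        return self.intercept + self.slope * np.asarray(BL_mm, dtype=float)


def fit_mass_length(morph_males: pd.DataFrame) -> MassLengthModel:
    """Fit the linear male mass-vs-BL regression used for model weights."""
    df = morph_males.dropna(subset=["mass_g", "body_length_mm"])
    if len(df) < 3:
        raise ValueError("need at least 3 males to fit mass vs body length")
    x = df["body_length_mm"].to_numpy(float)
    y = df["mass_g"].to_numpy(float)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return MassLengthModel(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                           bl_range=(float(x.min()), float(x.max())), n=len(df))


def model_weight(
    BL_mm: float,
    delta_abd_area_m2: float,
    mass_model: MassLengthModel,
    areal_density_g_m2: float = 89.7,
    g: float = 9.81,
) -> float:
    """Weight (N) of a body model, shape-corrected by abdominal areal density.

    The reference mass comes from the mass-vs-BL regression at BL; models
    whose abdominal lobes were widened or shrunk gain or lose mass at
    ``areal_density_g_m2`` (default 89.7 g/m^2, the measured areal density
    of the leaf-like abdominal expansions) times the area change.  Body
    lengths well outside the fitted range trigger an extrapolation warning.
    """
    lo, hi = mass_model.bl_range
    span = hi - lo
    if BL_mm < lo - 0.1 * span or BL_mm > hi + 0.1 * span:
        warnings.warn(f"BL {BL_mm} mm outside the fitted range [{lo:.1f}, {hi:.1f}]; "
                      "extrapolating the mass regression", stacklevel=2)
    mass_g = float(mass_model.predict_g(BL_mm)) + areal_density_g_m2 * delta_abd_area_m2
    return mass_g / 1000.0 * g


def process_aero_table(
    forces: pd.DataFrame,
    mass_model: MassLengthModel,
    delta_area_col: str | None = None,
    g: float = 9.81,
) -> pd.DataFrame:
    """Coefficient table from a CFD force table.

    ``forces`` follows the ``aero_forces.csv`` layout (model_id, BL_mm,
    aspect_ratio, frontal_area_m2, F_drag_N, F_lift_N, rho, v).  Model
    weights come from the mass regression, optionally shape-corrected via
    a column of abdominal area changes (m^2).
    """
    rows = []
    for _, r in forces.iterrows():
        rec = AeroForceRecord(
            model_id=str(r["model_id"]), BL_mm=float(r["BL_mm"]),
            aspect_ratio=float(r["aspect_ratio"]),
            frontal_area_m2=float(r["frontal_area_m2"]),
            F_drag_N=float(r["F_drag_N"]), F_lift_N=float(r["F_lift_N"]),
            rho=float(r.get("rho", RHO_CFD)), v=float(r.get("v", 1.57)),
        )
        dA = float(r[delta_area_col]) if delta_area_col else 0.0
        w = model_weight(rec.BL_mm, dA, mass_model, g=g)
        c = aero_coefficients(rec, w)
        rows.append({
            "model_id": rec.model_id, "BL_mm": rec.BL_mm,
            "aspect_ratio": rec.aspect_ratio, "weight_N": w,
            "C_D": c.C_D, "C_L": c.C_L, "L_over_D": c.L_over_D,
            "rel_drag": c.rel_drag, "rel_lift": c.rel_lift,
        })
    return pd.DataFrame(rows)
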