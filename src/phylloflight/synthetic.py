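"""Ground-truthed synthetic data: drop-recovery flights, calibration drops,
morphometrics and attachment forces.

The generator emulates the structure of drop-release flight trials in a
sexually dimorphic leaf insect: a held male is released, free-falls while
tipping nose-down, opens its wings (t1), actively rights itself at a roughly
constant pitch rate until the pitch stabilizes (t2), then flies at a steady
velocity until contacting the landing target.  Morphometric and attachment
tables are drawn from log-normal distributions with prescribed power-law
(allometric) structure so that downstream slope estimators can be checked
against known exponents.

Trajectories here are kinematic constructions, not aerodynamic simulations:
they provide exact ground truth for recovery tests, nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .track import TrajectoryTrack

__all__ = [
    "TrajectoryParams",
    "GroundTruth",
    "MorphSimSpec",
    "simulate_drop_flight",
    "simulate_ball_drop",
    "simulate_morphometrics",
    "simulate_attachment",
    "simulate_landing_trials",
    "simulate_aero_forces",
    "G_CALIBRATION",
]

#: Reference gravitational acceleration used for trajectory construction
#: and the vertical-direction calibration (m/s^2).
G_CALIBRATION = 9.805


@dataclass
class TrajectoryParams:
    """Parameters of one synthetic drop-recovery flight trial.

    Defaults describe a typical adult male: body length 52.6 mm, released
    nose-level, tipping to -28 deg during free fall, righting at 400 deg/s
    up to a stable +44 deg pitch, then flying at 1.57 m/s horizontally with
    a slight sink, beating its wings at 25 Hz with 120 deg stroke amplitude.
    """

    fps: float = 500.0
    pitch0: float = 0.0           # deg, pitch at release
    pitch_min: float = -28.0      # deg, pitch at the end of free fall
    omega_true: float = 400.0     # deg/s, righting rotational velocity
    pitch_stable: float = 44.0    # deg, post-recovery pitch
    t_freefall: float = 0.25      # s
    vx_steady: float = 1.57       # m/s
    vy_steady: float = -0.20      # m/s
    wingbeat_freq: float = 25.0   # Hz
    stroke_amp_true: float = 120.0  # deg
    wing_length: float = 0.040    # m
    com_fraction: float = 0.5     # hinge/COM position along head->abdomen axis
    body_length: float = 0.0526   # m
    noise_sd: float = 0.0         # m, isotropic Gaussian landmark noise
    duration: float = 1.2         # s
    seed: int = 0
    pitch_osc_amp: float = 0.0    # deg, optional within-wingbeat pitch wobble
    x0: float = 0.0               # m, release position
    y0: float = 1.5               # m, release height

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.t_freefall >= self.duration:
            raise ValueError("t_freefall must be shorter than duration")
        if self.omega_true <= 0:
            raise ValueError("omega_true must be positive")
        if self.pitch_stable <= self.pitch_min:
            raise ValueError("pitch_stable must exceed pitch_min")
        if self.pitch_min >= self.pitch0:
            raise ValueError("pitch_min must be below pitch0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.com_fraction <= 1.0:
            raise ValueError("com_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Oracle values carried alongside a synthetic track."""

    omega_true: float
    vx_steady: float
    vy_steady: float
    wingbeat_freq: float
    stroke_amp_true: float
    t1_true: float
    t2_true: float
    landing_speed_true: float


def simulate_drop_flight(params: TrajectoryParams) -> tuple[TrajectoryTrack, GroundTruth]:
    """Build one drop-recovery trial and its ground truth.

    Construction: the centre of mass falls ballistically (g = 9.805 m/s^2)
    over [0, t_freefall]; its velocity then blends linearly, over the
    righting interval dt = (pitch_stable - pitch_min)/omega_true, to the
    constant steady velocity.  Pitch decreases monotonically (a cubic
    easing into its minimum with zero slope and curvature) from pitch0 to
    pitch_min during free fall, rises along a quintic smoothstep whose
    *average* rate over the righting interval is exactly omega_true, then
    stays constant.  The profile is C2 throughout: omega_true is defined
    as the mean righting rate, the quantity the rotational-velocity
    statistic measures, and the smooth construction avoids
    angular-acceleration impulses that no real maneuver contains.  Head
    and abdomen sit at
    +/- body_length/2 along the pitch direction around the COM; the wing
    tip oscillates sinusoidally about a hinge at ``com_fraction`` along the
    body axis once righting is complete.  Wing-reversal frame indices are
    stored in ``track.meta["reversal_frames"]``.
    """
    params.validate()
    t1 = params.t_freefall
    dt_right = (params.pitch_stable - params.pitch_min) / params.omega_true
    t2 = t1 + dt_right
    if t2 >= params.duration:
        raise ValueError(
            f"duration {params.duration} s too short to contain the righting "
            f"interval ending at {t2:.4f} s"
        )

    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration * params.fps))
    t = np.arange(n) / params.fps

    # pitch profile (deg): C2 piecewise — cubic fall easing into the minimum,
    # quintic smoothstep righting with mean rate omega_true
    pitch = np.empty(n)
    fall = t < t1
    right = (t >= t1) & (t < t2)
    dpitch = params.pitch_stable - params.pitch_min
    pitch[fall] = params.pitch_min + (params.pitch0 - params.pitch_min) * (1.0 - t[fall] / t1) ** 3
    s = (t[right] - t1) / dt_right
    pitch[right] = params.pitch_min + dpitch * s**3 * (10.0 - 15.0 * s + 6.0 * s**2)
    pitch[t >= t2] = params.pitch_stable
    if params.pitch_osc_amp > 0:
        osc = params.pitch_osc_amp * np.sin(2 * np.pi * params.wingbeat_freq * (t - t2))
        pitch = pitch + np.where(t >= t2, osc, 0.0)

    # COM velocity: ballistic -> linear blend -> steady
    v_fall_y = -G_CALIBRATION * np.minimum(t, t1)
    w = np.clip((t - t1) / dt_right, 0.0, 1.0)
    vx = w * params.vx_steady
    vy = (1 - w) * v_fall_y + w * params.vy_steady
    x = params.x0 + cumulative_trapezoid(vx, t, initial=0.0)
    y = params.y0 + cumulative_trapezoid(vy, t, initial=0.0)
    com = np.column_stack([x, y])

    rad = np.deg2rad(pitch)
    axis = np.column_stack([np.cos(rad), np.sin(rad)])
    head = com + 0.5 * params.body_length * axis
    abd = com - 0.5 * params.body_length * axis

    # wing tip about the hinge, flapping after t2
    hinge = head + params.com_fraction * (abd - head)
    phase = 2 * np.pi * params.wingbeat_freq * (t - t2)
    half = np.deg2rad(params.stroke_amp_true) / 2.0
    phi = np.where(t >= t2, half * np.sin(phase), 0.0)
    wdir = rad + np.pi / 2 + phi
    wing = hinge + params.wing_length * np.column_stack([np.cos(wdir), np.sin(wdir)])

    # reversal times: extrema of sin(phase) after t2
    period = 1.0 / params.wingbeat_freq
    n_rev = int(np.floor((params.duration - t2) / (period / 2)))
    rev_t = t2 + period / 4 + np.arange(n_rev) * period / 2
    reversal_frames = np.unique(np.round(rev_t * params.fps).astype(int))
    reversal_frames = reversal_frames[reversal_frames < n]

    if params.noise_sd > 0:
        head = head + rng.normal(0.0, params.noise_sd, head.shape)
        abd = abd + rng.normal(0.0, params.noise_sd, abd.shape)
        wing = wing + rng.normal(0.0, params.noise_sd, wing.shape)

    track = TrajectoryTrack(
        t=t, head=head, abd=abd, wing=wing, fps=params.fps, units_calibrated=True,
        meta={"reversal_frames": reversal_frames, "seed": params.seed},
    )
    truth = GroundTruth(
        omega_true=params.omega_true,
        vx_steady=params.vx_steady,
        vy_steady=params.vy_steady,
        wingbeat_freq=params.wingbeat_freq,
        stroke_amp_true=params.stroke_amp_true,
        t1_true=t1,
        t2_true=t2,
        landing_speed_true=math.hypot(params.vx_steady, params.vy_steady),
    )
    return track, truth


def simulate_ball_drop(
    g: float = G_CALIBRATION,
    fps: float = 500.0,
    noise_sd: float = 0.0,
    duration: float = 0.5,
    seed: int = 0,
    y0: float = 1.8,
) -> TrajectoryTrack:
    """Free-falling ball for vertical-direction / gravity calibration.

    Returns a single-landmark track with y(t) = y0 - g t^2 / 2 plus noise.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    pos = np.column_stack([np.zeros(n), y0 - 0.5 * g * t**2])
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, pos.shape)
    return TrajectoryTrack(t=t, head=pos, fps=fps, units_calibrated=True,
                           meta={"kind": "ball_drop", "g_true": g})


@dataclass
class MorphSimSpec:
    """Morphometric simulation: log-normal body length per sex, power-law traits.

    Mean masses default to the study population (males 0.46 g, females
    5.22 g, a ~11-fold dimorphism); male mean body length 52.6 mm.  Female
    body length defaults to 80 mm (not printed for the source population;
    a realistic value for large leaf-mimicking females).  Traits scale as
    BL^slope with log-normal residuals of sd ``residual_sd_log10`` dex.
    """

    n_males: int = 20
    n_females: int = 20
    mean_bl_male: float = 52.6    # mm
    mean_bl_female: float = 80.0  # mm
    cv_bl: float = 0.025
    slope_mass_bl: float = 3.0
    slope_wingarea_bl: float = 2.0
    slope_pad_bl: float = 2.0
    residual_sd_log10: float = 0.02
    mean_mass_male: float = 0.46  # g
    mean_mass_female: float = 5.22  # g
    seed: int = 0

    def validate(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise ValueError("counts must be non-negative")
        if self.cv_bl < 0 or self.residual_sd_log10 < 0:
            raise ValueError("cv and residual sd must be non-negative")


# per-sex trait means at the sex's mean body length, and the trait's
# dimensional isometric slope (1 length, 2 area, 3 mass)
_TRAIT_TABLE = {
    # column                (male mean, female mean, default slope key or number)
    "body_area_mm2":        (350.0, 1860.0, 2.0),
    "aspect_ratio":         (5.6, 2.55, 0.0),
    "circularity":          (0.30, 0.60, 0.0),
    "antenna_len_mm":       (35.0, 8.0, 1.0),
    "wing_area_mm2":        (1050.0, 2000.0, "slope_wingarea_bl"),
    "wing_length_mm":       (40.0, 30.0, 1.0),
    "muscle_mass_mg":       (30.0, 0.0, "slope_mass_bl"),
    "arolium_area_mm2":     (0.25, 0.65, "slope_pad_bl"),
    "euplantula_area_mm2":  (0.75, 1.45, "slope_pad_bl"),
}


def simulate_morphometrics(spec: MorphSimSpec) -> pd.DataFrame:
    """Per-individual morphometrics table (one row per animal).

    Columns: id, sex (M/F), body_length_mm, mass_g, body_area_mm2,
    aspect_ratio, circularity, antenna_len_mm, wing_area_mm2,
    wing_length_mm, muscle_mass_mg, arolium_area_mm2, euplantula_area_mm2,
    pad_area_mm2.  Flight muscle mass is zero for the flightless females.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sd_log_bl = spec.cv_bl / np.log(10)  # CV of a log-normal ~ sd of ln for small CV

    rows = []
    for sex, n, bl_mean, mass_mean in (
        ("M", spec.n_males, spec.mean_bl_male, spec.mean_mass_male),
        ("F", spec.n_females, spec.mean_bl_female, spec.mean_mass_female),
    ):
        bl = bl_mean * 10 ** rng.normal(0.0, sd_log_bl, n)
        rel = bl / bl_mean

        def power_law(mean, slope, n=n, rel=rel):
            eps = rng.normal(0.0, spec.residual_sd_log10, n)
            return mean * rel**slope * 10**eps

        mass = power_law(mass_mean, spec.slope_mass_bl)
        traits = {}
        for col, (m_mean, f_mean, slope) in _TRAIT_TABLE.items():
            mean = m_mean if sex == "M" else f_mean
            if isinstance(slope, str):
                slope = getattr(spec, slope)
            traits[col] = power_law(mean, slope) if mean > 0 else np.zeros(n)
        for i in range(n):
            rows.append({
                "id": f"{sex}{i + 1:02d}",
                "sex": sex,
                "body_length_mm": bl[i],
                "mass_g": mass[i],
                **{col: traits[col][i] for col in _TRAIT_TABLE},
            })
    df = pd.DataFrame(rows, columns=["id", "sex", "body_length_mm", "mass_g", *_TRAIT_TABLE])
    df["pad_area_mm2"] = df["arolium_area_mm2"] + df["euplantula_area_mm2"]
    return df


def simulate_attachment(
    morph: pd.DataFrame,
    slope_friction: float = 2.0,
    slope_adhesion: float = 2.0,
    strength_at_ref: float = 63.0,
    residual_sd_log10: float = 0.05,
    seed: int = 0,
    bl_ref: float = 52.6,
) -> pd.DataFrame:
    """Maximal friction/adhesion forces (mN) as power laws of body length.

    ``strength_at_ref`` (mN) is the force at the reference body length
    ``bl_ref`` (mm).  The default 63 mN at 52.6 mm gives a static safety
    factor of about 14 at the mean male mass.
    """
    if len(morph) == 0:
        raise ValueError("morphometrics table is empty")
    if strength_at_ref <= 0:
        raise ValueError("strength_at_ref must be positive")
    if residual_sd_log10 < 0:
        raise ValueError("residual sd must be non-negative")
    rng = np.random.default_rng(seed)
    rel = morph["body_length_mm"].to_numpy(float) / bl_ref
    n = len(morph)
    friction = strength_at_ref * rel**slope_friction * 10 ** rng.normal(0, residual_sd_log10, n)
    adhesion = strength_at_ref * rel**slope_adhesion * 10 ** rng.normal(0, residual_sd_log10, n)
    return pd.DataFrame({
        "id": morph["id"].to_numpy(),
        "sex": morph["sex"].to_numpy(),
        "body_length_mm": morph["body_length_mm"].to_numpy(float),
        "mass_g": morph["mass_g"].to_numpy(float),
        "friction_mN": friction,
        "adhesion_mN": adhesion,
    })


def simulate_landing_trials(
    n_individuals: int = 16,
    trials_per_individual: int = 2,
    mean_mass_g: float = 0.43,
    sd_mass_g: float = 0.06,
    speed_intercept: float = 0.7,
    speed_slope: float = 2000.0,
    individual_sd: float = 0.03,
    trial_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trial (mass, landing speed) data with individual structure.

    Landing speed follows v = intercept + slope * m(kg) plus a per-individual
    random intercept (sd ``individual_sd`` m/s) and per-trial noise.  The
    defaults give ~1.56 m/s at the mean male mass with a positive
    mass-speed relationship, mirroring heavier males dropping faster.
    """
    rng = np.random.default_rng(seed)
    mass = rng.normal(mean_mass_g, sd_mass_g, n_individuals) / 1000.0  # kg
    mass = np.clip(mass, 1e-4, None)
    indiv = rng.normal(0.0, individual_sd, n_individuals)
    rows = []
    for i in range(n_individuals):
        for j in range(trials_per_individual):
            v = speed_intercept + speed_slope * mass[i] + indiv[i] + rng.normal(0, trial_sd)
            rows.append({"individual_id": f"M{i + 1:02d}", "trial": j + 1,
                         "mass_kg": mass[i], "landing_speed_m_s": max(v, 0.05)})
    return pd.DataFrame(rows)


def simulate_aero_forces(
    n_shapes: int = 5,
    scales: tuple[float, ...] = (0.85, 0.95, 1.0, 1.05, 1.15),
    bl_ref_mm: float = 53.0,
    ar_range: tuple[float, float] = (2.28, 9.47),
    rho: float = 1.20473,
    v: float = 1.57,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Synthetic stand-in for an external CFD force table.

    Emits one row per (shape, scale) body model with drag/lift forces built
    from assumed coefficient laws C_D = 1.35 + 0.02*AR and
    C_L = 1.07 - 0.02*AR (decreasing lift and increasing drag coefficient
    with body aspect ratio, coefficients in the ~1.4 / ~0.95 regime of a
    poorly streamlined body at high angle of attack).  This is synthetic
    plumbing so the coefficient post-processing is testable offline; it is
    not a fluid simulation.
    """
    rng = np.random.default_rng(seed)
    ars = np.linspace(ar_range[0], ar_range[1], n_shapes)
    rows = []
    q = 0.5 * rho * v**2
    for k, ar in enumerate(ars):
        for s in scales:
            bl = bl_ref_mm * s
            # frontal area of the tilted body; ~4 cm^2 for the reference male
            area = 4.0e-4 * s**2 * (5.6 / ar) ** 0.3
            cd = 1.35 + 0.02 * ar + rng.normal(0, noise_sd)
            cl = 1.07 - 0.02 * ar + rng.normal(0, noise_sd)
            rows.append({
                "model_id": f"S{k + 1}x{s:g}",
                "BL_mm": bl,
                "aspect_ratio": ar,
                "frontal_area_m2": area,
                "F_drag_N": cd * q * area,
                "F_lift_N": cl * q * area,
                "rho": rho,
                "v": v,
            })
    return pd.DataFrame(rows)
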