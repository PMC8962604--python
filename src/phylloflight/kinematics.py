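"""Per-trial flight kinematics from calibrated 2D landmark tracks.

Pipeline: body pitch (head-abdomen angle vs horizontal, Savitzky-Golay
smoothed, order 3 / window 71) -> phase marks t1 (minimum pitch, wing
opening) and t2 (pitch stabilization, first local minimum of pitch rate
after its large recovery peak) -> mean rotational velocity during righting
omega = (pitch(t2) - pitch(t1)) / (t2 - t1) -> COM trajectory (window 31)
with velocities/accelerations by central differences -> steady-state mean
velocities -> wingbeat frequency/stroke amplitude from wing-reversal
frames -> landing speed just before target contact.

Conventions: x along the flight direction, y up, angles in degrees
(positive pitch = nose up), time zero at the first frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import savgol_filter

from .track import TrajectoryTrack

__all__ = [
    "PitchProfile",
    "PhaseMarks",
    "ComSeries",
    "FlightSummary",
    "KinematicsConfig",
    "calibrate_scale",
    "verify_gravity",
    "compute_pitch",
    "segment_phases",
    "rotational_velocity",
    "com_trajectory",
    "steady_velocities",
    "wingbeat_stats",
    "landing_speed",
    "analyze_trial",
]


@dataclass
class PitchProfile:
    t: np.ndarray
    pitch_raw: np.ndarray     # deg; continuous (unwrapped), first sample in (-180, 180]
    pitch_smooth: np.ndarray  # deg
    pitch_rate: np.ndarray    # deg/s, central differences of pitch_smooth


@dataclass
class PhaseMarks:
    t1: float
    t2: float
    steady_onset_vx: float | None = None
    steady_onset_vy: float | None = None


@dataclass
class ComSeries:
    """Smoothed centre-of-mass trajectory with derivatives."""

    t: np.ndarray
    pos: np.ndarray  # (n, 2) m
    vel: np.ndarray  # (n, 2) m/s
    acc: np.ndarray  # (n, 2) m/s^2
    fps: float


@dataclass
class FlightSummary:
    omega: float
    mean_vx: float
    mean_vy: float
    wingbeat_freq: float
    stroke_amp: float
    landing_speed: float
    pitch_stable: float
    t1: float
    t2: float
    steady_onset_vx: float
    steady_onset_vy: float


@dataclass
class KinematicsConfig:
    """Per-trial analysis parameters (defaults = study settings)."""

    sg_window_pitch: int = 71
    sg_window_traj: int = 31
    sg_order: int = 3
    steady_window_s: float = 0.2
    steady_a_tol: float = 2.0   # m/s^2
    com_fraction: float = 0.5
    hinge_fraction: float = 0.5
    stab_frac: float = 0.07             # pitch-stabilization threshold (fraction of peak rate)
    contact_time: float | None = None   # default: last frame
    cutoff_time: float | None = None    # landing-approach cutoff for steady averaging


def _savgol(y: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smoothing; edge windows are polynomial-refit, not padded."""
    if window % 2 == 0:
        raise ValueError("Savitzky-Golay window must be odd")
    if window >= len(y):
        raise ValueError(f"window {window} must be shorter than the series ({len(y)})")
    if order >= window:
        raise ValueError("polynomial order must be below the window size")
    return savgol_filter(y, window, order, mode="interp")


def calibrate_scale(track_px: TrajectoryTrack, bar_len_px: float, bar_len_true: float) -> TrajectoryTrack:
    """Scale a pixel-coordinate track to metres using a scale bar.

    All coordinates are multiplied by ``bar_len_true / bar_len_px``.
    Calibrating an already-calibrated track is an error (no double scaling).
    """
    if bar_len_px <= 0 or bar_len_true <= 0:
        raise ValueError("scale-bar lengths must be positive")
    if track_px.units_calibrated:
        raise ValueError("track is already calibrated; refusing to scale twice")
    s = bar_len_true / bar_len_px
    out = track_px.copy()
    out.head = out.head * s
    if out.abd is not None:
        out.abd = out.abd * s
    if out.wing is not None:
        out.wing = out.wing * s
    out.units_calibrated = True
    out.meta["scale_m_per_px"] = s
    return out


def verify_gravity(ball: TrajectoryTrack, g_ref: float = 9.805, tol_frac: float = 0.01) -> tuple[float, bool]:
    """Measure gravitational acceleration from a ball-drop track.

    A least-squares quadratic is fitted to y(t); g = -2 * (quadratic
    coefficient).  Passes when |g - g_ref| / g_ref < tol_frac.
    """
    if ball.n_frames < 10:
        raise ValueError("need at least 10 frames for the gravity check")
    t = ball.t
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame times must be strictly increasing")
    coef = np.polyfit(t, ball.head[:, 1], 2)
    g_measured = -2.0 * coef[0]
    ok = abs(g_measured - g_ref) / g_ref < tol_frac
    return float(g_measured), bool(ok)


def compute_pitch(track: TrajectoryTrack, sg_window: int = 71, sg_order: int = 3) -> PitchProfile:
    """Body pitch: angle of the abdomen->head axis above horizontal, in degrees.

    Raw pitch is atan2(head_y - abd_y, head_x - abd_x), unwrapped to a
    continuous series (first sample in (-180, 180]); the smoothed series is
    a Savitzky-Golay fit and the rate its central-difference derivative.
    """
    if track.abd is None:
        raise ValueError("track has no abdomen landmark; pitch undefined")
    d = track.head - track.abd
    r = np.hypot(d[:, 0], d[:, 1])
    bad = np.flatnonzero(r == 0)
    if bad.size:
        raise ValueError(f"head and abdomen coincide at frame {bad[0]}")
    raw = np.degrees(np.unwrap(np.arctan2(d[:, 1], d[:, 0])))
    smooth = _savgol(raw, sg_window, sg_order)
    rate = np.gradient(smooth, track.t)
    return PitchProfile(t=track.t, pitch_raw=raw, pitch_smooth=smooth, pitch_rate=rate)


def segment_phases(pp: PitchProfile, stab_frac: float = 0.07, min_decay_frac: float = 0.5) -> PhaseMarks:
    """Locate t1 (wing opening) and t2 (pitch stabilization).

    t1 is the time of the global minimum of smoothed pitch (earliest on
    ties).  The recovery peak is the global maximum of pitch rate after
    t1.  t2 — the moment pitch stabilizes — is the earliest subsequent
    sample at which the rate either attains a local minimum (sample i with
    rate[i-1] > rate[i] <= rate[i+1], the strict decrease exceeding a tiny
    relative tolerance so floating-point jitter on plateaus does not
    register) or drops below ``stab_frac`` of the peak rate, i.e. the
    rotation has effectively ceased.  Two guards make the mark robust:
    the threshold branch keeps it tight to the stabilization point when
    the smoothed rate decays with a long shallow tail (where the first
    literal local minimum can sit well past the maneuver), and a local
    minimum only qualifies once the rate has decayed below
    ``min_decay_frac`` of the peak, so tracking-noise wiggles on the still
    -large descending rate are not mistaken for stabilization.  A trial
    whose pitch never recovers raises a "no recovery detected" error.
    """
    n = len(pp.t)
    i1 = int(np.argmin(pp.pitch_smooth))
    rate = pp.pitch_rate
    if i1 >= n - 2:
        raise ValueError("no recovery detected: pitch minimum at the end of the trial")
    ipeak = i1 + int(np.argmax(rate[i1:]))
    tol = 1e-9 * max(1.0, float(np.max(np.abs(rate))))
    thresh = stab_frac * rate[ipeak]
    decay = min_decay_frac * rate[ipeak]
    i2 = None
    for i in range(max(ipeak + 1, 1), n - 1):
        is_local_min = rate[i - 1] > rate[i] + tol and rate[i] <= rate[i + 1] + tol
        if rate[i] <= thresh or (is_local_min and rate[i] <= decay):
            i2 = i
            break
    if i2 is None:
        raise ValueError("no recovery detected: no local minimum of pitch rate after the peak")
    return PhaseMarks(t1=float(pp.t[i1]), t2=float(pp.t[i2]))


def rotational_velocity(pp: PitchProfile, marks: PhaseMarks) -> float:
    """Mean righting rotational velocity omega = Δpitch / Δt over [t1, t2], deg/s."""
    if marks.t2 <= marks.t1:
        raise ValueError("t2 must be after t1")
    p1 = float(np.interp(marks.t1, pp.t, pp.pitch_smooth))
    p2 = float(np.interp(marks.t2, pp.t, pp.pitch_smooth))
    return (p2 - p1) / (marks.t2 - marks.t1)


def com_trajectory(
    track: TrajectoryTrack,
    com_fraction: float = 0.5,
    sg_window: int = 31,
    sg_order: int = 3,
    normal_offset: float = 0.0,
) -> ComSeries:
    """Smoothed centre-of-mass trajectory with velocity and acceleration.

    COM(t) = head + com_fraction * (abd - head), optionally displaced by
    ``normal_offset`` metres perpendicular (left-normal) to the body axis.
    Positions are smoothed per axis; derivatives are successive central
    differences of the smoothed series.
    """
    if not 0.0 <= com_fraction <= 1.0:
        raise ValueError("com_fraction must lie in [0, 1]")
    if track.abd is None:
        raise ValueError("track has no abdomen landmark; COM undefined")
    pos = track.head + com_fraction * (track.abd - track.head)
    if normal_offset != 0.0:
        axis = track.head - track.abd
        axis = axis / np.hypot(axis[:, 0], axis[:, 1])[:, None]
        normal = np.column_stack([-axis[:, 1], axis[:, 0]])
        pos = pos + normal_offset * normal
    sm = np.column_stack([_savgol(pos[:, k], sg_window, sg_order) for k in range(2)])
    vel = np.column_stack([np.gradient(sm[:, k], track.t) for k in range(2)])
    acc = np.column_stack([np.gradient(vel[:, k], track.t) for k in range(2)])
    return ComSeries(t=track.t, pos=sm, vel=vel, acc=acc, fps=track.fps)


def steady_velocities(
    com: ComSeries,
    marks: PhaseMarks,
    window_s: float = 0.2,
    a_tol: float = 2.0,
    cutoff_time: float | None = None,
) -> tuple[float, float, PhaseMarks]:
    """Steady-state mean horizontal/vertical velocities.

    Per axis, the steady state begins at the earliest time tau >= t2 from
    which the magnitude of the centred sliding-window mean acceleration
    (window ``window_s`` seconds) stays below ``a_tol`` through the end of
    the usable series (``cutoff_time``, default last frame).  Averaging
    the signed acceleration before taking the magnitude operationalizes
    "acceleration oscillating around zero": tracking noise averages out
    while any sustained acceleration registers.  The criterion is
    evaluated only where the centred window is fully supported (the last
    half-window, where boundary refits inflate the acceleration noise, is
    excluded).  Mean velocities are taken from tau to the cutoff; onsets
    are recorded in the returned PhaseMarks.
    """
    t = com.t
    if marks.t2 >= t[-1]:
        raise ValueError("series does not extend beyond t2")
    iend = len(t) if cutoff_time is None else int(np.searchsorted(t, cutoff_time, side="right"))
    i2 = int(np.searchsorted(t, marks.t2, side="left"))
    if iend <= i2 + 1:
        raise ValueError("cutoff leaves no samples after t2")
    w = max(1, int(round(window_s * com.fps)))
    iend_crit = max(i2 + 2, iend - w // 2)
    onsets, means = [], []
    for k in range(2):
        amean = np.abs(uniform_filter1d(com.acc[:, k], size=w, mode="nearest"))
        quiet = amean[:iend_crit] < a_tol
        # earliest index >= i2 from which the criterion holds through the end
        bad = np.flatnonzero(~quiet[i2:iend_crit])
        i_on = i2 if bad.size == 0 else i2 + bad[-1] + 1
        if i_on >= iend_crit - 1:
            axis = "horizontal" if k == 0 else "vertical"
            raise ValueError(
                f"steady-state criterion never met for the {axis} axis; "
                "review steady_window_s / steady_a_tol or the cutoff"
            )
        onsets.append(float(t[i_on]))
        means.append(float(np.mean(com.vel[i_on:iend, k])))
    out = PhaseMarks(t1=marks.t1, t2=marks.t2, steady_onset_vx=onsets[0], steady_onset_vy=onsets[1])
    return means[0], means[1], out


def wingbeat_stats(
    track: TrajectoryTrack,
    reversal_frames: np.ndarray,
    wing_length: float | None = None,
    hinge_fraction: float = 0.5,
    after: float = 0.0,
) -> tuple[float, float]:
    """Wingbeat frequency (Hz) and mean stroke amplitude (deg).

    Only stroke reversals at t >= ``after`` (normally t2, once body pitch is
    stable) are used.  Frequency is full cycles divided by the elapsed time
    between the first and last used reversal (two reversals per cycle).
    The stroke amplitude of each half-stroke is the angle subtended at the
    wing hinge — located at ``hinge_fraction`` along the head->abdomen
    axis — by the wing-tip positions at consecutive reversals (law of
    cosines on the 2D coordinates); amplitudes are averaged across
    half-strokes.  ``wing_length`` is informational (nominal wing length);
    the measured hinge-to-tip distances are used.
    """
    if track.wing is None:
        raise ValueError("no wing track: wing-tip landmark absent")
    if track.abd is None:
        raise ValueError("track has no abdomen landmark; hinge undefined")
    rev = np.asarray(reversal_frames, dtype=int)
    rev = rev[(rev >= 0) & (rev < track.n_frames)]
    rev = rev[track.t[rev] >= after]
    if len(rev) < 3:
        raise ValueError("need at least 3 stroke reversals after the stable-pitch time")
    t_rev = track.t[rev]
    n_cycles = (len(rev) - 1) / 2.0
    freq = n_cycles / (t_rev[-1] - t_rev[0])

    hinge = track.head + hinge_fraction * (track.abd - track.head)
    amps = []
    for i, j in zip(rev[:-1], rev[1:]):
        # angle at the hinge between the two hinge->tip vectors (law of
        # cosines after translating both vectors to a common origin, so
        # body translation between reversals does not leak into the angle)
        u = track.wing[i] - hinge[i]
        v = track.wing[j] - hinge[j]
        cosang = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
        amps.append(np.degrees(np.arccos(cosang)))
    return float(freq), float(np.mean(amps))


def landing_speed(com: ComSeries, contact_time: float, steady_onset: float | None = None) -> float:
    """Instantaneous speed (m/s) at the last sample strictly before contact."""
    i = int(np.searchsorted(com.t, contact_time, side="left")) - 1
    if i < 0 or contact_time > com.t[-1] + 0.5 / com.fps:
        raise ValueError("contact_time outside the trial")
    if steady_onset is not None and contact_time < steady_onset:
        warnings.warn("contact before steady-state onset; landing speed may be transient",
                      stacklevel=2)
    return float(np.hypot(com.vel[i, 0], com.vel[i, 1]))


def analyze_trial(
    track: TrajectoryTrack,
    meta: dict | None = None,
    config: KinematicsConfig | None = None,
) -> FlightSummary:
    """Run the full per-trial pipeline and return a FlightSummary.

    Stages run in order (pitch -> phases -> omega -> COM -> steady
    velocities -> wingbeat -> landing speed); failures are re-raised with
    the stage name.  A trial without a wing track (or reversal annotations)
    yields NaN wingbeat fields, everything else filled.
    """
    if not track.units_calibrated:
        raise ValueError("track must be calibrated before analysis")
    cfg = config or KinematicsConfig()
    meta = meta or {}

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ValueError as e:
            raise ValueError(f"[{name}] {e}") from e

    pp = stage("pitch", compute_pitch, track, cfg.sg_window_pitch, cfg.sg_order)
    marks = stage("phases", segment_phases, pp, cfg.stab_frac)
    omega = stage("omega", rotational_velocity, pp, marks)
    com = stage("com", com_trajectory, track, cfg.com_fraction, cfg.sg_window_traj, cfg.sg_order)
    vx, vy, marks = stage("steady", steady_velocities, com, marks,
                          cfg.steady_window_s, cfg.steady_a_tol, cfg.cutoff_time)

    rev = meta.get("reversal_frames", track.meta.get("reversal_frames"))
    if track.wing is not None and rev is not None and len(np.atleast_1d(rev)) >= 3:
        try:
            freq, amp = wingbeat_stats(track, rev, hinge_fraction=cfg.hinge_fraction,
                                       after=marks.t2)
        except ValueError:
            freq, amp = float("nan"), float("nan")
    else:
        freq, amp = float("nan"), float("nan")

    contact = cfg.contact_time if cfg.contact_time is not None else float(track.t[-1])
    v_land = stage("landing", landing_speed, com, contact, marks.steady_onset_vy)

    after_t2 = pp.pitch_smooth[pp.t >= marks.t2]
    return FlightSummary(
        omega=float(omega),
        mean_vx=vx,
        mean_vy=vy,
        wingbeat_freq=freq,
        stroke_amp=amp,
        landing_speed=v_land,
        pitch_stable=float(np.mean(after_t2)),
        t1=marks.t1,
        t2=marks.t2,
        steady_onset_vx=marks.steady_onset_vx,
        steady_onset_vy=marks.steady_onset_vy,
    )
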