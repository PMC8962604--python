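# Methods

`phylloflight` implements the quantitative pipeline behind a comparative
study of locomotor costs in a strongly size-dimorphic leaf insect
(*Phyllium philippinicum*), in which small flying males search for large
sedentary females. The package covers four linked analyses — drop-recovery
flight kinematics from 2D videogrammetry landmarks, a cantilever-leaf
landing-impact model with attachment safety factors, allometric log-log
scaling with isometry tests and an induced-power scaling derivation, and
aerodynamic-coefficient post-processing — plus a synthetic-data generator
that makes every stage verifiable without any external data.

## Flight kinematics

A trial is a uniformly sampled (500 fps) 2D track of the head and terminal
abdominal segment, optionally the wing tip, filmed side-on with the flight
path parallel to the sensor plane. Pixel coordinates are converted to
metres with a scale bar (`calibrate_scale`), and the vertical axis is
validated against a filmed ball drop: a least-squares quadratic fit of
y(t) must recover the local gravitational acceleration (9.805 m/s²) to
within 1% (`verify_gravity`).

Body pitch is the angle of the abdomen→head axis above horizontal
(positive nose-up, continuous/unwrapped, degrees). It is smoothed with a
Savitzky–Golay filter (polynomial order 3, window 71 samples = 0.142 s at
500 fps); the pitch rate is the central-difference derivative of the
smoothed series. Boundary windows are polynomial-refit on the available
samples (`scipy.signal.savgol_filter(..., mode="interp")`) rather than
padded, so no data are fabricated at the drop and landing ends.

A dropped male free-falls nose-down, opens its wings at the pitch minimum
(t1), rotates nose-up at a roughly constant rate, and stabilizes its pitch
(t2). t1 is the time of the global minimum of smoothed pitch (earliest on
ties). t2 is found after the global maximum of pitch rate following t1:
the earliest sample at which the rate either reaches a local minimum or
falls below `stab_frac` (default 0.07) of the peak rate, whichever comes
first; local minima only qualify once the rate has decayed below half the
peak. Two numerical realities motivate the two guards. First, after
smoothing, the literal first local minimum of the rate can sit in the
filter's undershoot 15–25 frames past the true stabilization, or — under
tracking noise — in a wiggle on the still-large descending rate; both
displace t2 far from the event it marks. Second, the rate of a smooth
maneuver approaches zero with a long shallow tail, so "rotation
effectively ceased" is best expressed as a threshold. The 0.07 default
was calibrated once against the synthetic generator's ground truth so
that the detected mark coincides with the true stabilization time across
the realistic range of righting velocities (≈300–450 °/s); it is a
configuration parameter (`stab_frac`).

The torsional-agility statistic is the mean rotational velocity during
righting,

    omega = (pitch(t2) − pitch(t1)) / (t2 − t1),

evaluated on the smoothed pitch. With the default smoothing window the
recovered omega is accurate to ~3% on noise-free synthetic trials and ~10%
under 0.5 mm landmark noise; for maneuvers much faster than ~500 °/s the
righting interval approaches the smoothing window and omega is
systematically attenuated — a documented limitation of the fixed window,
not of the estimator.

The centre of mass is placed at a fixed fraction (`com_fraction`, default
0.5) along the head–abdomen axis, with an optional perpendicular offset
(default 0, as no off-axis balance point is available). COM positions are
smoothed per axis (order 3, window 31) and differentiated twice by central
differences. The steady state of each velocity component begins at the
earliest time ≥ t2 from which the magnitude of the 0.2 s sliding-window
mean acceleration stays below 2 m/s² (both configurable) through the end
of the usable series; the criterion is evaluated only where the centred
window is fully supported, because boundary refits inflate acceleration
noise in the last half-window. Averaging the signed acceleration before
taking its magnitude is what "acceleration oscillating around zero" means
operationally: zero-mean tracking noise cancels while sustained
acceleration registers. Mean steady velocities are then taken from the
onset to the landing-approach cutoff (default: last frame).

Wingbeat frequency uses only stroke reversals after t2: full cycles (two
reversals each) divided by the elapsed time between the first and last
reversal used. Stroke amplitude is, for each half-stroke, the angle at the
wing hinge (at `hinge_fraction` along the body axis) between the two
hinge→wing-tip vectors at consecutive reversals — the law of cosines
applied after translating both vectors to a common origin, so body
translation between reversals (several centimetres at 1.57 m/s and 25 Hz)
does not leak into the angle. Amplitudes are averaged across half-strokes.
Both quantities are 2D projections; out-of-plane stroke components bias
the amplitude downward and are not corrected (trials deviate < 10° from
the filming plane). Landing speed is the smoothed speed at the last sample
strictly before target contact.

## Landing-impact model

The landing platform (leaf + petiole) is a uniform, initially horizontal
cantilever beam, point-loaded at the tip by the insect. Under the
small-deflection (linear) beam theory used throughout,

    delta = m g L^3 / (3 EI),

with tip slope angle atan(m g L² / (2 EI)) = atan(3 delta / 2L); rows with
tip angles ≥ 5° are flagged invalid rather than dropped. Two built-in leaf
presets span compliant-small to stiff-large platforms: L = 0.23 m with
EI = 2.67×10⁻³ N m², and L = 0.86 m with EI = 28.48×10⁻³ N m². The
landing load follows from the work–energy principle,

    F_i = m g + m v² / (2 delta),

i.e. the weight plus the kinetic energy dissipated over the leaf's
deflection. Leg-joint compliance and beam vibration are deliberately
ignored, so F_i is an upper-bound estimate; a rigid substrate (delta = 0)
with nonzero landing speed is a singularity and an error. g = 9.81 m/s²
in this module (9.805 in the calibration context); both are arguments.

Safety factors: SF_static = attachment force / body weight; SF_dynamic =
friction force / F_i, friction being the force component that
accommodates landing deceleration. The weight enters the denominator once
— F_i already contains m g. Describing the load as "impact + weight" is
read as labelling the two terms of F_i; a `double_count_weight` flag
exposes the alternative reading (adding m g again) for sensitivity
analysis. SF < 1 predicts slippage.

Landing speed is predicted from body mass by a linear model fitted on
repeated trials per individual. Repeated measures are collapsed to
per-individual means before ordinary least squares; the downstream
contract is only the (intercept, slope) pair, so this two-stage fit
replaces a random-intercept mixed model without changing what the
predictions consume. `landing_sweep` crosses individuals with leaf
presets, using each individual's measured friction force (per-individual
means); a fitted force–mass curve could substitute for out-of-sample
masses but is not the default.

## Allometry and power scaling

Scaling fits regress log10(trait) on log10(body length) per sex by OLS,
with slope standard errors and 95% CIs from the per-group fits and a
sequential (type-I) ANOVA for predictor, sex, and their interaction — in
that order, which the implementation guarantees by building the interaction
design with numeric dummies. Isometry (geometric similarity) predicts
slopes of 1, 2, 3 for lengths, areas, masses; verdicts compare the closed
95% CI with the expectation (an endpoint exactly on the expected slope
counts as consistent). Sex differences in single traits use two-sided
Wilcoxon–Mann–Whitney tests, exact for modest tie-free samples.

Wing loading is body weight over total wing area (N/m²). Wing disc
loading divides weight by the area swept by the beating wings,

    DL = W_B / (2 pi L_w^2 theta / 360),

with wing length L_w (m) and stroke amplitude theta (degrees). Momentum-
jet theory for slow flight makes the induced power — the dominant term of
power required — proportional to W_B √DL. Under isometry W_B ∝ BL³ and
DL ∝ BL, so β_Pr = 3.5; the power available is muscle work (∝ BL³) times
flapping frequency (∝ BL⁻¹), so β_Pa = 2. An empirical disc-loading
exponent maps through the exact affine transform β_Pr = 3 + β_DL/2, and
CI endpoints map through the same transform (exact for an affine map; no
resampling). The power margin ΔP = P_a − P_r declines faster than
isometry predicts whenever β_Pr exceeds both 3.5 and β_Pa. The
disc-loading exponent itself is estimated by OLS on per-individual means
(log10 DL vs log10 BL), an approximation to a random-intercept fit that
the repeated-measures structure would otherwise call for.

## Aerodynamic coefficients

External CFD force tables are post-processed into C_D = 2F_drag/(ρv²A)
and C_L = 2F_lift/(ρv²A) using the projected frontal area A, plus forces
relative to body weight. The solver itself is out of scope; the package
consumes its force table. Air density defaults to 1.20473 kg/m³ for
coefficient work, with 1.07 kg/m³ available as the high-elevation preset
for power calculations; viscosity defaults to 1.82×10⁻⁵ Pa s (20 °C).
Reynolds numbers use body length as the characteristic length by default
(configurable — the original choice is not documented).

Model weights come from a *linear* regression of male body mass on body
length (not log-log), shape-corrected for artificially widened or shrunk
abdominal lobes at 89.7 g/m² of lobe area; predictions outside the fitted
length range warn about extrapolation.

The Morrison single-formula sphere-drag correlation is provided for
simulation sanity checks, implemented in an overflow-safe algebraic form
(term three as 0.411/(x^7.94 + x^-0.06)) and verified against the Stokes
law (within 1% below Re = 0.1) and an independent literal transcription.
Direct evaluation at Re = 5558 gives C_D ≈ 0.399, near the classical
experimental drag curve at that Reynolds number. A published comparison
at this Re pairs a simulated 0.643 with a correlation value of 0.652;
that 0.652 is not reproduced by direct evaluation of the correlation as
printed (a different formula variant or reference convention may be
involved), so the implementation exposes the correlation transparently
and documents the computed value rather than forcing agreement. No test
asserts the published pair.

## Synthetic data: what it emulates, and what it does not

The generator produces four kinds of ground-truthed inputs.

**Drop-recovery trials** are kinematic constructions, not aerodynamic
simulations: the COM falls ballistically (9.805 m/s²), blends linearly in
velocity over the righting interval to a constant steady velocity, and
the pitch profile is a C² piecewise polynomial — a cubic easing into the
free-fall minimum, a quintic smoothstep rising to the stable pitch, then
a constant. The smoothstep's *average* rate over the righting interval is
exactly `omega_true`, which is precisely the quantity the rotational-
velocity statistic measures, and the ground truth preserves
t2 − t1 = Δpitch/omega. A piecewise-linear ramp was rejected: its corner
discontinuities are angular-acceleration impulses no real maneuver
contains, and they interact with the 71-sample smoother to bias the
omega chord by 10–25%, which would test the filter's corner response
rather than the estimator. Head and abdomen sit at ±body_length/2 along
the pitch direction; the wing tip oscillates sinusoidally about the hinge
after t2, with reversal frames emitted as annotations so frequency and
amplitude recovery can be tested without a peak detector. Isotropic
Gaussian noise (default test condition 0.5 mm) models digitization error;
it is white, whereas real tracking error is autocorrelated and can
contain outliers — recovery under the synthetic noise therefore bounds
digitization jitter, not gross mistracking.

**Ball drops** are noisy parabolas for the gravity check.

**Morphometrics** are log-normal body lengths per sex (male mean 52.6 mm,
CV 0.025; female mean 80 mm — a realistic value for large leaf-mimicking
females, chosen once since no female length was available) with traits
generated as power laws of body length plus log-normal residuals
(default 0.02 dex). Mean masses are 0.46 g (males) and 5.22 g (females),
the ~11-fold dimorphism of the study population; default exponents are
isometric (3 for mass, 2 for areas). Flight muscle mass is zero for the
flightless females.

**Attachment forces** are power laws of body length (default exponent 2
for friction and adhesion) scaled to 63 mN at the reference male length,
which yields a static safety factor near 14 at the mean male mass — the
">14" regime. One strength scale serves both force directions and both
sexes; the sex-specific intercept differences present in real
measurements are not emulated.

A small synthetic CFD force table (5 aspect ratios × 5 scales, labelled
synthetic) uses assumed coefficient laws C_D = 1.35 + 0.02·AR and
C_L = 1.07 − 0.02·AR so the aero post-processing runs offline; it encodes
the direction and magnitude of realistic shape effects, nothing more.

Passing recovery tests on these constructions shows the estimators are
correct for data that satisfy the pipeline's assumptions (planar motion,
uniform sampling, white noise, a single clean righting maneuver). They do
not validate performance on trials with multiple aborted maneuvers,
occlusions, or out-of-plane flight.

## Pipeline defaults

The end-to-end run simulates 16 flight individuals × 2 trials (the study's
trial structure), 20 + 20 individuals for morphometrics and attachment,
and couples morphology to trial parameters with effect sizes emulating the
reported directions: righting velocity −2400 °/s per gram, sink rate
−10.6 m/s per gram, wingbeat frequency +14.6 Hz per gram, and stroke
amplitude ∝ BL^−3.96. The amplitude exponent makes disc loading rise
disproportionately with size (β_DL ≈ 5, the disproportionate increase the
stroke-amplitude decline produces in the study system), so the cohort-
level power chain lands near β_Pr ≈ 5.5 by construction of the same
mechanism. Problem sizes throughout (600-frame trials, 50-replicate noise
studies, 500-replicate coverage checks) were chosen so the whole suite
runs in well under a minute of simulation time while keeping Monte-Carlo
error far below the tolerances being asserted.

Configuration is a single YAML file mapped onto `RunConfig`; unknown keys
are errors, so typos cannot silently revert a parameter to its default.
All angles are serialized in degrees and lengths in SI units with
unit-suffixed column names; every report number traces to a named
intermediate CSV.

## Known limitations

- omega is attenuated when the righting interval is shorter than the
  smoothing window (fast maneuvers at ≳500 °/s with the default 71-sample
  window); the window is configurable but fixed by convention.
- The t1 mark sits a few frames early on asymmetric pitch valleys; the
  effect on omega is ≲3% at default settings and is included in the
  documented tolerances.
- Stroke amplitude is a planar projection; no out-of-plane correction.
- The disc-loading exponent uses per-individual means, not a mixed model;
  with two trials per individual the difference is negligible, but the CI
  is approximate.
- Small-deflection beam theory overestimates deflection beyond ~5° tip
  slope; such rows are flagged, not corrected.
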