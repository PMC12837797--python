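# Methods

This note documents the model, the numerical choices, and what the
synthetic validation does and does not demonstrate.

## The model and its assumptions

The pipeline estimates axial compressive load at L4/L5 from six surface-EMG
channels (bilateral erector spinae, rectus abdominis, external oblique). It
rests on the following assumptions:

- **Agonist-only moment balance.** During calibration the whole measured
  extension moment is attributed to the ES pair and the whole flexion
  moment to the RA/EO pairs; antagonist co-activation is not modeled. Any
  co-activation present in real recordings inflates the calibrated gains
  and, downstream, the estimated load.
- **Bilateral symmetry.** Calibration motion is sagittal, so left and right
  muscles of a pair carry equal force (each side gets half the group force
  and is paired with its own side's envelope).
- **Equal-stress flexor split.** The flexion moment is divided between RA
  and EO in proportion to their cross-sectional areas
  (F_EO = r·F_RA, r = CSA_EO/CSA_RA).
- **Static vertical balance.** The joint load is
  F_J = 0.67·BW·cos θ_UBW + Σ F_M·sin θ_M per sample; segment inertial
  terms, shear, moments and intra-abdominal pressure are out of scope. The
  0.67·BW upper-body weight fraction is a fixed model constant.
- **One inclination angle per muscle.** The same angle θ_M supplies the
  cos θ_M of the sagittal moment balance and the sin θ_M of the vertical
  balance. The two balances arguably probe different projections of the
  line of action; the construction (arcsin(d_M/d_L) for ES and RA, 45°
  fixed for EO) is isolated in `anthropometrics.muscle_angles` so an
  alternative reading can be swapped in, and a `ra_angle_fixed_45` switch
  pins the RA at 45° (the text supports both readings for the RA).

### Units of the corrected dynamometer reading

The printed moment balances multiply the corrected dynamometer reading
M_B* by the lever-arm length d_L. For the products to be moments, M_B* is
carried as the equivalent resistive *force* at the lever pad (N); torque
input in N·m is divided by d_L once, on ingest
(`extract_calibration_samples`). This is a pure units convention with no
effect on the solved forces.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| RMS window | 51 | samples | standard envelope width for trunk sEMG; edges truncate the window rather than padding (no phantom data) |
| phase deadband | ±2 | deg/s | lever-velocity band around direction reversals excluded from calibration |
| task relationships | 60 deg/s; ES linear, RA/EO logarithmic | — | contraction speed closest to the lifting task; forms with the lowest observed percent error |
| lift threshold / hysteresis | 2 / 1 | cm | ball must rise 2 cm above the floor band to open a cycle and fall back within 1 cm to close it |
| floor estimate | 5th percentile | — | robust resting-height estimate of the ball channel |
| upper-body weight fraction | 0.67 | — | fixed anthropometric constant of the vertical balance |
| percent-task grid | 101 points | — | 0–100 % of a lift cycle for cross-model curve comparison |

Percent error is defined as 100 · mean |F_pred − F_obs| / max(F_obs) over a
sample set. Normalizing by the maximum (not by each sample's own force)
keeps the measure finite near zero force and scale-invariant; the
denominator choice is a definition, not an estimate, and lives in one
function (`calibration.percent_error`).

The anthropometric coefficient table (torso depth/width → CSA and moment
arm per muscle group) ships with editable placeholder values in
physiological ranges (ES CSA ≈ 20 cm², ES arm ≈ 5.5 cm, RA arm ≈ 9 cm for
a 0.22 × 0.30 m torso). Every validation result is defined *relative to the
table* — the generator and the pipeline share it — so substituting
literature regression coefficients changes absolute outputs but not the
correctness of the inversion.

## Fitting, including the measurement-error mode

Relationships are fitted by ordinary least squares of force on the envelope
(or its logarithm), matching how force–sEMG scatter is usually trended.
OLS assumes the scatter sits on the force axis; when the envelope itself is
the noisy axis (as in the synthetic data, where forces are exact), OLS
slopes are attenuation-biased. `fit_relationship(..., envelope_noise_sd=σ)`
therefore offers a measurement-error mode, with σ estimable from the rest
trial (`RestBaseline.noise_sd`):

- **linear**: inverse regression — envelope on force, then inverted. With
  noise confined to the envelope this is the textbook-consistent direction.
- **logarithmic**: regression of the second-order bias-corrected
  log-envelope ln s + σ²/(2s²) on force, inverted, restricted to the upper
  90 % of the force range. The restriction must select on the *noise-free*
  axis: a floor on the noisy envelope would correlate the selection with
  the noise and re-introduce bias (observed as a ~7 % slope bias before
  this choice was made).

General relationships are fitted on axes normalized per subject by maximum
force and maximum envelope, pooled, and rescaled by the target subject's
own maxima at prediction time. Subjects with a zero maximum are excluded
with a warning. Maxima are taken per subject across all VCTs at one speed.

Degenerate inputs fail loudly: fewer than 3 samples, zero envelope
variance, non-positive envelopes under a log fit, all-zero observed forces
in the percent-error denominator, cos θ_ES = 0 (within 1e-12) in a solver
denominator. Negative solved forces and negative predictions clamp to
zero. Form selection ties break toward the linear (simpler) form.

## The synthetic generator

The generator emulates the study conditions: 5 s supine rest; three-cycle
triangle-wave VCTs over 90° at 30 and 60 deg/s with effort levels
1.0/0.7/0.4 across the three trials per speed; and ~30 s SLSS bouts (three
lifts by default: 2 s stoop segments, 2 s upright holds, 8 kg ball) with a
raised-cosine torso-angle profile. BMI is drawn N(25.2, 0.8) (clipped to
18–30) and height N(1.78, 0.06) m; torso dimensions scale with height.

Ground truth per subject: geometry from the shared coefficient table with
lever arm 0.3·height; maximum group forces 3000 N (ES) and 1100 N (RA)
scaled by mass/75 kg, EO = r·RA; per-channel relationships with a
log-uniform envelope gain (spread 3×) and an activation threshold
s0 ~ U(0.15, 0.35) envelope units. Gain heterogeneity alone is *removed*
by max-normalization (two subjects differing only in gain produce an exact
pooled fit), so the threshold spread is what gives subject-specific
relationships their measurable advantage over general ones. The lower
bound s0 ≥ 0.15 also keeps envelope noise clipping at zero negligible at
the noise levels exercised. The torso-weight torque artifact is a smooth
cubic in lever angle (deliberately not W·sinθ) emitted as a dense 0.02°
relaxed sweep, so the piecewise-linear calibration curve reproduces it far
below the 1e-6 round-trip tolerance.

EMG is synthesized at the envelope level — the inverse ground-truth mapping
of the prescribed per-side force, plus optional white noise (default SD
0.02 envelope units). With zero effort a channel's envelope sits at its
threshold s0, which maps to exactly zero force.

**What passing tests show, and what they do not.** Noise-free recovery to
machine precision demonstrates that the implementation inverts its own
forward model exactly — calibration, geometry, gravity correction and the
load balance are mutually consistent. It does not validate the model
against real tissue: raw-EMG spectral content, movement artifact,
co-activation, electrode placement and day-to-day variability are all
outside the generator, so real-data percent errors will be far larger than
the synthetic ones (single-digit %), and the synthetic specific-vs-general
gap is a direction check, not an effect-size prediction.

Prescribed SLSS effort yields peak loads of roughly 1.2–1.3× body weight.
This is at the low end of published lifting loads, a direct consequence of
the shallow line-of-action angles produced by arcsin(d_M/d_L) (sin θ_ES ≈
0.1): the vertical balance transmits only a small fraction of muscle force
into the joint term. Larger moment-arm tables or steeper angle conventions
raise it; the package reports whatever the configured geometry implies.

## Problem sizes and reproducibility

Defaults sample EMG at 2000 Hz and kinematics at 100 Hz. The replicated
statistical validations (noisy coefficient recovery over 100 replicates,
the 20-subject × 100-seed specificity comparison) run at reduced envelope
rates (250 and 100 Hz): sampling rate is resolution, not a study condition,
and the statistics of interest are governed by noise SD, heterogeneity and
subject counts, which stay at their stated values. All randomness flows
from `numpy.random.default_rng` seeded per (config seed, stream, subject,
trial), so identical configurations are byte-identical; the acceptance
script derives everything from its `--seed`.

## Known limitations

- No antagonist co-activation, EMG-to-activation dynamics, or
  force–length/velocity scaling.
- Six muscles only; moments must be fully absorbed by them, so individual
  activation strategies bias absolute loads (not relationship shapes).
- The percent-error definition and the impulse units are package
  conventions (impulse is reported both raw in N·s and BW-normalized in s,
  since "normalized impulse" is dimensionally seconds).
- Marker processing is minimal: torso angle from the sacrum→sternum vector
  and ball height from a single marker; full marker-set kinematics are out
  of scope.
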