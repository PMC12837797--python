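"""Force-to-sEMG calibration from isokinetic voluntary-contraction trials (VCTs).

A VCT records the lever-arm angle and resistance moment of an isokinetic
dynamometer together with the six trunk sEMG envelopes while the subject
performs three concentric flexion/extension cycles at a fixed angular speed
(30 or 60 deg/s). Calibration proceeds in five steps:

1. *Gravity correction* — a relaxed sweep gives a calibration curve of rest
   torque versus lever angle (the torso-weight artifact); subtracting it
   from the recorded torque leaves the muscle-generated moment.
2. *Moment balance* — during extension the corrected moment is attributed
   entirely to the erector spinae; during flexion it is split between the
   rectus abdominis and external oblique in proportion to their
   cross-sectional areas (equal muscle stress).
3. *Pairing* — solved muscle forces are paired sample-by-sample with the
   concurrent envelope of the corresponding channel, extension samples
   feeding the ES channels and flexion samples the RA/EO channels.
4. *Fitting* — a linear (F = a + b*s) or logarithmic (F = a + b*ln s)
   relationship is fitted per muscle by least squares, either
   subject-*specific* or *general* (pooled across subjects on axes
   normalized by each subject's maximum force and envelope).
5. *Scoring* — candidate forms are compared by percent error and the lowest
   is selected.

Units: the gravity-corrected dynamometer reading M_B* is carried as the
equivalent resistive force at the lever-arm pad (N), so M_B* * d_L is the
external moment in N*m; torque input in N*m is divided by the lever arm
length on ingest.  Sign convention: extension-positive torque.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import (
    ConfigurationError,
    FitError,
    GeometryError,
    InputError,
    ParameterError,
)
from .anthropometrics import (
    CHANNELS,
    EO_ANGLE_DEG,
    GROUP_OF,
    MuscleGeometry,
    Subject,
    csa_ratio,
    estimate_muscle_geometry,
    muscle_angles,
)
from .emg import RestBaseline

FLEXION = 1
EXTENSION = -1
NO_PHASE = 0

PHASE_DEADBAND_DPS = 2.0  # deg/s; samples slower than this are unlabelled

LINEAR = "linear"
LOGARITHMIC = "logarithmic"
FORMS = (LINEAR, LOGARITHMIC)

#: relationship form used for each muscle group when estimating task loads
DEFAULT_TASK_FORMS = {"ES": LINEAR, "RA": LOGARITHMIC, "EO": LOGARITHMIC}

#: VCT speed whose relationships drive task-load estimation
DEFAULT_TASK_SPEED = 60.0


@dataclass
class VctTrial:
    """One voluntary-contraction trial on a common timebase.

    ``torque_nm`` is the raw dynamometer moment (N*m, extension positive);
    ``envelopes`` maps each channel label to an envelope array of the same
    length as ``time``. ``rest_sweep`` optionally carries a relaxed
    (angle, torque) sweep for gravity calibration.
    """

    time: np.ndarray
    lever_angle_deg: np.ndarray
    torque_nm: np.ndarray
    envelopes: dict[str, np.ndarray]
    speed: float
    lever_arm_length: float
    rest_sweep: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.lever_angle_deg = np.asarray(self.lever_angle_deg, dtype=float)
        self.torque_nm = np.asarray(self.torque_nm, dtype=float)
        n = self.time.size
        if self.lever_angle_deg.size != n or self.torque_nm.size != n:
            raise InputError("angle, torque and time must share a common timebase")
        for channel, env in self.envelopes.items():
            env = np.asarray(env, dtype=float)
            if env.size != n:
                raise InputError(f"envelope {channel!r} not aligned with the trial timebase")
            self.envelopes[channel] = env
        if self.lever_arm_length <= 0:
            raise GeometryError("lever_arm_length must be positive")


@dataclass
class CalibrationCurve:
    """Piecewise-linear rest torque vs. lever angle (gravity artifact).

    Queries outside the measured angle range clamp to the endpoint values.
    """

    angles_deg: np.ndarray
    torques_nm: np.ndarray

    def __call__(self, angle_deg) -> np.ndarray:
        return np.interp(angle_deg, self.angles_deg, self.torques_nm)


def fit_gravity_calibration(angles_deg, torques_nm) -> CalibrationCurve:
    """Build the gravity calibration curve from a relaxed sweep.

    Duplicate angles are averaged; at least two distinct angles are needed.
    """
    angles = np.asarray(angles_deg, dtype=float).ravel()
    torques = np.asarray(torques_nm, dtype=float).ravel()
    if angles.size != torques.size:
        raise InputError("angle and torque sweeps differ in length")
    uniq, inverse = np.unique(angles, return_inverse=True)
    if uniq.size < 2:
        raise InputError("gravity calibration needs at least 2 distinct angles")
    sums = np.zeros(uniq.size)
    counts = np.zeros(uniq.size)
    np.add.at(sums, inverse, torques)
    np.add.at(counts, inverse, 1.0)
    return CalibrationCurve(angles_deg=uniq, torques_nm=sums / counts)


def correct_moment(raw_torque_nm, angle_deg, curve: CalibrationCurve) -> np.ndarray:
    """Torso-weight-corrected moment: raw torque minus the rest curve at that angle."""
    return np.asarray(raw_torque_nm, dtype=float) - curve(angle_deg)


def label_phases(
    lever_angle_deg, sampling_rate: float, deadband_dps: float = PHASE_DEADBAND_DPS
):
    """Label each sample flexion (+1), extension (-1) or neither (0).

    Phase is the sign of the lever angular velocity (increasing angle =
    flexion); samples inside the +/- deadband (direction reversals) are
    left unlabelled and excluded from calibration.
    """
    angle = np.asarray(lever_angle_deg, dtype=float)
    if angle.size < 2:
        return np.zeros(angle.size, dtype=int)
    velocity = np.gradient(angle) * sampling_rate
    phases = np.zeros(angle.size, dtype=int)
    phases[velocity > deadband_dps] = FLEXION
    phases[velocity < -deadband_dps] = EXTENSION
    return phases


def solve_extension_force(mbstar, lever_arm_length: float, geometry_es: MuscleGeometry):
    """Total (bilateral) erector spinae force from the extension moment balance.

    M_B* * d_L = F_ES * d_ES * cos(theta_ES); negative solutions clamp to 0.
    Accepts scalars or arrays; per-side force is half the returned total.
    """
    denom = geometry_es.moment_arm * math.cos(math.radians(geometry_es.inclination_deg))
    if denom <= 1e-12:  # cos(theta) = 0 at 90 deg up to round-off
        raise GeometryError("degenerate ES geometry: d_ES * cos(theta_ES) must be positive")
    force = np.asarray(mbstar, dtype=float) * lever_arm_length / denom
    return np.clip(force, 0.0, None)


def solve_flexion_forces(
    mbstar,
    lever_arm_length: float,
    geometry_ra: MuscleGeometry,
    geometry_eo: MuscleGeometry,
    csa_ratio_eo_ra: float,
):
    """Total RA and EO forces from the flexion moment balance.

    M_B* * d_L = F_RA * d_RA * cos(theta_RA) + F_EO * d_EO * cos(45 deg),
    closed with the equal-stress split F_EO = r * F_RA where r is the
    EO/RA cross-sectional-area ratio. Returns (F_RA, F_EO) totals, clamped
    at zero; per-side forces are half.
    """
    if csa_ratio_eo_ra < 0:
        raise ParameterError(f"CSA ratio must be non-negative, got {csa_ratio_eo_ra}")
    denom = geometry_ra.moment_arm * math.cos(
        math.radians(geometry_ra.inclination_deg)
    ) + csa_ratio_eo_ra * geometry_eo.moment_arm * math.cos(math.radians(EO_ANGLE_DEG))
    if denom <= 1e-12:
        raise GeometryError("degenerate flexion geometry: moment-arm denominator must be positive")
    f_ra = np.clip(np.asarray(mbstar, dtype=float) * lever_arm_length / denom, 0.0, None)
    return f_ra, csa_ratio_eo_ra * f_ra


@dataclass
class ForceEmgSamples:
    """Per-muscle (force, envelope) calibration pairs from one or more VCTs."""

    muscle: str
    force: np.ndarray
    envelope: np.ndarray
    speed: float

    def __post_init__(self) -> None:
        self.force = np.asarray(self.force, dtype=float)
        self.envelope = np.asarray(self.envelope, dtype=float)
        if self.force.size != self.envelope.size:
            raise InputError("force and envelope sample arrays differ in length")

    @property
    def n(self) -> int:
        return self.force.size

    @staticmethod
    def merge(sets: Sequence["ForceEmgSamples"]) -> "ForceEmgSamples":
        first = sets[0]
        return ForceEmgSamples(
            muscle=first.muscle,
            force=np.concatenate([s.force for s in sets]),
            envelope=np.concatenate([s.envelope for s in sets]),
            speed=first.speed,
        )


def pair_force_emg(
    forces: Mapping[str, np.ndarray],
    envelopes: Mapping[str, np.ndarray],
    phases: np.ndarray,
    speed: float,
    rest_masks: Mapping[str, np.ndarray] | None = None,
) -> dict[str, ForceEmgSamples]:
    """Pair per-side muscle force series with concurrent envelopes.

    Extension-phase samples feed the ES channels, flexion-phase samples the
    RA and EO channels; unlabelled samples and samples under a channel's
    rest mask are excluded.
    """
    out: dict[str, ForceEmgSamples] = {}
    for channel, force in forces.items():
        env = np.asarray(envelopes[channel], dtype=float)
        force = np.asarray(force, dtype=float)
        if force.size != env.size or force.size != phases.size:
            raise InputError(f"{channel}: force/envelope/phase series not on a common timebase")
        phase = EXTENSION if GROUP_OF[channel] == "ES" else FLEXION
        keep = phases == phase
        if rest_masks is not None and channel in rest_masks:
            keep &= ~np.asarray(rest_masks[channel], dtype=bool)
        out[channel] = ForceEmgSamples(
            muscle=channel, force=force[keep], envelope=env[keep], speed=speed
        )
    return out


def extract_calibration_samples(
    trial: VctTrial,
    geometry: Mapping[str, MuscleGeometry],
    curve: CalibrationCurve,
    rest_baselines: Mapping[str, RestBaseline] | None = None,
    deadband_dps: float = PHASE_DEADBAND_DPS,
) -> dict[str, ForceEmgSamples]:
    """Run steps 1-3 (gravity correction, moment balances, pairing) on one VCT."""
    rate = 1.0 / float(np.median(np.diff(trial.time)))
    tau_corr = correct_moment(trial.torque_nm, trial.lever_angle_deg, curve)
    mbstar = tau_corr / trial.lever_arm_length  # resistive force at the pad, N
    phases = label_phases(trial.lever_angle_deg, rate, deadband_dps)

    f_es = solve_extension_force(mbstar, trial.lever_arm_length, geometry["RES"])
    # flexion torque is extension-negative; flip sign before solving
    f_ra, f_eo = solve_flexion_forces(
        -mbstar, trial.lever_arm_length, geometry["RRA"], geometry["REO"], csa_ratio(geometry)
    )
    per_side = {"ES": f_es / 2.0, "RA": f_ra / 2.0, "EO": f_eo / 2.0}
    forces = {ch: per_side[GROUP_OF[ch]] for ch in trial.envelopes}

    rest_masks = None
    if rest_baselines is not None:
        rest_masks = {
            ch: trial.envelopes[ch] < rest_baselines[ch].rest_envelope_level
            for ch in trial.envelopes
            if ch in rest_baselines
        }
    return pair_force_emg(forces, trial.envelopes, phases, trial.speed, rest_masks)


@dataclass
class ForceEmgRelationship:
    """Fitted mapping from envelope to muscle force.

    ``specificity`` is 'specific' (one subject, raw axes) or 'general'
    (pooled across subjects on axes normalized to [0, 1] by each subject's
    maximum force and envelope; prediction for a new subject rescales by
    that subject's own maxima). Predictions are clamped at zero.
    """

    muscle: str
    form: str
    specificity: str
    speed: float
    a: float
    b: float
    max_force: float | None = None
    max_envelope: float | None = None
    rss: float = float("nan")
    n: int = 0
    se_a: float | None = None
    se_b: float | None = None

    def _raw_predict(self, s: np.ndarray) -> np.ndarray:
        if self.form == LINEAR:
            return self.a + self.b * s
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(s > 0, self.a + self.b * np.log(np.where(s > 0, s, 1.0)), 0.0)
        return out

    def predict(
        self,
        envelope,
        max_force: float | None = None,
        max_envelope: float | None = None,
    ) -> np.ndarray:
        """Predicted muscle force (N), clamped at zero.

        For a general relationship the target subject's ``max_force`` and
        ``max_envelope`` must be supplied (or stored on the instance).
        """
        s = np.asarray(envelope, dtype=float)
        if self.specificity == "general":
            max_force = max_force if max_force is not None else self.max_force
            max_envelope = max_envelope if max_envelope is not None else self.max_envelope
            if not max_force or not max_envelope:
                raise ConfigurationError(
                    f"{self.muscle}: general relationship needs the subject's "
                    "max_force and max_envelope for rescaling"
                )
            return np.clip(self._raw_predict(s / max_envelope), 0.0, None) * max_force
        return np.clip(self._raw_predict(s), 0.0, None)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Simple OLS of y on x; returns (intercept, slope, se_intercept, se_slope)."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = np.sum((x - xbar) ** 2)
    if sxx <= 0:
        raise FitError("zero variance in the regressor")
    slope = float(np.sum((x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - (intercept + slope * x)
    sigma2 = float(np.sum(resid**2) / max(n - 2, 1))
    se_slope = math.sqrt(sigma2 / sxx)
    se_intercept = math.sqrt(sigma2 * (1.0 / n + xbar**2 / sxx))
    return intercept, slope, se_intercept, se_slope


def fit_relationship(
    samples: ForceEmgSamples,
    form: str,
    specificity: str = "specific",
    envelope_noise_sd: float | None = None,
    min_envelope: float | None = None,
) -> ForceEmgRelationship:
    """Least-squares fit of a linear or logarithmic force-to-sEMG relationship.

    Default is ordinary least squares of force on the envelope (or its
    logarithm). When ``envelope_noise_sd`` is given (e.g. estimated from the
    rest trial), the fit instead accounts for envelope measurement noise:
    the linear form is fitted by inverse regression (envelope on force, then
    inverted), which is consistent when the noise sits on the envelope axis;
    the logarithmic form regresses the second-order bias-corrected
    log-envelope ln(s) + sigma^2/(2 s^2) on force and inverts, restricted to
    the upper 90% of the force range (selecting on the noise-free axis keeps
    the restriction from correlating with the envelope noise). Standard
    errors are reported for the plain OLS route only.
    """
    if form not in FORMS:
        raise ConfigurationError(f"unknown relationship form {form!r}")
    s = samples.envelope
    f = samples.force
    finite = np.isfinite(s) & np.isfinite(f)
    s, f = s[finite], f[finite]
    if min_envelope:
        keep = s >= min_envelope
        s, f = s[keep], f[keep]
    if envelope_noise_sd and form == LOGARITHMIC and f.size:
        keep = (f >= 0.1 * np.max(f)) & (s > 0)
        s, f = s[keep], f[keep]
    if s.size < 3:
        raise FitError(f"{samples.muscle}: need at least 3 usable samples, have {s.size}")
    if form == LOGARITHMIC and np.any(s <= 0):
        raise FitError(f"{samples.muscle}: logarithmic fit requires strictly positive envelopes")
    if np.ptp(s) == 0:
        raise FitError(f"{samples.muscle}: zero envelope variance")

    se_a = se_b = None
    if envelope_noise_sd:
        if np.ptp(f) == 0:
            raise FitError(f"{samples.muscle}: zero force variance (inverse regression)")
        if form == LINEAR:
            alpha, beta, _, _ = _ols(f, s)
        else:
            y = np.log(s) + envelope_noise_sd**2 / (2.0 * s**2)
            alpha, beta, _, _ = _ols(f, y)
        if beta <= 0:
            raise FitError(f"{samples.muscle}: non-positive envelope gain in inverse regression")
        b = 1.0 / beta
        a = -alpha * b
    else:
        x = s if form == LINEAR else np.log(s)
        a, b, se_a, se_b = _ols(x, f)

    rel = ForceEmgRelationship(
        muscle=samples.muscle,
        form=form,
        specificity=specificity,
        speed=samples.speed,
        a=float(a),
        b=float(b),
        max_force=float(np.max(f)) if f.size else None,
        max_envelope=float(np.max(s)) if s.size else None,
        n=int(s.size),
        se_a=se_a,
        se_b=se_b,
    )
    x = s if form == LINEAR else np.log(s)
    rel.rss = float(np.sum((f - (rel.a + rel.b * x)) ** 2))
    return rel


def build_general_relationship(
    sample_sets: Sequence[ForceEmgSamples], form: str
) -> ForceEmgRelationship:
    """Pool per-subject sample sets on normalized axes and fit a general relationship.

    Each subject's samples are scaled to [0, 1] by that subject's maximum
    force and maximum envelope; subjects with a zero maximum are excluded
    with a warning. At least two usable subjects are required.
    """
    if len(sample_sets) < 2:
        raise FitError("a general relationship needs sample sets from at least 2 subjects")
    pooled_f: list[np.ndarray] = []
    pooled_s: list[np.ndarray] = []
    for samples in sample_sets:
        fmax = np.max(samples.force) if samples.n else 0.0
        smax = np.max(samples.envelope) if samples.n else 0.0
        if fmax <= 0 or smax <= 0:
            warnings.warn(
                f"{samples.muscle}: subject with zero maximum force or envelope "
                "excluded from the general relationship",
                stacklevel=2,
            )
            continue
        pooled_f.append(samples.force / fmax)
        pooled_s.append(samples.envelope / smax)
    if len(pooled_f) < 2:
        raise FitError("fewer than 2 subjects usable for the general relationship")
    first = sample_sets[0]
    pooled = ForceEmgSamples(
        muscle=first.muscle,
        force=np.concatenate(pooled_f),
        envelope=np.concatenate(pooled_s),
        speed=first.speed,
    )
    rel = fit_relationship(pooled, form, specificity="general")
    # pooled maxima are not a subject's; prediction must rescale per subject
    rel.max_force = None
    rel.max_envelope = None
    return rel


def percent_error(
    relationship: ForceEmgRelationship,
    samples: ForceEmgSamples,
    max_force: float | None = None,
    max_envelope: float | None = None,
) -> float:
    """Mean absolute prediction error as a percentage of the maximum observed force.

    Normalizing by the maximum (rather than each sample's own force) keeps
    the measure finite near zero force and scale-invariant.
    """
    if samples.n == 0:
        raise InputError(f"{samples.muscle}: no samples to score")
    fmax = float(np.max(samples.force))
    if fmax <= 0:
        raise InputError(f"{samples.muscle}: all observed forces are zero; percent error undefined")
    if relationship.specificity == "general":
        if max_force is None:
            max_force = fmax
        if max_envelope is None:
            max_envelope = float(np.max(samples.envelope))
        pred = relationship.predict(samples.envelope, max_force, max_envelope)
    else:
        pred = relationship.predict(samples.envelope)
    return float(100.0 * np.mean(np.abs(pred - samples.force)) / fmax)


def select_best_relationship(errors: Mapping[str, float]) -> str:
    """Pick the form with the lowest percent error; ties break toward linear."""
    for form in FORMS:
        if form not in errors:
            raise ConfigurationError(f"error grid incomplete: missing {form!r}")
    if errors[LINEAR] <= errors[LOGARITHMIC]:
        return LINEAR
    return LOGARITHMIC


@dataclass
class SubjectCalibration:
    """All calibration products for one subject."""

    subject: Subject
    geometry: dict[str, MuscleGeometry]
    curve: CalibrationCurve
    lever_arm_length: float
    samples: dict[float, dict[str, ForceEmgSamples]] = field(default_factory=dict)
    relationships: dict[tuple[str, str, float], ForceEmgRelationship] = field(
        default_factory=dict
    )

    def relationship(self, channel: str, form: str, speed: float) -> ForceEmgRelationship:
        try:
            return self.relationships[(channel, form, speed)]
        except KeyError as exc:
            raise ConfigurationError(
                f"no fitted relationship for {channel!r} ({form}, {speed} deg/s)"
            ) from exc

    def subject_maxima(self, channel: str, speed: float) -> tuple[float, float]:
        """(max force, max envelope) of this subject's samples at one speed."""
        samples = self.samples[speed][channel]
        return float(np.max(samples.force)), float(np.max(samples.envelope))


def calibrate_subject(
    subject: Subject,
    trials: Sequence[VctTrial],
    rest_baselines: Mapping[str, RestBaseline] | None = None,
    table: Mapping | None = None,
    ra_angle_fixed_45: bool = False,
    forms: Sequence[str] = FORMS,
    envelope_noise_sd: float | None = None,
    deadband_dps: float = PHASE_DEADBAND_DPS,
) -> SubjectCalibration:
    """Full per-subject calibration over a set of VCTs.

    Samples from trials at the same speed are pooled (so normalization
    maxima are per subject across that speed's VCTs), and every requested
    form is fitted per channel and speed.
    """
    if not trials:
        raise InputError("at least one VCT is required")
    d_l = trials[0].lever_arm_length
    geometry = muscle_angles(
        estimate_muscle_geometry(subject, table), d_l, ra_angle_fixed_45=ra_angle_fixed_45
    )
    sweeps = [t.rest_sweep for t in trials if t.rest_sweep is not None]
    if not sweeps:
        raise InputError("no rest sweep available for gravity calibration")
    curve = fit_gravity_calibration(
        np.concatenate([s[0] for s in sweeps]), np.concatenate([s[1] for s in sweeps])
    )

    calibration = SubjectCalibration(
        subject=subject, geometry=geometry, curve=curve, lever_arm_length=d_l
    )
    by_speed: dict[float, dict[str, list[ForceEmgSamples]]] = {}
    for trial in trials:
        per_channel = extract_calibration_samples(
            trial, geometry, curve, rest_baselines, deadband_dps
        )
        bucket = by_speed.setdefault(trial.speed, {ch: [] for ch in per_channel})
        for channel, samples in per_channel.items():
            bucket.setdefault(channel, []).append(samples)
    for speed, bucket in by_speed.items():
        calibration.samples[speed] = {
            ch: ForceEmgSamples.merge(sets) for ch, sets in bucket.items() if sets
        }
        for channel, samples in calibration.samples[speed].items():
            for form in forms:
                calibration.relationships[(channel, form, speed)] = fit_relationship(
                    samples, form, envelope_noise_sd=envelope_noise_sd
                )
    return calibration


def population_error_records(
    calibrations: Sequence[tuple[str, SubjectCalibration]],
    forms: Sequence[str] = FORMS,
    speeds: Sequence[float] | None = None,
) -> tuple[dict[tuple[str, str, float], ForceEmgRelationship], list[dict]]:
    """Fit general relationships across subjects and score every factor cell.

    ``calibrations`` pairs a subject id with its :class:`SubjectCalibration`.
    Returns the general relationships keyed by (channel, form, speed) and a
    long-format record list (subject, muscle, specificity, linearity, speed,
    percent_error) covering both specific and general fits — the input for
    :func:`lumbarload.stats.build_factor_grid`.
    """
    if speeds is None:
        speeds = sorted({s for _, c in calibrations for s in c.samples})
    general: dict[tuple[str, str, float], ForceEmgRelationship] = {}
    records: list[dict] = []
    for speed in speeds:
        for channel in CHANNELS:
            sets = [c.samples[speed][channel] for _, c in calibrations if speed in c.samples]
            for form in forms:
                general[(channel, form, speed)] = build_general_relationship(sets, form)
    for subject_id, calibration in calibrations:
        for speed in speeds:
            if speed not in calibration.samples:
                continue
            for channel in CHANNELS:
                samples = calibration.samples[speed][channel]
                for form in forms:
                    spec_rel = calibration.relationship(channel, form, speed)
                    records.append(
                        {
                            "subject": subject_id,
                            "muscle": channel,
                            "specificity": "specific",
                            "linearity": form,
                            "speed": speed,
                            "percent_error": percent_error(spec_rel, samples),
                        }
                    )
                    records.append(
                        {
                            "subject": subject_id,
                            "muscle": channel,
                            "specificity": "general",
                            "linearity": form,
                            "speed": speed,
                            "percent_error": percent_error(
                                general[(channel, form, speed)], samples
                            ),
                        }
                    )
    return general, records
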