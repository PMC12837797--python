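"""Synthetic motion-lab data with known ground truth.

Generates everything the pipeline consumes — subjects, supine rest traces,
isokinetic voluntary-contraction trials (VCTs) and straight-leg
stoop-to-stand (SLSS) lifting trials — from prescribed muscle-force
trajectories pushed *forward* through the same moment and force balances
the pipeline later inverts. Because the ground-truth force-to-sEMG
relationships, geometry and gravity artifact are stored alongside each
trial, calibration and load estimation are testable by parameter recovery
without any recorded data.

Study conditions emulated (defaults): 5 s supine rest; three-cycle
concentric flexion/extension VCTs over a 90 degree range at 30 and 60
deg/s, one maximum-effort trial and two sub-maximal (efforts 1.0/0.7/0.4)
per speed, with a smooth angle-dependent torso-weight torque artifact; and
~30 s SLSS bouts lifting an 8 kg ball with 2 s upright holds.

EMG is synthesized at the *envelope* level: each channel's envelope is the
inverse ground-truth mapping of its prescribed per-side force, plus
optional white noise. Raw-signal spectral realism is out of scope — the
pipeline only consumes envelopes after RMS filtering. Per-subject
heterogeneity enters through an envelope gain (log-uniform, spread
``gain_spread``) and an activation threshold s0 (uniform 0.15-0.35 envelope
units): gain differences alone are removed by max-normalization, so the
threshold spread is what differentiates subject-specific from general
relationships.

The torso-weight torque artifact is a smooth cubic in lever angle, a
deliberate departure from W*sin(angle): the measured torso-weight curve of
an instrumented dynamometer does not follow the sine assumption, and the
gravity-calibration step must not be able to cheat by assuming it.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import ConfigurationError, InputError, ParameterError
from .anthropometrics import (
    CHANNELS,
    GROUP_OF,
    GROUPS,
    MuscleGeometry,
    Subject,
    csa_ratio,
    default_coefficient_table,
    estimate_muscle_geometry,
    muscle_angles,
)
from .calibration import EO_ANGLE_DEG, VctTrial
from .emg import EmgTrace
from .load import (
    DEFAULT_HYSTERESIS_M,
    DEFAULT_LIFT_THRESHOLD_M,
    TaskTrial,
    UPPER_BODY_WEIGHT_FRACTION,
)

# rng stream codes (kept stable so trials are reproducible individually)
_STREAM_SUBJECT = 1
_STREAM_TRUTH = 2
_STREAM_REST = 3
_STREAM_VCT = 4
_STREAM_SLSS = 5

_SWEEP_ANGLE_STEP_DEG = 0.02  # dense relaxed sweep for gravity calibration


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters for the generator.

    Rates in Hz, noise in envelope units, ball mass in kg, speeds in deg/s.
    A fixed ``seed`` makes every generated artifact byte-identical across
    runs.
    """

    seed: int = 0
    n_subjects: int = 7
    emg_sampling_rate: float = 2000.0
    kinematic_sampling_rate: float = 100.0
    noise_sd: float = 0.02
    baseline_offset: float = 0.5
    vct_speeds: tuple[float, ...] = (30.0, 60.0)
    vct_angle_range_deg: float = 90.0
    effort_levels: tuple[float, ...] = (1.0, 0.7, 0.4)
    n_lifts: int = 3
    ball_mass_kg: float = 8.0
    rest_duration_s: float = 5.0
    bmi_mean: float = 25.2
    bmi_sd: float = 0.8
    bmi_range: tuple[float, float] = (18.0, 30.0)
    gain_spread: float = 3.0
    slss_stoop_angle_deg: float = 60.0
    slss_move_s: float = 2.0
    slss_hold_s: float = 2.0
    slss_pause_s: float = 0.5
    ball_floor_height_m: float = 0.10
    ra_angle_fixed_45: bool = False

    def __post_init__(self) -> None:
        if self.emg_sampling_rate <= 0 or self.kinematic_sampling_rate <= 0:
            raise ParameterError("sampling rates must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")
        if self.bmi_range[0] > self.bmi_range[1]:
            raise ParameterError("bmi_range must be (low, high)")


def _rng(config: SyntheticConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *[int(k) for k in keys]])


@dataclass
class TrueRelationship:
    """Ground-truth per-side force-to-envelope mapping for one channel.

    linear:      F = a + b*s   (a = -b*s0, zero force at the threshold s0)
    logarithmic: F = a + b*ln(s) = b*ln(s/s0)
    """

    form: str
    a: float
    b: float

    def force(self, envelope) -> np.ndarray:
        s = np.asarray(envelope, dtype=float)
        if self.form == "linear":
            f = self.a + self.b * s
        else:
            f = np.where(s > 0, self.a + self.b * np.log(np.where(s > 0, s, 1.0)), 0.0)
        return np.clip(f, 0.0, None)

    def envelope(self, force) -> np.ndarray:
        f = np.asarray(force, dtype=float)
        if self.form == "linear":
            return (f - self.a) / self.b
        return np.exp((f - self.a) / self.b)

    @property
    def threshold(self) -> float:
        """Envelope level at which force crosses zero (s0)."""
        if self.form == "linear":
            return -self.a / self.b
        return math.exp(-self.a / self.b)


@dataclass
class GravityArtifact:
    """Smooth empirical torso-weight torque vs. lever angle (N*m).

    tau(theta) = scale * (c0 + c2*u^2 + c3*u^3), u = theta / 90 deg.
    A pure function of angle: repeated angles give repeated rest torque.
    """

    scale: float
    c0: float = 0.12
    c2: float = 1.05
    c3: float = -0.32

    def __call__(self, angle_deg) -> np.ndarray:
        u = np.asarray(angle_deg, dtype=float) / 90.0
        return self.scale * (self.c0 + self.c2 * u**2 + self.c3 * u**3)


@dataclass
class GroundTruth:
    """Everything needed to reconstruct a subject's data and verify recovery."""

    subject: Subject
    geometry: dict[str, MuscleGeometry]
    lever_arm_length: float
    relationships: dict[str, TrueRelationship]
    gravity: GravityArtifact
    max_group_force: dict[str, float]


@dataclass
class TaskTruth:
    """Stored truth for one SLSS trial (never read by the pipeline)."""

    forces: dict[str, np.ndarray]  # per-side force per channel, N
    load: np.ndarray  # true compressive load F_J, N
    lift_intervals: list[tuple[float, float]]  # ball above-threshold spans, s
    grab_release: list[tuple[float, float]]  # ball pick-up / put-down times, s


def generate_subject(config: SyntheticConfig, index: int) -> Subject:
    """Draw one subject; deterministic per (seed, index).

    Height ~ N(1.78, 0.06) m, BMI ~ N(bmi_mean, bmi_sd) clipped to
    ``bmi_range``; torso depth/width and leg length scale with height plus
    small individual variation.
    """
    if not 0 <= index < config.n_subjects:
        raise IndexError(f"subject index {index} out of range [0, {config.n_subjects})")
    rng = _rng(config, _STREAM_SUBJECT, index)
    height = float(np.clip(rng.normal(1.78, 0.06), 1.60, 1.98))
    bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), *config.bmi_range))
    jitter = rng.normal(0.0, 1.0, size=3).clip(-2.5, 2.5)
    return Subject(
        mass=float(bmi * height**2),
        height=height,
        torso_depth=float(0.125 * height * (1.0 + 0.04 * jitter[0])),
        torso_width=float(0.170 * height * (1.0 + 0.04 * jitter[1])),
        leg_length=float(0.53 * height * (1.0 + 0.02 * jitter[2])),
        subject_id=f"S{index:02d}",
    )


def generate_ground_truth(
    config: SyntheticConfig, index: int, subject: Subject | None = None
) -> GroundTruth:
    """Draw the subject's true geometry, relationships and gravity artifact.

    Geometry comes from the same default coefficient table the pipeline
    uses, so geometry round trips are exact by construction.
    """
    if subject is None:
        subject = generate_subject(config, index)
    rng = _rng(config, _STREAM_TRUTH, index)
    lever_arm = 0.30 * subject.height
    geometry = muscle_angles(
        estimate_muscle_geometry(subject, default_coefficient_table()),
        lever_arm,
        ra_angle_fixed_45=config.ra_angle_fixed_45,
    )
    scale = subject.mass / 75.0
    max_group = {"ES": 3000.0 * scale, "RA": 1100.0 * scale}
    max_group["EO"] = csa_ratio(geometry) * max_group["RA"]

    half_log_spread = 0.5 * math.log(config.gain_spread)
    relationships: dict[str, TrueRelationship] = {}
    for channel in CHANNELS:
        group = GROUP_OF[channel]
        gain = math.exp(rng.uniform(-half_log_spread, half_log_spread))
        s_max = 1.0 / gain
        s0 = rng.uniform(0.15, 0.35)
        f_max_side = max_group[group] / 2.0
        if group == "ES":
            b = f_max_side / (s_max - s0)
            relationships[channel] = TrueRelationship(form="linear", a=-b * s0, b=b)
        else:
            b = f_max_side / math.log(s_max / s0)
            relationships[channel] = TrueRelationship(
                form="logarithmic", a=-b * math.log(s0), b=b
            )

    gravity_scale = (
        UPPER_BODY_WEIGHT_FRACTION
        * subject.body_weight
        * 0.25
        * (1.0 + 0.08 * float(np.clip(rng.normal(), -2.0, 2.0)))
    )
    return GroundTruth(
        subject=subject,
        geometry=geometry,
        lever_arm_length=lever_arm,
        relationships=relationships,
        gravity=GravityArtifact(scale=gravity_scale),
        max_group_force=max_group,
    )


def generate_rest_trial(
    config: SyntheticConfig,
    index: int,
    duration_s: float | None = None,
) -> dict[str, EmgTrace]:
    """Supine rest recording: baseline offset plus zero-mean white noise."""
    duration = config.rest_duration_s if duration_s is None else duration_s
    if duration <= 0:
        raise ParameterError(f"duration_s must be positive, got {duration}")
    rng = _rng(config, _STREAM_REST, index)
    n = int(round(duration * config.emg_sampling_rate))
    traces = {}
    for channel in CHANNELS:
        noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        traces[channel] = EmgTrace(
            channel=channel,
            samples=config.baseline_offset + noise,
            sampling_rate=config.emg_sampling_rate,
            trial_kind="rest",
        )
    return traces


def gravity_sweep(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Relaxed sweep on a dense uniform angle grid for gravity calibration."""
    n = int(round(config.vct_angle_range_deg / _SWEEP_ANGLE_STEP_DEG)) + 1
    angles = np.linspace(0.0, config.vct_angle_range_deg, n)
    return angles, truth.gravity(angles)


def vct_duration(config: SyntheticConfig, speed: float) -> float:
    """Duration of three flexion/extension cycles at the given speed."""
    return 3.0 * 2.0 * config.vct_angle_range_deg / speed


def _effort_per_cycle(effort_profile, n_cycles: int = 3) -> np.ndarray:
    efforts = np.atleast_1d(np.asarray(effort_profile, dtype=float))
    if efforts.size == 1:
        efforts = np.repeat(efforts, n_cycles)
    if efforts.size != n_cycles:
        raise ParameterError(f"effort_profile must be scalar or length {n_cycles}")
    if np.any((efforts < 0) | (efforts > 1)):
        raise ParameterError("effort values must lie in [0, 1]")
    return efforts


def generate_vct(
    config: SyntheticConfig,
    index: int,
    truth: GroundTruth,
    speed: float,
    effort_profile=1.0,
    trial_index: int = 0,
    attach_rest_sweep: bool = True,
) -> VctTrial:
    """One voluntary-contraction trial at a configured speed.

    The lever angle is a triangle wave (three cycles, 0 to the configured
    range); prescribed group forces are half-sine bursts per half-cycle
    scaled by the per-cycle effort (flexion drives RA/EO with the
    equal-stress split, extension drives ES). The recorded torque is the
    gravity artifact plus the forward moment balance (extension positive);
    envelopes are the inverse ground-truth mappings of the per-side forces
    plus noise.
    """
    if speed not in config.vct_speeds:
        raise ConfigurationError(f"speed {speed} deg/s not in configured speeds {config.vct_speeds}")
    efforts = _effort_per_cycle(effort_profile)
    rng = _rng(config, _STREAM_VCT, index, trial_index, int(speed))

    rng_range = config.vct_angle_range_deg
    duration = vct_duration(config, speed)
    n = int(round(duration * config.emg_sampling_rate))
    t = np.arange(n) / config.emg_sampling_rate
    cycle_pos = (speed * t) % (2.0 * rng_range)
    angle = np.where(cycle_pos <= rng_range, cycle_pos, 2.0 * rng_range - cycle_pos)
    flexing = cycle_pos < rng_range
    progress = np.where(flexing, cycle_pos, cycle_pos - rng_range) / rng_range
    cycle_idx = np.minimum((speed * t) // (2.0 * rng_range), 2).astype(int)
    effort_t = efforts[cycle_idx]

    burst = np.sin(np.pi * progress)
    f_es = np.where(~flexing, effort_t * truth.max_group_force["ES"] * burst, 0.0)
    f_ra = np.where(flexing, effort_t * truth.max_group_force["RA"] * burst, 0.0)
    r = csa_ratio(truth.geometry)
    f_eo = r * f_ra

    geo = truth.geometry
    tau_muscle = f_es * geo["RES"].moment_arm * np.cos(
        np.radians(geo["RES"].inclination_deg)
    ) - (
        f_ra * geo["RRA"].moment_arm * np.cos(np.radians(geo["RRA"].inclination_deg))
        + f_eo * geo["REO"].moment_arm * np.cos(np.radians(EO_ANGLE_DEG))
    )
    torque = truth.gravity(angle) + tau_muscle

    group_force = {"ES": f_es, "RA": f_ra, "EO": f_eo}
    envelopes: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        s = truth.relationships[channel].envelope(group_force[GROUP_OF[channel]] / 2.0)
        if config.noise_sd > 0:
            s = np.clip(s + rng.normal(0.0, config.noise_sd, size=n), 0.0, None)
        envelopes[channel] = s

    sweep = gravity_sweep(config, truth) if attach_rest_sweep else None
    return VctTrial(
        time=t,
        lever_angle_deg=angle,
        torque_nm=torque,
        envelopes=envelopes,
        speed=speed,
        lever_arm_length=truth.lever_arm_length,
        rest_sweep=sweep,
    )


def _slss_segments(config: SyntheticConfig, n_lifts: int) -> list[tuple[str, float, bool]]:
    """(kind, duration, ball_carried) timeline: pause, then per lift
    down/up+ball/hold/down+ball/up, pause."""
    segments: list[tuple[str, float, bool]] = [("pause", config.slss_pause_s, False)]
    for _ in range(n_lifts):
        segments += [
            ("down", config.slss_move_s, False),
            ("up", config.slss_move_s, True),
            ("hold", config.slss_hold_s, True),
            ("down", config.slss_move_s, True),
            ("up", config.slss_move_s, False),
            ("pause", config.slss_pause_s, False),
        ]
    return segments


def generate_slss_trial(
    config: SyntheticConfig,
    index: int,
    truth: GroundTruth,
    n_lifts: int | None = None,
    effort: float = 1.0,
    stoop_angle_deg: float | None = None,
    trial_index: int = 0,
) -> tuple[TaskTrial, TaskTruth]:
    """One straight-leg stoop-to-stand trial with stored ground truth.

    Torso inclination ramps (raised-cosine) between upright and the stoop
    angle; the ball rises from the floor to carrying height exactly
    ``n_lifts`` times, with a 2 s upright hold per lift. Prescribed muscle
    forces combine an inclination-dependent extensor demand with a tonic
    carrying component; the true compressive load series computed through
    the vertical force balance is stored for recovery tests.
    """
    if n_lifts is None:
        n_lifts = config.n_lifts
    if n_lifts < 1:
        raise ParameterError(f"n_lifts must be >= 1, got {n_lifts}")
    if not 0.0 <= effort <= 1.0:
        raise ParameterError("effort must lie in [0, 1]")
    theta_max = config.slss_stoop_angle_deg if stoop_angle_deg is None else stoop_angle_deg
    rng = _rng(config, _STREAM_SLSS, index, trial_index)

    segments = _slss_segments(config, n_lifts)
    duration = sum(d for _, d, _ in segments)
    rate = config.emg_sampling_rate
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    subject = truth.subject
    floor = config.ball_floor_height_m
    lift_amp = 0.62 * subject.height - floor

    theta = np.zeros(n)
    height = np.full(n, floor)
    carried = np.zeros(n)
    grab_release: list[tuple[float, float]] = []
    lift_intervals: list[tuple[float, float]] = []
    # analytic crossing times matching the default segmentation bands:
    # a cycle starts when the ball passes floor + threshold on the way up and
    # ends when it drops back below floor + hysteresis
    p_up = math.acos(1.0 - 2.0 * DEFAULT_LIFT_THRESHOLD_M / lift_amp) / math.pi
    p_down = math.acos(2.0 * DEFAULT_HYSTERESIS_M / lift_amp - 1.0) / math.pi

    t0 = 0.0
    current_grab: float | None = None
    current_rise: float | None = None
    for kind, seg_dur, is_carried in segments:
        sel = (t >= t0) & (t < t0 + seg_dur)
        p = (t[sel] - t0) / seg_dur
        if kind == "down":
            theta[sel] = theta_max * 0.5 * (1.0 - np.cos(np.pi * p))
        elif kind == "up":
            theta[sel] = theta_max * 0.5 * (1.0 + np.cos(np.pi * p))
        if is_carried:
            carried[sel] = 1.0
            if kind == "up":  # ascent with the ball: rising from the floor
                height[sel] = floor + lift_amp * 0.5 * (1.0 - np.cos(np.pi * p))
                current_grab = t0
                current_rise = t0 + p_up * seg_dur
            elif kind == "hold":
                height[sel] = floor + lift_amp
            elif kind == "down":  # descent with the ball: back to the floor
                height[sel] = floor + lift_amp * 0.5 * (1.0 + np.cos(np.pi * p))
                if current_grab is not None:
                    grab_release.append((current_grab, t0 + seg_dur))
                    lift_intervals.append((current_rise, t0 + p_down * seg_dur))
                    current_grab = current_rise = None
        t0 += seg_dur

    theta_rad = np.radians(theta)
    sin_theta = np.sin(theta_rad)
    group_force = {
        "ES": effort * truth.max_group_force["ES"] * (0.55 * sin_theta + 0.25 * carried),
        "RA": effort * truth.max_group_force["RA"] * (0.12 * sin_theta + 0.05 * carried),
        "EO": effort * truth.max_group_force["EO"] * (0.10 * sin_theta + 0.06 * carried),
    }

    envelopes: dict[str, np.ndarray] = {}
    true_forces: dict[str, np.ndarray] = {}
    load = UPPER_BODY_WEIGHT_FRACTION * subject.body_weight * np.cos(theta_rad)
    for channel in CHANNELS:
        f_side = group_force[GROUP_OF[channel]] / 2.0
        true_forces[channel] = f_side
        load = load + f_side * np.sin(np.radians(truth.geometry[channel].inclination_deg))
        if effort > 0:
            s = truth.relationships[channel].envelope(f_side)
        else:
            s = np.zeros(n)  # fully silent channels in the degenerate no-effort trial
        if config.noise_sd > 0:
            s = np.clip(s + rng.normal(0.0, config.noise_sd, size=n), 0.0, None)
        envelopes[channel] = s

    trial = TaskTrial(
        time=t,
        envelopes=envelopes,
        torso_angle_deg=theta,
        ball_height_m=height,
        subject_id=subject.subject_id,
    )
    return trial, TaskTruth(
        forces=true_forces, load=load, lift_intervals=lift_intervals, grab_release=grab_release
    )


def generate_standing_trial(
    config: SyntheticConfig,
    index: int,
    truth: GroundTruth,
    duration_s: float = 5.0,
) -> tuple[TaskTrial, TaskTruth]:
    """Quiet upright standing: silent envelopes, ball on the floor.

    The true load is the upper-body weight term alone, 0.67 * BW.
    """
    n = int(round(duration_s * config.emg_sampling_rate))
    t = np.arange(n) / config.emg_sampling_rate
    zeros = np.zeros(n)
    trial = TaskTrial(
        time=t,
        envelopes={ch: zeros.copy() for ch in CHANNELS},
        torso_angle_deg=zeros.copy(),
        ball_height_m=np.full(n, config.ball_floor_height_m),
        subject_id=truth.subject.subject_id,
    )
    load = np.full(n, UPPER_BODY_WEIGHT_FRACTION * truth.subject.body_weight)
    return trial, TaskTruth(
        forces={ch: zeros.copy() for ch in CHANNELS},
        load=load,
        lift_intervals=[],
        grab_release=[],
    )


@dataclass
class SubjectDataset:
    """All generated artifacts for one subject."""

    subject: Subject
    truth: GroundTruth
    rest: dict[str, EmgTrace]
    vcts: list[VctTrial]
    slss: TaskTrial | None = None
    slss_truth: TaskTruth | None = None


def generate_subject_dataset(
    config: SyntheticConfig,
    index: int,
    speeds: Sequence[float] | None = None,
    include_slss: bool = True,
) -> SubjectDataset:
    """Full per-subject dataset: rest, VCTs at every speed/effort, SLSS."""
    subject = generate_subject(config, index)
    truth = generate_ground_truth(config, index, subject)
    rest = generate_rest_trial(config, index)
    vcts = [
        generate_vct(config, index, truth, speed, effort, trial_index=k)
        for speed in (speeds if speeds is not None else config.vct_speeds)
        for k, effort in enumerate(config.effort_levels)
    ]
    slss = slss_truth = None
    if include_slss:
        slss, slss_truth = generate_slss_trial(config, index, truth)
    return SubjectDataset(
        subject=subject, truth=truth, rest=rest, vcts=vcts, slss=slss, slss_truth=slss_truth
    )


def _truth_to_json(truth: GroundTruth, slss_truth: TaskTruth | None) -> dict:
    payload = {
        "subject": asdict(truth.subject),
        "lever_arm_length_m": truth.lever_arm_length,
        "geometry": {ch: asdict(g) for ch, g in truth.geometry.items()},
        "relationships": {ch: asdict(r) for ch, r in truth.relationships.items()},
        "gravity": asdict(truth.gravity),
        "max_group_force_n": truth.max_group_force,
    }
    if slss_truth is not None:
        payload["slss"] = {
            "lift_intervals_s": slss_truth.lift_intervals,
            "grab_release_s": slss_truth.grab_release,
        }
    return payload


def simulate_dataset(config: SyntheticConfig, outdir) -> list[Path]:
    """Write a full synthetic study to ``outdir`` (one directory per subject).

    Trial files are the delimited-text formats the pipeline reads; ground
    truth goes to a structured sidecar (``ground_truth.json``) the pipeline
    never reads.
    """
    from . import io as _io

    outdir = Path(outdir)
    written: list[Path] = []
    for index in range(config.n_subjects):
        ds = generate_subject_dataset(config, index)
        subject_dir = outdir / ds.subject.subject_id
        subject_dir.mkdir(parents=True, exist_ok=True)
        _io.write_subject(ds.subject, subject_dir / "subject.yaml")
        _io.write_rest_trial(ds.rest, subject_dir / "rest.csv")
        sweep = ds.vcts[0].rest_sweep
        _io.write_gravity_sweep(sweep[0], sweep[1], subject_dir / "gravity_sweep.csv")
        counts: dict[float, int] = {}
        for trial in ds.vcts:
            k = counts.get(trial.speed, 0) + 1
            counts[trial.speed] = k
            _io.write_vct_trial(trial, subject_dir / f"vct_{int(trial.speed)}_{k}.csv")
        if ds.slss is not None:
            _io.write_task_trial(ds.slss, subject_dir / "slss.csv")
        with open(subject_dir / "ground_truth.json", "w") as fh:
            json.dump(_truth_to_json(ds.truth, ds.slss_truth), fh, indent=1)
        written.append(subject_dir)
    return written
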