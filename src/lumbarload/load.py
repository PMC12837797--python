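"""L4/L5 compressive load estimation for lifting-task trials.

Fitted force-to-sEMG relationships are applied to the task-trial envelopes
(sub-rest samples forced to zero), and the compressive joint load follows
from the vertical force balance at L4/L5:

    F_J(t) = F_UBW * cos(theta_UBW(t)) + sum_M F_M(t) * sin(theta_M)

where F_UBW = 0.67 * body weight is the upper-body weight, theta_UBW the
torso inclination from vertical, and theta_M each muscle's line-of-action
inclination. Lift cycles are segmented from the ball-height channel and the
compressive impulse (time integral of F_J) is reported per cycle, both raw
(N*s) and normalized by body weight (s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._exceptions import ConfigurationError, InputError
from .anthropometrics import GROUP_OF, MuscleGeometry, Subject
from .calibration import DEFAULT_TASK_FORMS, DEFAULT_TASK_SPEED, ForceEmgRelationship
from .emg import Envelope, RestBaseline

UPPER_BODY_WEIGHT_FRACTION = 0.67

DEFAULT_LIFT_THRESHOLD_M = 0.02
DEFAULT_HYSTERESIS_M = 0.01
DEFAULT_FLOOR_PERCENTILE = 5.0
PERCENT_TASK_POINTS = 101


@dataclass
class TaskTrial:
    """One lifting-task (e.g. stoop-to-stand) trial on a common timebase."""

    time: np.ndarray
    envelopes: dict[str, np.ndarray]
    torso_angle_deg: np.ndarray
    ball_height_m: np.ndarray
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.torso_angle_deg = np.asarray(self.torso_angle_deg, dtype=float)
        self.ball_height_m = np.asarray(self.ball_height_m, dtype=float)
        n = self.time.size
        if self.torso_angle_deg.size != n or self.ball_height_m.size != n:
            raise InputError("kinematic channels not aligned with the trial timebase")
        for channel, env in self.envelopes.items():
            env = np.asarray(env, dtype=float)
            if env.size != n:
                raise InputError(f"envelope {channel!r} not aligned with the trial timebase")
            self.envelopes[channel] = env

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class LoadSeries:
    """Compressive load over time, absolute (N) and as percent body weight."""

    time: np.ndarray
    f_j: np.ndarray
    f_j_pct_bw: np.ndarray
    muscle_forces: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass(frozen=True)
class LiftCycle:
    """One lift: ball leaves the floor band at start, returns at end."""

    start_index: int
    end_index: int
    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise InputError("lift cycle must end after it starts")


@dataclass
class ImpulseSummary:
    """Per-cycle compressive impulses and their per-subject summary."""

    impulses_ns: np.ndarray
    impulses_normalized_s: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.impulses_ns.size

    @property
    def mean_ns(self) -> float:
        return float(np.mean(self.impulses_ns))

    @property
    def sd_ns(self) -> float:
        return float(np.std(self.impulses_ns, ddof=1)) if self.n_cycles > 1 else 0.0

    @property
    def mean_normalized_s(self) -> float:
        return float(np.mean(self.impulses_normalized_s))

    @property
    def sd_normalized_s(self) -> float:
        return float(np.std(self.impulses_normalized_s, ddof=1)) if self.n_cycles > 1 else 0.0


def predict_muscle_force(
    relationship: ForceEmgRelationship,
    envelope,
    rest_baseline: RestBaseline | None = None,
    max_force: float | None = None,
    max_envelope: float | None = None,
) -> np.ndarray:
    """Muscle force series from an envelope through a fitted relationship.

    Samples with envelope strictly below the rest level are zero force;
    otherwise the relationship is evaluated and clamped at zero. General
    relationships rescale by the subject's maxima.
    """
    if isinstance(envelope, Envelope):
        if rest_baseline is not None and envelope.channel != rest_baseline.channel:
            raise InputError(
                f"channel mismatch: envelope {envelope.channel!r} "
                f"vs baseline {rest_baseline.channel!r}"
            )
        values = envelope.samples
    else:
        values = np.asarray(envelope, dtype=float)
    force = relationship.predict(values, max_force=max_force, max_envelope=max_envelope)
    if rest_baseline is not None:
        force = np.where(values < rest_baseline.rest_envelope_level, 0.0, force)
    return force


def torso_angle_from_markers(sacrum, sternum, vertical_axis: int = 2) -> np.ndarray:
    """Torso inclination from vertical (degrees) from sacrum/sternum markers.

    Accepts single 3-vectors or (n, 3) frame stacks.
    """
    vec = np.atleast_2d(np.asarray(sternum, dtype=float)) - np.atleast_2d(
        np.asarray(sacrum, dtype=float)
    )
    norm = np.linalg.norm(vec, axis=1)
    if np.any(norm == 0):
        raise InputError("sacrum and sternum markers coincide; torso vector has zero length")
    cos_theta = np.clip(vec[:, vertical_axis] / norm, -1.0, 1.0)
    angles = np.degrees(np.arccos(cos_theta))
    return angles if angles.size > 1 else float(angles[0])


def compute_load_series(
    time,
    muscle_forces: Mapping[str, np.ndarray],
    geometry: Mapping[str, MuscleGeometry],
    subject: Subject,
    torso_angle_deg,
    include_ball_weight: bool = False,
    ball_mass_kg: float = 0.0,
    ball_carried: np.ndarray | None = None,
) -> LoadSeries:
    """Vertical force balance: compressive L4/L5 load per sample.

    ``include_ball_weight`` optionally adds the carried ball's weight to the
    upper-body term for sensitivity analyses (off by default; the base model
    lists only the upper-body weight and muscle terms).
    """
    time = np.asarray(time, dtype=float)
    theta = np.radians(np.asarray(torso_angle_deg, dtype=float))
    if theta.size != time.size:
        raise InputError("torso angle series not aligned with the timebase")
    bw = subject.body_weight
    f_j = UPPER_BODY_WEIGHT_FRACTION * bw * np.cos(theta)
    if include_ball_weight and ball_mass_kg > 0:
        carried = (
            np.ones_like(f_j) if ball_carried is None else np.asarray(ball_carried, dtype=float)
        )
        f_j = f_j + ball_mass_kg * 9.81 * carried * np.cos(theta)
    forces: dict[str, np.ndarray] = {}
    for channel, force in muscle_forces.items():
        force = np.asarray(force, dtype=float)
        if force.size != time.size:
            raise InputError(f"muscle force series {channel!r} not aligned with the timebase")
        f_j = f_j + force * np.sin(np.radians(geometry[channel].inclination_deg))
        forces[channel] = force
    return LoadSeries(time=time, f_j=f_j, f_j_pct_bw=100.0 * f_j / bw, muscle_forces=forces)


def segment_lift_cycles(
    ball_height_m,
    time=None,
    lift_threshold_m: float = DEFAULT_LIFT_THRESHOLD_M,
    hysteresis_m: float = DEFAULT_HYSTERESIS_M,
    floor_percentile: float = DEFAULT_FLOOR_PERCENTILE,
) -> list[LiftCycle]:
    """Detect lift cycles from the ball-height channel.

    The resting floor is estimated as a low percentile of the series; a
    cycle starts at the upward crossing of floor + ``lift_threshold_m`` and
    ends at the subsequent downward crossing back into the floor band
    (floor + ``hysteresis_m``). A trailing incomplete cycle is discarded;
    a flat series yields no cycles.
    """
    height = np.asarray(ball_height_m, dtype=float)
    if height.size == 0:
        raise InputError("empty ball-height series")
    if time is None:
        time = np.arange(height.size, dtype=float)
    else:
        time = np.asarray(time, dtype=float)
    floor = np.percentile(height, floor_percentile)
    upper = floor + lift_threshold_m
    lower = floor + hysteresis_m
    cycles: list[LiftCycle] = []
    start: int | None = None
    for i, h in enumerate(height):
        if start is None:
            if h > upper:
                start = i
        elif h < lower:
            cycles.append(
                LiftCycle(
                    start_index=start,
                    end_index=i,
                    start_time=float(time[start]),
                    end_time=float(time[i]),
                )
            )
            start = None
    return cycles


def compute_impulse(
    load_series: LoadSeries, cycle: LiftCycle, body_weight: float
) -> tuple[float, float]:
    """Trapezoidal compressive impulse over one cycle: (N*s, BW-normalized s)."""
    if cycle.end_index >= load_series.f_j.size:
        raise InputError("lift cycle extends beyond the load series")
    sl = slice(cycle.start_index, cycle.end_index + 1)
    if cycle.end_index - cycle.start_index < 1:
        raise InputError("empty lift cycle")
    raw = float(np.trapezoid(load_series.f_j[sl], load_series.time[sl]))
    return raw, raw / body_weight


def summarize_impulses(
    load_series: LoadSeries, cycles: Sequence[LiftCycle], body_weight: float
) -> ImpulseSummary:
    """Per-cycle impulses for a trial, raw and BW-normalized."""
    if not cycles:
        raise InputError("no lift cycles to integrate")
    pairs = [compute_impulse(load_series, c, body_weight) for c in cycles]
    return ImpulseSummary(
        impulses_ns=np.array([p[0] for p in pairs]),
        impulses_normalized_s=np.array([p[1] for p in pairs]),
    )


def resample_cycle_percent(
    load_series: LoadSeries, cycle: LiftCycle, n_points: int = PERCENT_TASK_POINTS
) -> np.ndarray:
    """Normalized-load curve of one cycle on a 0-100 %task grid (%BW units)."""
    sl = slice(cycle.start_index, cycle.end_index + 1)
    t = load_series.time[sl]
    grid = np.linspace(t[0], t[-1], n_points)
    return np.interp(grid, t, load_series.f_j_pct_bw[sl])


def estimate_task_load(
    trial: TaskTrial,
    relationships: Mapping[str, ForceEmgRelationship],
    geometry: Mapping[str, MuscleGeometry],
    subject: Subject,
    rest_baselines: Mapping[str, RestBaseline] | None = None,
    subject_maxima: Mapping[str, tuple[float, float]] | None = None,
    include_ball_weight: bool = False,
    ball_mass_kg: float = 0.0,
) -> LoadSeries:
    """Apply per-channel relationships to a task trial and balance the load.

    ``relationships`` maps each channel to its chosen relationship (by
    default the 60 deg/s fit, linear for ES and logarithmic for RA/EO —
    see :data:`lumbarload.calibration.DEFAULT_TASK_FORMS`). For general
    relationships, ``subject_maxima[channel] = (max_force, max_envelope)``
    supplies the rescaling constants.
    """
    forces: dict[str, np.ndarray] = {}
    for channel, env in trial.envelopes.items():
        if channel not in relationships:
            raise ConfigurationError(f"no relationship configured for channel {channel!r}")
        baseline = rest_baselines.get(channel) if rest_baselines else None
        max_f = max_s = None
        if subject_maxima and channel in subject_maxima:
            max_f, max_s = subject_maxima[channel]
        forces[channel] = predict_muscle_force(
            relationships[channel], env, baseline, max_force=max_f, max_envelope=max_s
        )
    return compute_load_series(
        trial.time,
        forces,
        geometry,
        subject,
        trial.torso_angle_deg,
        include_ball_weight=include_ball_weight,
        ball_mass_kg=ball_mass_kg,
    )
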