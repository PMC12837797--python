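"""Trunk anthropometry and muscle geometry.

Torso dimensions are measured from reflective-marker positions (or entered
directly) and mapped to per-muscle cross-sectional areas (CSA), moment arms
and line-of-action inclinations through a linear coefficient table. The
three muscle groups crossing the L4/L5 plane in this model are the erector
spinae (ES, trunk extensor), rectus abdominis (RA) and external oblique
(EO, trunk flexors); each is instrumented bilaterally (R/L channels) and
bilateral geometry is identical because all calibration motion is sagittal.

Coordinate convention: right-handed lab frame, x sagittal (forward),
y mediolateral, z vertical up.

The shipped coefficient table contains editable placeholder values in
physiological ranges (ES CSA ~20 cm^2, ES moment arm ~5.5 cm, RA moment arm
~9 cm). Correctness of the calibration/estimation round trip is defined
relative to whatever table is supplied, so users may substitute literature
regression coefficients without touching code.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from ._exceptions import ConfigurationError, GeometryError, InputError

GRAVITY = 9.81  # m/s^2

#: sEMG channel labels, right/left  erector spinae, rectus abdominis, external oblique
CHANNELS = ("RES", "LES", "RRA", "LRA", "REO", "LEO")

#: bilateral muscle groups -> their channels
GROUPS: dict[str, tuple[str, str]] = {
    "ES": ("RES", "LES"),
    "RA": ("RRA", "LRA"),
    "EO": ("REO", "LEO"),
}

#: group of each channel
GROUP_OF = {ch: g for g, chans in GROUPS.items() for ch in chans}

#: fixed external-oblique line-of-action inclination, degrees
EO_ANGLE_DEG = 45.0


@dataclass(frozen=True)
class Subject:
    """Anthropometric record of one participant.

    Parameters are SI: mass in kg, lengths in m. ``body_weight`` (N) is
    derived as mass * g.
    """

    mass: float
    height: float
    torso_depth: float
    torso_width: float
    leg_length: float
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        for name in ("mass", "height", "torso_depth", "torso_width", "leg_length"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InputError(f"Subject.{name} must be positive and finite, got {value!r}")

    @property
    def body_weight(self) -> float:
        """Weight in newtons (mass * 9.81)."""
        return self.mass * GRAVITY

    @property
    def bmi(self) -> float:
        return self.mass / self.height**2


@dataclass
class MuscleGeometry:
    """Geometry of one muscle channel at the L4/L5 plane.

    ``csa`` is in cm^2 (only its ratio is ever used), ``moment_arm`` in m,
    ``inclination_deg`` is the single line-of-action angle whose cosine
    enters the sagittal moment balance and whose sine enters the vertical
    force balance.
    """

    muscle: str
    csa: float
    moment_arm: float
    inclination_deg: float = float("nan")

    def __post_init__(self) -> None:
        if self.csa <= 0:
            raise GeometryError(f"{self.muscle}: csa must be positive, got {self.csa}")
        if self.moment_arm <= 0:
            raise GeometryError(
                f"{self.muscle}: moment arm must be positive, got {self.moment_arm}"
            )


# Coefficient table: per group, value = c0 + c_depth*torso_depth + c_width*torso_width
# (lengths in m, csa in cm^2, moment_arm in m).  Placeholder defaults sit in
# physiological ranges for a ~0.22 m deep, ~0.30 m wide torso.
_DEFAULT_TABLE: dict[str, dict[str, tuple[float, float, float]]] = {
    "ES": {"csa": (0.0, 90.0, 0.0), "moment_arm": (0.0, 0.25, 0.0)},
    "RA": {"csa": (0.0, 36.0, 0.0), "moment_arm": (0.0, 0.40, 0.0)},
    "EO": {"csa": (0.0, 0.0, 40.0), "moment_arm": (0.0, 0.0, 0.25)},
}


def default_coefficient_table() -> dict:
    """Return a fresh copy of the default anthropometric coefficient table."""
    return copy.deepcopy(_DEFAULT_TABLE)


def load_coefficient_table(path) -> dict:
    """Load a coefficient table from a YAML file (same structure as the default)."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    for group, entries in table.items():
        for key in ("csa", "moment_arm"):
            entries[key] = tuple(float(c) for c in entries[key])
    return table


def save_coefficient_table(table: Mapping, path) -> None:
    serializable = {g: {k: list(v) for k, v in e.items()} for g, e in table.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(serializable, fh, sort_keys=True)


_REQUIRED_MARKERS = ("sacrum", "sternum", "left_iliac_crest", "right_iliac_crest", "calcaneus")


def _marker_mean(value) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(value, dtype=float))
    if arr.shape[-1] != 3:
        raise InputError(f"marker positions must be 3D, got shape {arr.shape}")
    return arr.mean(axis=0)


def measure_torso(
    marker_positions: Mapping[str, "np.ndarray"],
    sagittal_axis: int = 0,
    vertical_axis: int = 2,
) -> tuple[float, float, float]:
    """Measure (torso_depth, torso_width, leg_length) from a standing trial.

    ``marker_positions`` maps marker names to a 3-vector or an (n, 3) frame
    stack (averaged over frames). Depth is the sagittal-axis distance from
    sacrum to sternum; width the Euclidean distance between the iliac-crest
    markers; leg length the vertical distance from the (mean) iliac crest to
    the calcaneus.
    """
    for name in _REQUIRED_MARKERS:
        if name not in marker_positions:
            raise InputError(f"missing required marker: {name!r}")
    pos = {name: _marker_mean(marker_positions[name]) for name in _REQUIRED_MARKERS}
    depth = abs(pos["sternum"][sagittal_axis] - pos["sacrum"][sagittal_axis])
    width = float(np.linalg.norm(pos["left_iliac_crest"] - pos["right_iliac_crest"]))
    crest_height = 0.5 * (
        pos["left_iliac_crest"][vertical_axis] + pos["right_iliac_crest"][vertical_axis]
    )
    leg_length = abs(crest_height - pos["calcaneus"][vertical_axis])
    return float(depth), width, float(leg_length)


def _evaluate(coeffs: tuple[float, float, float], depth: float, width: float) -> float:
    c0, c_depth, c_width = coeffs
    return c0 + c_depth * depth + c_width * width


def estimate_muscle_geometry(
    subject: Subject, table: Mapping | None = None
) -> dict[str, MuscleGeometry]:
    """Estimate CSA and moment arm for every channel from torso dimensions.

    Bilateral channels share identical geometry (sagittal-plane symmetry).
    Line-of-action inclinations are left unset; see :func:`muscle_angles`.
    """
    if table is None:
        table = _DEFAULT_TABLE
    geometry: dict[str, MuscleGeometry] = {}
    for group, channels in GROUPS.items():
        if group not in table:
            raise ConfigurationError(f"coefficient table missing muscle group {group!r}")
        entry = table[group]
        csa = _evaluate(entry["csa"], subject.torso_depth, subject.torso_width)
        arm = _evaluate(entry["moment_arm"], subject.torso_depth, subject.torso_width)
        for channel in channels:
            geometry[channel] = MuscleGeometry(muscle=channel, csa=csa, moment_arm=arm)
    return geometry


def muscle_angles(
    geometry: Mapping[str, MuscleGeometry],
    lever_arm_length: float,
    ra_angle_fixed_45: bool = False,
) -> dict[str, MuscleGeometry]:
    """Assign line-of-action inclinations from moment arms and the lever arm.

    ES and RA inclinations are arcsin(d_M / d_L); the EO crosses the L4/L5
    plane at a fixed 45 degrees. ``ra_angle_fixed_45=True`` pins the RA at
    45 degrees as well (the alternative reading of the RA assumption).
    Returns a new geometry mapping; the input is not mutated.
    """
    if lever_arm_length <= 0:
        raise GeometryError(f"lever arm length must be positive, got {lever_arm_length}")
    out: dict[str, MuscleGeometry] = {}
    for channel, geom in geometry.items():
        group = GROUP_OF[channel]
        if group == "EO" or (group == "RA" and ra_angle_fixed_45):
            angle = EO_ANGLE_DEG
        else:
            if geom.moment_arm >= lever_arm_length:
                raise GeometryError(
                    f"{channel}: moment arm {geom.moment_arm:.4f} m must be smaller than "
                    f"the lever arm {lever_arm_length:.4f} m"
                )
            angle = math.degrees(math.asin(geom.moment_arm / lever_arm_length))
        out[channel] = replace(geom, inclination_deg=angle)
    return out


def csa_ratio(geometry: Mapping[str, MuscleGeometry]) -> float:
    """CSA_EO / CSA_RA, the equal-stress split of the flexion moment."""
    return geometry["REO"].csa / geometry["RRA"].csa
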