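"""Delimited-text I/O for trials, subjects and fitted relationships.

Time-series files are plain CSV (UTF-8, '.' decimal): a ``time_s`` column
plus one column per channel, preceded by ``# key: value`` metadata lines
(sampling rate, trial kind, VCT speed, lever arm length). Subjects are
YAML; fitted relationships are JSON. Ground-truth sidecars written by the
generator are JSON and are never read by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._exceptions import InputError
from .anthropometrics import CHANNELS, Subject
from .calibration import ForceEmgRelationship, VctTrial
from .emg import EmgTrace
from .load import LoadSeries, TaskTrial

_FLOAT_FMT = "%.12g"


def _write_csv(path, frame: pd.DataFrame, metadata: Mapping | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_csv(path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    metadata: dict = {}
    with open(path, encoding="utf-8") as fh:
        position = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(position)
                break
            key, _, raw = line.lstrip("# ").partition(":")
            metadata[key.strip()] = yaml.safe_load(raw.strip())
            position = fh.tell()
        frame = pd.read_csv(fh)
    return frame, metadata


def write_subject(subject: Subject, path) -> None:
    data = {
        k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
        for k, v in asdict(subject).items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_subject(path) -> Subject:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return Subject(**data)


def write_rest_trial(traces: Mapping[str, EmgTrace], path) -> None:
    first = next(iter(traces.values()))
    frame = pd.DataFrame({"time_s": first.time})
    for channel in CHANNELS:
        frame[channel] = traces[channel].samples
    _write_csv(
        path, frame, {"trial_kind": "rest", "sampling_rate_hz": first.sampling_rate}
    )


def read_rest_trial(path) -> dict[str, EmgTrace]:
    frame, metadata = _read_csv(path)
    rate = float(metadata.get("sampling_rate_hz") or _infer_rate(frame))
    return {
        ch: EmgTrace(channel=ch, samples=frame[ch].to_numpy(), sampling_rate=rate,
                     trial_kind="rest")
        for ch in CHANNELS
        if ch in frame
    }


def _infer_rate(frame: pd.DataFrame) -> float:
    t = frame["time_s"].to_numpy()
    if t.size < 2:
        raise InputError("cannot infer sampling rate from fewer than 2 samples")
    return 1.0 / float(np.median(np.diff(t)))


def write_gravity_sweep(angles_deg, torques_nm, path) -> None:
    _write_csv(
        path,
        pd.DataFrame({"lever_angle_deg": angles_deg, "torque_nm": torques_nm}),
        {"trial_kind": "gravity_sweep"},
    )


def read_gravity_sweep(path) -> tuple[np.ndarray, np.ndarray]:
    frame, _ = _read_csv(path)
    return frame["lever_angle_deg"].to_numpy(), frame["torque_nm"].to_numpy()


def write_vct_trial(trial: VctTrial, path) -> None:
    frame = pd.DataFrame(
        {
            "time_s": trial.time,
            "lever_angle_deg": trial.lever_angle_deg,
            "torque_nm": trial.torque_nm,
        }
    )
    for channel in CHANNELS:
        frame[channel] = trial.envelopes[channel]
    _write_csv(
        path,
        frame,
        {
            "trial_kind": "vct",
            "speed_deg_s": trial.speed,
            "lever_arm_length_m": trial.lever_arm_length,
            "signal_kind": "envelope",
        },
    )


def read_vct_trial(path, rest_sweep: tuple | None = None) -> VctTrial:
    frame, metadata = _read_csv(path)
    for key in ("speed_deg_s", "lever_arm_length_m"):
        if key not in metadata:
            raise InputError(f"VCT file {path} missing metadata {key!r}")
    return VctTrial(
        time=frame["time_s"].to_numpy(),
        lever_angle_deg=frame["lever_angle_deg"].to_numpy(),
        torque_nm=frame["torque_nm"].to_numpy(),
        envelopes={ch: frame[ch].to_numpy() for ch in CHANNELS if ch in frame},
        speed=float(metadata["speed_deg_s"]),
        lever_arm_length=float(metadata["lever_arm_length_m"]),
        rest_sweep=rest_sweep,
    )


def write_task_trial(trial: TaskTrial, path) -> None:
    frame = pd.DataFrame(
        {
            "time_s": trial.time,
            "torso_angle_deg": trial.torso_angle_deg,
            "ball_height_m": trial.ball_height_m,
        }
    )
    for channel in CHANNELS:
        frame[channel] = trial.envelopes[channel]
    _write_csv(
        path,
        frame,
        {"trial_kind": "task", "subject_id": trial.subject_id, "signal_kind": "envelope"},
    )


def read_task_trial(path) -> TaskTrial:
    frame, metadata = _read_csv(path)
    return TaskTrial(
        time=frame["time_s"].to_numpy(),
        envelopes={ch: frame[ch].to_numpy() for ch in CHANNELS if ch in frame},
        torso_angle_deg=frame["torso_angle_deg"].to_numpy(),
        ball_height_m=frame["ball_height_m"].to_numpy(),
        subject_id=str(metadata.get("subject_id", "S00")),
    )


def write_relationships(relationships: Sequence[ForceEmgRelationship], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([asdict(rel) for rel in relationships], fh, indent=1)


def read_relationships(path) -> list[ForceEmgRelationship]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return [ForceEmgRelationship(**entry) for entry in payload]


def write_load_series(series: LoadSeries, path) -> None:
    frame = pd.DataFrame(
        {"time_s": series.time, "f_j_n": series.f_j, "f_j_pct_bw": series.f_j_pct_bw}
    )
    for channel, force in series.muscle_forces.items():
        frame[f"force_{channel}_n"] = force
    _write_csv(path, frame, {"content": "load_series"})
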