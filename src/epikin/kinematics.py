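"""Kinematic summaries of epicardial marker motion.

Four per-recording parameters describe the tracked motion of the
right-ventricle surface (unit mass; pixel units are kept, no mm
calibration):

* maximum contraction velocity (px/s) — peak instantaneous marker speed;
* force (px/s^2) — peak acceleration magnitude, an unit-mass
  instantaneous-force proxy;
* energy (px^2/s) — discrete kinetic-energy integral 0.5 * sum(v^2) dt
  over the recording;
* perimeter (px) — total path length traced by the marker, a proxy for
  ventricular compliance.

Derivatives use second-order central differences in the interior and
one-sided differences at the ends; trajectories are not smoothed before
differentiation, so noise sensitivity is inherited by design and
characterized in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .recording import TrajectoryRecording

__all__ = [
    "KinematicSummary",
    "PhaseSummary",
    "velocity_series",
    "summarize_kinematics",
    "aggregate_phase",
    "kinematics_table",
]

PARAMETER_NAMES = ("max_contraction_velocity", "force", "energy", "perimeter")


@dataclass(frozen=True)
class KinematicSummary:
    """The four kinematic parameters of one recording."""

    max_contraction_velocity: float  # px/s
    force: float  # px/s^2
    energy: float  # px^2/s
    perimeter: float  # px

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}


@dataclass(frozen=True)
class PhaseSummary:
    """Mean +- SEM of each kinematic parameter across one phase's videos."""

    mean: dict[str, float]
    sem: dict[str, float]
    n: int


def _check(recording: TrajectoryRecording) -> None:
    if recording.n_samples < 3:
        raise ValueError("kinematics requires at least 3 samples")


def velocity_series(recording: TrajectoryRecording) -> np.ndarray:
    """Instantaneous marker speed (px/s), one value per frame."""
    _check(recording)
    dt = 1.0 / recording.sampling_rate
    vx = np.gradient(recording.x, dt)
    vy = np.gradient(recording.y, dt)
    return np.hypot(vx, vy)


def summarize_kinematics(recording: TrajectoryRecording) -> KinematicSummary:
    """Compute the four kinematic parameters for one recording."""
    _check(recording)
    dt = 1.0 / recording.sampling_rate
    vx = np.gradient(recording.x, dt)
    vy = np.gradient(recording.y, dt)
    speed = np.hypot(vx, vy)
    ax = np.gradient(vx, dt)
    ay = np.gradient(vy, dt)
    return KinematicSummary(
        max_contraction_velocity=float(speed.max()),
        force=float(np.hypot(ax, ay).max()),
        energy=float(0.5 * np.sum(speed**2) * dt),
        perimeter=float(np.sum(np.hypot(np.diff(recording.x), np.diff(recording.y)))),
    )


def aggregate_phase(summaries: list[KinematicSummary]) -> PhaseSummary:
    """Mean +- SEM per parameter across a phase's recordings.

    SEM is the sample standard deviation (ddof=1) over sqrt(n); it is 0
    when a single recording is supplied.
    """
    if len(summaries) == 0:
        raise ValueError("aggregate_phase requires at least one summary")
    n = len(summaries)
    mean, sem = {}, {}
    for name in PARAMETER_NAMES:
        values = np.array([getattr(s, name) for s in summaries], dtype=float)
        mean[name] = float(values.mean())
        sem[name] = 0.0 if n == 1 else float(values.std(ddof=1) / math.sqrt(n))
    return PhaseSummary(mean=mean, sem=sem, n=n)


def kinematics_table(recordings: list[TrajectoryRecording]):
    """Per-recording kinematics as a pandas DataFrame (one row per video)."""
    import pandas as pd

    rows = []
    for rec in recordings:
        row = {"patient_id": rec.patient_id, "phase": rec.phase, "recording_id": rec.recording_id}
        row.update(summarize_kinematics(rec).as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
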