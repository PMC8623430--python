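"""Synthetic cohort generator for epicardial marker trajectories.

The generator stands in for intraoperative video recordings of the
exposed beating heart: each trace is a near-periodic, sinusoidal-like
motion at the heart-rate fundamental with a few decaying harmonics,
plus additive white pixel noise from tracking jitter and respiratory /
measurement disturbance.

Class structure
---------------
Two class profiles are provided.  The *unhealthy* (before-surgery)
profile has larger motion amplitudes and substantially larger noise
than the *healthy* (after-surgery) profile, so that

* kinematic energy and perimeter decrease after surgery, and
* the spectral signal-to-noise ratio of the motion is lower before
  surgery than after, with non-overlapping per-class SNR ranges.

The amplitude/noise contrast (not the absolute pixel values) is the
modelled quantity; the direction of the SNR contrast is configurable
because real intraoperative SNR values are not published.

Seeding
-------
One master seed drives everything.  Per-recording random streams are
derived with a documented counter scheme,
``SeedSequence([master, patient_index, phase_index, video_index])``,
so any single recording can be regenerated without generating the rest
of the cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .recording import TrajectoryRecording

__all__ = [
    "MotionModelParams",
    "ClassProfile",
    "CohortConfig",
    "HEALTHY_PROFILE",
    "UNHEALTHY_PROFILE",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_heldout_patient",
]

# Tags for deriving parameter-draw streams; arbitrary fixed primes keep
# them disjoint from the (patient, phase, video) recording streams.
_TAG_PATIENT = 999_979
_TAG_PHASE_PARAMS = 999_983


@dataclass(frozen=True)
class MotionModelParams:
    """Parameters of one harmonic-sum marker motion model.

    x(t) = baseline_x + drift_rate*t
           + sum_h amplitudes_x[h] * sin(2*pi*(h+1)*fundamental_freq*t + phases_x[h])
           + N(0, noise_sd^2)   (and likewise for y, independent noise)
    """

    fundamental_freq: float  # Hz; heart rate / 60
    amplitudes_x: tuple[float, ...]  # px per harmonic 1..H
    amplitudes_y: tuple[float, ...]
    phases_x: tuple[float, ...]  # rad per harmonic
    phases_y: tuple[float, ...]
    baseline_x: float = 0.0  # px
    baseline_y: float = 0.0
    drift_rate: float = 0.0  # px/s, linear drift on both axes
    noise_sd: float = 0.0  # px, additive white Gaussian per axis

    def __post_init__(self):
        if not self.fundamental_freq > 0:
            raise ValueError("fundamental_freq must be > 0")
        ax, ay = np.asarray(self.amplitudes_x), np.asarray(self.amplitudes_y)
        if ax.size < 1 or ay.size < 1:
            raise ValueError("at least one harmonic amplitude is required")
        if ax.size != len(self.phases_x) or ay.size != len(self.phases_y):
            raise ValueError("amplitudes and phases must have equal length")
        if (ax < 0).any() or (ay < 0).any():
            raise ValueError("amplitudes must be >= 0")
        if ax[0] <= 0 and ay[0] <= 0:
            raise ValueError("the first-harmonic amplitude must be > 0 on at least one axis")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def scaled(self, amplitude_factor: float = 1.0, noise_factor: float = 1.0) -> "MotionModelParams":
        """Return a copy with amplitudes and/or noise rescaled."""
        return dataclasses.replace(
            self,
            amplitudes_x=tuple(a * amplitude_factor for a in self.amplitudes_x),
            amplitudes_y=tuple(a * amplitude_factor for a in self.amplitudes_y),
            noise_sd=self.noise_sd * noise_factor,
        )


@dataclass(frozen=True)
class ClassProfile:
    """Distributions from which per-patient motion parameters are drawn."""

    label: str  # "unhealthy" or "healthy"
    amplitude_range: tuple[float, float]  # px, first harmonic, per axis
    noise_sd_range: tuple[float, float]  # px
    n_harmonics: int = 3
    harmonic_decay: float = 0.4  # geometric amplitude ratio between harmonics
    fundamental_range: tuple[float, float] = (1.0, 2.0)  # Hz, 60-120 bpm
    baseline_range: tuple[float, float] = (0.0, 0.0)  # px, marker rest offset
    drift_rate: float = 0.0  # px/s

    def draw_params(self, fundamental_freq: float, rng: np.random.Generator) -> MotionModelParams:
        """Draw one patient-phase parameter set at a given heart rate."""
        a1x = rng.uniform(*self.amplitude_range)
        a1y = rng.uniform(*self.amplitude_range)
        decay = self.harmonic_decay ** np.arange(self.n_harmonics)
        return MotionModelParams(
            fundamental_freq=fundamental_freq,
            amplitudes_x=tuple(a1x * decay),
            amplitudes_y=tuple(a1y * decay),
            phases_x=tuple(rng.uniform(0.0, 2.0 * np.pi, self.n_harmonics)),
            phases_y=tuple(rng.uniform(0.0, 2.0 * np.pi, self.n_harmonics)),
            baseline_x=rng.uniform(*self.baseline_range),
            baseline_y=rng.uniform(*self.baseline_range),
            drift_rate=self.drift_rate,
            noise_sd=rng.uniform(*self.noise_sd_range),
        )


# Default study conditions: the unhealthy (pre-surgery) ventricle moves
# with roughly twice the amplitude of the healthy one but with an order
# of magnitude more incoherent pixel noise, so energy/perimeter fall and
# SNR rises after a successful valve replacement.
UNHEALTHY_PROFILE = ClassProfile(label="unhealthy", amplitude_range=(5.0, 10.0), noise_sd_range=(0.5, 1.0))
HEALTHY_PROFILE = ClassProfile(label="healthy", amplitude_range=(2.5, 5.0), noise_sd_range=(0.04, 0.08))

#: Per-patient video counts (same in both phases) reproducing the study
#: totals for 12 patients: 7*4 + 5*3 = 43 videos per phase.
_DEFAULT_VIDEO_PATTERN = (4, 4, 4, 4, 4, 4, 4, 3, 3, 3, 3, 3)

#: Per-video multiplicative amplitude jitter (uniform range), modelling
#: contractility variation between takes of the same heart.
_VIDEO_JITTER = (0.9, 1.1)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a full synthetic training cohort."""

    n_patients: int = 12
    videos_per_phase: int | tuple[int, ...] | None = None  # None -> study pattern
    sampling_rate: float = 200.0  # Hz
    duration: float = 5.0  # s
    profiles: tuple[ClassProfile, ClassProfile] = (UNHEALTHY_PROFILE, HEALTHY_PROFILE)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be > 0")
        n = self.sampling_rate * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate * duration must be an integer sample count")
        labels = {p.label for p in self.profiles}
        if labels != {"unhealthy", "healthy"}:
            raise ValueError("profiles must contain one unhealthy and one healthy profile")
        for c in self.video_counts():
            if c < 1:
                raise ValueError("videos_per_phase must be >= 1")

    def video_counts(self) -> tuple[int, ...]:
        """Number of videos per phase for each patient."""
        v = self.videos_per_phase
        if v is None:
            return tuple(_DEFAULT_VIDEO_PATTERN[i % len(_DEFAULT_VIDEO_PATTERN)] for i in range(self.n_patients))
        if isinstance(v, int):
            return (v,) * self.n_patients
        v = tuple(int(c) for c in v)
        if len(v) != self.n_patients:
            raise ValueError("per-patient video counts must have length n_patients")
        return v

    def profile_for(self, label: str) -> ClassProfile:
        for p in self.profiles:
            if p.label == label:
                return p
        raise ValueError(f"no profile labelled {label!r}")


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(e) for e in entropy]))


def simulate_trajectory(
    params: MotionModelParams,
    sampling_rate: float,
    duration: float,
    seed,
    patient_id: str = "synthetic",
    phase: str = "unknown",
    recording_id: str = "",
) -> TrajectoryRecording:
    """Simulate one tracked marker trace from a harmonic motion model.

    ``seed`` may be an integer, a :class:`numpy.random.SeedSequence` or a
    :class:`numpy.random.Generator`.  The same seed always yields the
    identical recording.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(sampling_rate * duration))
    t = np.arange(n) / sampling_rate

    def axis(baseline, amplitudes, phases):
        s = baseline + params.drift_rate * t
        for h, (a, ph) in enumerate(zip(amplitudes, phases), start=1):
            s = s + a * np.sin(2.0 * np.pi * h * params.fundamental_freq * t + ph)
        if params.noise_sd > 0:
            s = s + rng.normal(0.0, params.noise_sd, n)
        return s

    x = axis(params.baseline_x, params.amplitudes_x, params.phases_x)
    y = axis(params.baseline_y, params.amplitudes_y, params.phases_y)
    return TrajectoryRecording(
        patient_id=patient_id,
        phase=phase,
        sampling_rate=sampling_rate,
        x=x,
        y=y,
        recording_id=recording_id,
        meta={"params": params, "seed": repr(seed)},
    )


def _phase_recordings(
    master_seed: int,
    patient_index: int,
    patient_id: str,
    phase: str,
    phase_index: int,
    params: MotionModelParams,
    n_videos: int,
    sampling_rate: float,
    duration: float,
) -> list[TrajectoryRecording]:
    """Generate one patient-phase video set with per-video jitter."""
    out = []
    for v in range(n_videos):
        rng = _rng(master_seed, patient_index, phase_index, v)
        jitter = rng.uniform(*_VIDEO_JITTER)
        rec = simulate_trajectory(
            params.scaled(amplitude_factor=jitter),
            sampling_rate,
            duration,
            rng,
            patient_id=patient_id,
            phase=phase,
            recording_id=f"{patient_id}-{phase}-{v}",
        )
        out.append(rec)
    return out


def simulate_cohort(config: CohortConfig | None = None) -> list[TrajectoryRecording]:
    """Simulate the training cohort: every patient recorded in both phases.

    Before-phase recordings are drawn from the unhealthy profile and
    after-phase recordings from the healthy profile.  The heart-rate
    fundamental of a patient is identical in both phases (anesthesia is
    administered once; the study reports equal heart rates across the
    two timepoints).
    """
    config = config or CohortConfig()
    counts = config.video_counts()
    unhealthy = config.profile_for("unhealthy")
    healthy = config.profile_for("healthy")
    recordings: list[TrajectoryRecording] = []
    for p in range(config.n_patients):
        patient_id = f"P{p + 1:02d}"
        f0 = _rng(config.seed, p, _TAG_PATIENT).uniform(*unhealthy.fundamental_range)
        for phase_index, (phase, profile) in enumerate((("before", unhealthy), ("after", healthy))):
            params = profile.draw_params(f0, _rng(config.seed, p, phase_index, _TAG_PHASE_PARAMS))
            recordings.extend(
                _phase_recordings(
                    config.seed, p, patient_id, phase, phase_index, params,
                    counts[p], config.sampling_rate, config.duration,
                )
            )
    return recordings


#: Amplitude/noise worsening applied to the unfavorable patient's
#: after-surgery phase relative to their own before-surgery parameters.
_UNFAVORABLE_AFTER_FACTOR = 1.5


def simulate_heldout_patient(
    outcome: str,
    seed: int,
    n_videos: int = 4,
    sampling_rate: float = 200.0,
    duration: float = 5.0,
    profiles: tuple[ClassProfile, ClassProfile] = (UNHEALTHY_PROFILE, HEALTHY_PROFILE),
) -> tuple[list[TrajectoryRecording], list[TrajectoryRecording]]:
    """Simulate one held-out patient's (before, after) recording sets.

    ``outcome="favorable"`` models a successful valve replacement: the
    before phase is drawn from the unhealthy profile and the after phase
    from the healthy profile, so kinematic energy and perimeter drop.

    ``outcome="unfavorable"`` models a heart that does not recover: both
    phases use the patient's unhealthy parameters, with the after phase
    worsened (amplitudes and noise scaled up), so every kinematic
    parameter shows an increasing trend and the spectral SNR stays in
    the unhealthy range.
    """
    if outcome not in ("favorable", "unfavorable"):
        raise ValueError(f"outcome must be 'favorable' or 'unfavorable', got {outcome!r}")
    unhealthy = next(p for p in profiles if p.label == "unhealthy")
    healthy = next(p for p in profiles if p.label == "healthy")
    patient_id = f"heldout-{outcome}"
    # Patient index 10^6 keeps held-out streams disjoint from cohort patients.
    pidx = 1_000_000 + (0 if outcome == "favorable" else 1)
    f0 = _rng(seed, pidx, _TAG_PATIENT).uniform(*unhealthy.fundamental_range)

    before_params = unhealthy.draw_params(f0, _rng(seed, pidx, 0, _TAG_PHASE_PARAMS))
    if outcome == "favorable":
        after_params = healthy.draw_params(f0, _rng(seed, pidx, 1, _TAG_PHASE_PARAMS))
    else:
        after_params = before_params.scaled(_UNFAVORABLE_AFTER_FACTOR, _UNFAVORABLE_AFTER_FACTOR)

    before = _phase_recordings(seed, pidx, patient_id, "before", 0, before_params, n_videos, sampling_rate, duration)
    after = _phase_recordings(seed, pidx, patient_id, "after", 1, after_params, n_videos, sampling_rate, duration)
    return before, after
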