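"""Container for one tracked epicardial marker trajectory.

A recording is the (x, y) pixel path of a single virtual marker on the
right-ventricle epicardium across video frames, together with the frame
rate and the clinical labelling (which patient, which surgical phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Surgical phase -> training class label.  Before pulmonary valve
#: replacement the heart is labelled unhealthy, after it healthy.
PHASE_TO_LABEL = {"before": "unhealthy", "after": "healthy"}

PHASES = ("before", "after", "unknown")
CLASS_LABELS = ("unhealthy", "healthy")


@dataclass
class TrajectoryRecording:
    """One tracked marker trace from a single high-frame-rate video.

    Parameters
    ----------
    patient_id : str
        Identifier of the patient the video belongs to.
    phase : {"before", "after", "unknown"}
        Surgical phase of the recording; "unknown" is allowed for
        not-yet-labelled (held-out) material.
    sampling_rate : float
        Video frame rate in Hz (frames per second).
    x, y : array-like
        Marker pixel coordinates per frame.  The image convention is
        kept as tracked (y grows downward); only differences and spectra
        are consumed downstream.
    recording_id : str, optional
        Identifier of the individual video.
    """

    patient_id: str
    phase: str
    sampling_rate: float
    x: np.ndarray
    y: np.ndarray
    recording_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be a positive, finite number")
        if self.x.ndim != 1 or self.y.ndim != 1:
            raise ValueError("x and y must be one-dimensional series")
        if self.x.size != self.y.size:
            raise ValueError("x and y must have equal length")
        if self.x.size < 2:
            raise ValueError("a recording needs at least 2 samples")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates contain missing or non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def label(self) -> str | None:
        """Class label implied by the surgical phase, or None if unknown."""
        return PHASE_TO_LABEL.get(self.phase)
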