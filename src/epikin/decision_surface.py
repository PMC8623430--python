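"""2D decision surfaces on the (SNR_x, SNR_y) plane.

A trained classifier is reduced to two representative features (the
per-axis signal-to-noise ratios by default), refit on that plane, and
used to (a) paint a class label onto every cell of a Cartesian grid —
the decision surface — and (b) classify the recordings of a held-out
patient, with a majority vote per surgical phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .errors import DegenerateSignalError
from .recording import TrajectoryRecording
from .spectral_features import extract_feature_vector

__all__ = ["SurfaceGrid", "DEFAULT_FEATURE_PAIR", "fit_2d", "build_surface", "classify_patient"]

DEFAULT_FEATURE_PAIR = ("snr_x", "snr_y")


@dataclass
class SurfaceGrid:
    """A classified grid over a 2D feature plane.

    ``labels[i, j]`` is the predicted class at cell center
    (``x_centers[j]``, ``y_centers[i]``).
    """

    feature_pair: tuple[str, str]
    x_centers: np.ndarray
    y_centers: np.ndarray
    labels: np.ndarray  # (resolution, resolution) object array of class labels
    bounds: tuple[tuple[float, float], tuple[float, float]]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table: one row per cell (x, y, label)."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return pd.DataFrame(
            {
                self.feature_pair[0]: xx.ravel(),
                self.feature_pair[1]: yy.ravel(),
                "label": self.labels.ravel(),
            }
        )


def fit_2d(estimator, features: pd.DataFrame, labels, pair=DEFAULT_FEATURE_PAIR):
    """Fit a (clone of a) classifier on a two-feature restriction.

    ``features`` may be a full feature table (the pair's columns are
    selected) or an (n, 2) matrix already in pair order.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in pair if c not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks the chosen pair columns: {missing}")
        X2 = features.loc[:, list(pair)].to_numpy(dtype=float)
    else:
        X2 = np.asarray(features, dtype=float)
        if X2.ndim != 2 or X2.shape[1] != 2:
            raise ValueError("expected an (n, 2) feature matrix")
    model = clone(estimator).fit(X2, np.asarray(labels, dtype=object))
    model.feature_pair_ = tuple(pair)
    model.training_bounds_ = ((X2[:, 0].min(), X2[:, 0].max()), (X2[:, 1].min(), X2[:, 1].max()))
    return model


def _default_bounds(model) -> tuple[tuple[float, float], tuple[float, float]]:
    out = []
    for lo, hi in model.training_bounds_:
        margin = 0.1 * (hi - lo) if hi > lo else max(0.1 * abs(hi), 1.0)
        out.append((lo - margin, hi + margin))
    return tuple(out)


def build_surface(model, bounds=None, resolution: int = 200) -> SurfaceGrid:
    """Classify every cell center of a resolution x resolution grid.

    ``bounds`` defaults to the training min/max per axis with a 10%
    margin, which covers all training points by construction.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if model.n_features_in_ != 2:
        raise ValueError("build_surface requires a 2D-fitted model")
    if bounds is None:
        bounds = _default_bounds(model)
    (x_lo, x_hi), (y_lo, y_hi) = bounds

    def centers(lo, hi):
        edges = np.linspace(lo, hi, resolution + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    x_centers, y_centers = centers(x_lo, x_hi), centers(y_lo, y_hi)
    xx, yy = np.meshgrid(x_centers, y_centers)
    labels = model.predict(np.column_stack([xx.ravel(), yy.ravel()]))
    pair = getattr(model, "feature_pair_", DEFAULT_FEATURE_PAIR)
    return SurfaceGrid(
        feature_pair=tuple(pair),
        x_centers=x_centers,
        y_centers=y_centers,
        labels=np.asarray(labels, dtype=object).reshape(resolution, resolution),
        bounds=((float(x_lo), float(x_hi)), (float(y_lo), float(y_hi))),
    )


def classify_patient(
    model, recordings: list[TrajectoryRecording], pair=None
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Classify a patient's recordings on the 2D feature plane.

    Each recording is featurized, projected onto the model's feature
    pair and predicted.  Returns a per-recording table (coordinates,
    phase, predicted label) and the majority label per phase; tied votes
    resolve to "unhealthy".  Recordings whose features are degenerate
    are flagged (label None) and excluded from the majority, with a
    warning.
    """
    if not recordings:
        raise ValueError("classify_patient requires at least one recording")
    pair = tuple(pair or getattr(model, "feature_pair_", DEFAULT_FEATURE_PAIR))
    rows = []
    for rec in recordings:
        row = {"patient_id": rec.patient_id, "recording_id": rec.recording_id, "phase": rec.phase}
        try:
            feats = extract_feature_vector(rec)
        except DegenerateSignalError as err:
            warnings.warn(f"excluding degenerate recording from majority vote: {err}", RuntimeWarning)
            row.update({pair[0]: np.nan, pair[1]: np.nan, "predicted": None})
            rows.append(row)
            continue
        point = feats[list(pair)].to_numpy(dtype=float)[None, :]
        row.update({pair[0]: point[0, 0], pair[1]: point[0, 1],
                    "predicted": str(model.predict(point)[0])})
        rows.append(row)
    calls = pd.DataFrame(rows)

    majority: dict[str, str] = {}
    for phase, grp in calls.dropna(subset=["predicted"]).groupby("phase"):
        healthy = int((grp["predicted"] == "healthy").sum())
        unhealthy = int((grp["predicted"] == "unhealthy").sum())
        majority[str(phase)] = "healthy" if healthy > unhealthy else "unhealthy"
    return calls, majority
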