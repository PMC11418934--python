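"""Session-level glue: features across streams, label series, occupancy grids."""

from __future__ import annotations

import numpy as np

from .ethogram import BehavioralSegment
from .imu import FeatureSet, compute_features
from .io import ImuSession, PoseTrack, nearest_preceding_index
from .pose import axial_bending_angle, interpolate_low_likelihood


def session_features(
    imu: ImuSession,
    pose: PoseTrack | None = None,
    min_likelihood: float = 0.6,
    **imu_kwargs,
) -> FeatureSet:
    """All four clustering features on the IMU clock.

    Inertial features come from the IMU pipeline; the axial bending angle is
    computed per video frame and mapped to the IMU clock by nearest-preceding
    frame (zero-order hold).
    """
    feats = compute_features(imu, **imu_kwargs)
    if pose is not None:
        clean = interpolate_low_likelihood(pose, min_likelihood)
        theta = axial_bending_angle(clean)
        idx = nearest_preceding_index(feats.times, pose.frame_times)
        feats.theta_axial = theta[idx]
    return feats


def segment_label_series(
    segments: list[BehavioralSegment], assignments: np.ndarray, n_samples: int
) -> np.ndarray:
    """Per-sample cluster id from the segment tiling (-1 where uncovered)."""
    labels = np.full(n_samples, -1, dtype=int)
    for seg, c in zip(segments, assignments):
        labels[seg.start_idx : seg.end_idx] = int(c)
    return labels


def occupancy_seconds(labels: np.ndarray, rate: float) -> dict:
    """Seconds spent in each cluster id."""
    vals, counts = np.unique(labels[labels >= 0], return_counts=True)
    return {int(v): float(c / rate) for v, c in zip(vals, counts)}


def binarize_on_grid(
    values: np.ndarray, rate: float, targets, bin_s: float = 0.05
) -> np.ndarray:
    """Binary occupancy of ``targets`` on a coarse time grid.

    A grid bin is occupied when the majority of its samples carry a target
    value; used as the common timebase for cluster-annotation correlations.
    """
    values = np.asarray(values)
    hit = np.isin(values, np.asarray(list(np.atleast_1d(targets)))).astype(float)
    step = max(1, int(round(bin_s * rate)))
    n_bins = hit.size // step
    trimmed = hit[: n_bins * step].reshape(n_bins, step)
    return (trimmed.mean(axis=1) > 0.5).astype(float)
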