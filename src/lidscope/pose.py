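"""Axial bending angle from tracked keypoints.

The axial bending angle (theta_axial) is the unsigned angle at the midpoint
between the two hindlimbs (mid_HL) between the vector to the nose and the
vector to the tail base:

    cos(theta) = (v_nose . v_tail) / (|v_nose| |v_tail|)

A flat posture gives ~180 deg; strong axial torsion (dystonic bending)
pushes it toward small angles. Lateralization is carried by the head
rotation feature, not here, so the angle is unsigned. Keypoint frames whose
tracking likelihood falls below 0.6 are linearly interpolated from flanking
good frames before the geometry is evaluated.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import BODYPARTS_AXIAL, PoseTrack

DEFAULT_MIN_LIKELIHOOD = 0.6


def interpolate_low_likelihood(
    track: PoseTrack, min_likelihood: float = DEFAULT_MIN_LIKELIHOOD
) -> PoseTrack:
    """Linearly interpolate keypoints across low-likelihood frames.

    Frames with likelihood < ``min_likelihood`` are replaced by linear
    interpolation between the nearest flanking good frames; leading/trailing
    bad frames are held at the nearest good value. A bodypart with no good
    frame at all is rejected.
    """
    t = track.frame_times
    keypoints, likelihood = {}, {}
    for part in track.bodyparts:
        lik = track.likelihood[part]
        good = lik >= min_likelihood
        if not good.any():
            raise ValueError(f"bodypart {part!r} has no frame above likelihood threshold")
        xy = track.keypoints[part].copy()
        for c in range(2):
            xy[~good, c] = np.interp(t[~good], t[good], xy[good, c])
        keypoints[part] = xy
        likelihood[part] = lik
    return replace(track, keypoints=keypoints, likelihood=likelihood)


def axial_bending_angle(
    track: PoseTrack, fill_gaps: bool = True
) -> np.ndarray:
    """Per-frame axial bending angle in degrees.

    Degenerate frames (nose or tail base coincident with the hindlimb
    midpoint) are gaps; with ``fill_gaps`` they inherit the previous valid
    value (zero-order hold, matching the stream-alignment convention),
    otherwise they are NaN.
    """
    missing = [p for p in BODYPARTS_AXIAL if p not in track.bodyparts]
    if missing:
        raise ValueError(f"missing bodyparts for axial angle: {missing}")
    nose = track.keypoints["nose"]
    tail = track.keypoints["tail_base"]
    mid_hl = 0.5 * (track.keypoints["left_hindlimb"] + track.keypoints["right_hindlimb"])
    v_nose = nose - mid_hl
    v_tail = tail - mid_hl
    norm_n = np.linalg.norm(v_nose, axis=1)
    norm_t = np.linalg.norm(v_tail, axis=1)
    scale = max(norm_n.max(), norm_t.max(), 1.0)
    degenerate = (norm_n < 1e-9 * scale) | (norm_t < 1e-9 * scale)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.sum(v_nose * v_tail, axis=1) / (norm_n * norm_t)
    theta = np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0)))
    theta[degenerate] = np.nan
    if fill_gaps and degenerate.any():
        idx = np.arange(theta.size)
        valid = ~np.isnan(theta)
        if valid.any():
            last = np.maximum.accumulate(np.where(valid, idx, -1))
            first_valid = idx[valid][0]
            last[last < 0] = first_valid  # leading gaps take first valid value
            theta = theta[last]
    return theta


def semiautomatic_track_fill(
    keyframe_indices: np.ndarray,
    keyframe_points: dict,
    n_frames: int,
    fps: float,
) -> PoseTrack:
    """Densify sparse keyframe annotations of the 4 axial bodyparts.

    Emulates the semi-automatic workflow where bodyparts are annotated every
    5-20 frames and linearly interpolated to full frame rate. Likelihood is
    1 at keyframes, 0.99 between (so nothing is re-interpolated downstream).
    """
    keyframe_indices = np.asarray(keyframe_indices, dtype=int)
    if keyframe_indices.size < 2:
        raise ValueError("need at least 2 keyframes")
    missing = [p for p in BODYPARTS_AXIAL if p not in keyframe_points]
    if missing:
        raise ValueError(f"missing bodyparts in keyframes: {missing}")
    frames = np.arange(n_frames)
    keypoints, likelihood = {}, {}
    for part in BODYPARTS_AXIAL:
        pts = np.asarray(keyframe_points[part], dtype=float)
        if pts.shape != (keyframe_indices.size, 2):
            raise ValueError(f"keyframe_points[{part}] must be (n_keyframes, 2)")
        xy = np.column_stack(
            [np.interp(frames, keyframe_indices, pts[:, c]) for c in range(2)]
        )
        lik = np.full(n_frames, 0.99)
        lik[keyframe_indices[keyframe_indices < n_frames]] = 1.0
        keypoints[part] = xy
        likelihood[part] = lik
    return PoseTrack(
        frame_times=frames / fps,
        keypoints=keypoints,
        likelihood=likelihood,
        fps=fps,
        axial_only=True,
    )
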