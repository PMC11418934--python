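"""Inertial features: body acceleration, gravitational acceleration, head rotation.

The raw 6-channel inertial signal is denoised (median filter then Gaussian
smoothing), split into a slow gravitational component GA (per-axis low-pass,
0.5 Hz first-order Butterworth applied forward-backward) and a dynamic body
acceleration BA = filtered accel - GA, with total BA the Euclidean norm of
the three axis components. Head rotations are cumulative-angle events taken
from the dorsoventral gyroscope channel: contiguous supra-threshold runs of
constant sign, each carrying the time-integral of angular velocity (negative
= contralateral/left). A movement mask thresholds total BA at 0.05 g, the
valley of the bimodal distribution of ln(BA) seen in open-field recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d, median_filter
from scipy.stats import gaussian_kde

from .io import ImuSession

#: movement threshold on total body acceleration, g (ln 0.05 = -3 log units)
DEFAULT_MOVEMENT_THRESHOLD_G = 0.05
#: minimum angular speed that counts toward a head-rotation event, deg/s
DEFAULT_MIN_ROTATION_RATE = 10.0
GA_CUTOFF_HZ = 0.5


@dataclass
class FeatureSet:
    """Aligned per-sample clustering features on the IMU clock.

    ``theta_axial`` is filled by the pose pipeline; it stays NaN for
    IMU-only sessions.
    """

    times: np.ndarray
    ba: np.ndarray  # total body acceleration, g
    ba_axes: np.ndarray  # (n, 3) per-axis BA
    ga_axes: np.ndarray  # (n, 3) per-axis gravitational acceleration
    theta_head: np.ndarray  # deg, signed; 0 outside rotation events
    theta_axial: np.ndarray  # deg in (0, 180]; NaN if no pose stream
    rate: float

    @property
    def ga_ap(self) -> np.ndarray:
        return self.ga_axes[:, 0]

    def as_matrix(self) -> np.ndarray:
        """(n, 4) feature matrix in canonical order BA, GA_AP, theta_head, theta_axial."""
        return np.column_stack([self.ba, self.ga_ap, self.theta_head, self.theta_axial])


@dataclass
class MovementMask:
    moving: np.ndarray  # bool per sample
    threshold: float  # g
    rate: float

    @property
    def percent_moving(self) -> float:
        return 100.0 * float(np.mean(self.moving))


def preprocess_inertial(
    session: ImuSession, median_order: int = 7, gauss_sigma: float = 0.025
) -> tuple[np.ndarray, np.ndarray]:
    """Denoise the 6 inertial channels.

    Per-channel median filter of order ``median_order`` followed by Gaussian
    smoothing with standard deviation ``gauss_sigma`` seconds (reflect edge
    policy; output length equals input length).
    """
    n = session.timestamps.size
    if n < median_order:
        raise ValueError(f"need at least {median_order} samples, got {n}")
    sigma_samples = gauss_sigma * session.rate

    def _denoise(x: np.ndarray) -> np.ndarray:
        out = median_filter(x, size=median_order, mode="reflect", axes=0)
        if sigma_samples > 0:
            out = gaussian_filter1d(out, sigma_samples, axis=0, mode="reflect")
        return out

    return _denoise(session.accel), _denoise(session.gyro)


def gravitational_acceleration(
    filtered_accel: np.ndarray,
    rate: float,
    cutoff_hz: float = GA_CUTOFF_HZ,
    median_order: int = 7,
) -> np.ndarray:
    """Slow (postural) component of acceleration, per axis.

    Median filter then first-order low-pass Butterworth at ``cutoff_hz``
    applied zero-phase (forward-backward), so the effective magnitude
    response is the squared first-order response.
    """
    if rate < 2 * cutoff_hz:
        raise ValueError(f"sampling rate {rate} Hz below 2x cutoff {cutoff_hz} Hz")
    x = median_filter(filtered_accel, size=median_order, mode="reflect", axes=0)
    b, a = signal.butter(1, cutoff_hz, btype="low", fs=rate)
    return signal.filtfilt(b, a, x, axis=0)


def body_acceleration(
    filtered_accel: np.ndarray, ga: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dynamic component: per-axis BA = filtered accel - GA; total BA = |BA|."""
    if filtered_accel.shape != ga.shape:
        raise ValueError("filtered accel and GA length mismatch")
    ba_axes = filtered_accel - ga
    ba = np.sqrt(np.sum(ba_axes**2, axis=1))
    return ba_axes, ba


def head_rotation_angle(
    gyro_dv: np.ndarray,
    rate: float,
    min_rate: float = DEFAULT_MIN_ROTATION_RATE,
) -> tuple[np.ndarray, list]:
    """Cumulative head-rotation angle per rotation event.

    A rotation event is a contiguous run where |angular velocity| >= min_rate
    with constant sign (events break at zero crossings, so a left-right
    wiggle yields two events). Every sample in an event carries the event's
    total angle (trapezoidal time-integral of angular velocity, deg);
    samples outside events carry 0. Positive = ipsilateral/right, negative =
    contralateral/left.

    Returns the per-sample angle series and a list of
    ``(start_idx, end_idx_exclusive, total_angle_deg)`` events.
    """
    gyro_dv = np.asarray(gyro_dv, dtype=float)
    active = np.abs(gyro_dv) >= min_rate
    sign = np.sign(gyro_dv)
    theta = np.zeros_like(gyro_dv)
    events = []
    i, n = 0, gyro_dv.size
    while i < n:
        if not active[i]:
            i += 1
            continue
        j = i
        while j < n and active[j] and sign[j] == sign[i]:
            j += 1
        seg = gyro_dv[i:j]
        if seg.size == 1:
            angle = seg[0] / rate
        else:
            angle = np.trapezoid(seg, dx=1.0 / rate)
        theta[i:j] = angle
        events.append((i, j, float(angle)))
        i = j
    return theta, events


def movement_mask(
    ba: np.ndarray,
    rate: float,
    threshold: float = DEFAULT_MOVEMENT_THRESHOLD_G,
) -> tuple[MovementMask, dict]:
    """Threshold total BA into a moving/resting mask plus session summary."""
    moving = np.asarray(ba) >= threshold
    summary = {
        "percent_moving": 100.0 * float(np.mean(moving)),
        "mean_ba_moving": float(np.mean(ba[moving])) if moving.any() else float("nan"),
    }
    return MovementMask(moving=moving, threshold=threshold, rate=rate), summary


def estimate_bimodal_threshold(
    ba: np.ndarray,
    rate: float | None = None,
    fallback: float = DEFAULT_MOVEMENT_THRESHOLD_G,
    min_duration: float = 60.0,
) -> float:
    """Movement threshold from the valley of the bimodal ln(BA) distribution.

    A Gaussian KDE of ln(BA) is evaluated on a grid; the threshold is the
    density minimum between the two largest modes. Falls back to ``fallback``
    (0.05 g) with a warning when the distribution is unimodal.
    """
    ba = np.asarray(ba, dtype=float)
    if rate is not None and ba.size / rate < min_duration:
        raise ValueError("session too short for threshold estimation")
    log_ba = np.log(ba[ba > 0])
    grid = np.linspace(np.percentile(log_ba, 0.5), np.percentile(log_ba, 99.5), 512)
    dens = gaussian_kde(log_ba)(grid)
    peaks, props = signal.find_peaks(dens, prominence=0.01 * dens.max())
    if peaks.size < 2:
        warnings.warn("ln(BA) distribution unimodal; using fallback threshold")
        return fallback
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = np.sort(top2)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(np.exp(grid[valley]))


def compute_features(
    session: ImuSession,
    median_order: int = 7,
    gauss_sigma: float = 0.025,
    min_rotation_rate: float = DEFAULT_MIN_ROTATION_RATE,
) -> FeatureSet:
    """Full inertial pipeline: denoise, GA/BA split, head-rotation angle."""
    accel_f, gyro_f = preprocess_inertial(session, median_order, gauss_sigma)
    ga = gravitational_acceleration(accel_f, session.rate, median_order=median_order)
    ba_axes, ba = body_acceleration(accel_f, ga)
    theta_head, _ = head_rotation_angle(gyro_f[:, 2], session.rate, min_rotation_rate)
    return FeatureSet(
        times=session.timestamps,
        ba=ba,
        ba_axes=ba_axes,
        ga_axes=ga,
        theta_head=theta_head,
        theta_axial=np.full(ba.shape, np.nan),
        rate=session.rate,
    )
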