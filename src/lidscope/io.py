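"""Reading, validation and time alignment of the recording streams.

A session combines up to four independently clocked streams: a head-mounted
6-axis inertial sensor (~200 Hz), video keypoint tracking (~30-40 fps),
frame-wise dyskinesia annotations, and per-neuron calcium traces (~20 fps).
Everything downstream operates on a single master clock, which is the IMU
clock (the highest-rate stream); lower-rate streams are mapped onto it by
nearest-preceding sample (zero-order hold), never by extrapolation.

Units: time in seconds, acceleration in g, angular velocity in deg/s,
keypoints in pixels, calcium footprint centroids in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
import yaml

IMU_COLUMNS = ("time", "acc_ap", "acc_ml", "acc_dv", "gyro_ap", "gyro_ml", "gyro_dv")

#: canonical bodypart names of the full tracking set
BODYPARTS_FULL = (
    "nose",
    "tail_base",
    "tail_tip",
    "left_hindlimb",
    "right_hindlimb",
    "left_forelimb",
    "right_forelimb",
    "antenna_base",
    "antenna_tip",
)
#: minimal set needed for the axial bending angle
BODYPARTS_AXIAL = ("nose", "tail_base", "left_hindlimb", "right_hindlimb")

ANNOTATION_LABELS = ("axial", "limb")
#: combination labels derived from overlapping axial/limb intervals
COMBINATION_LABELS = ("axial_alone", "limb_alone", "axial_limb")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ImuSession:
    """Raw 6-axis inertial recording on its native clock.

    ``accel``/``gyro`` are (n, 3) arrays with columns in AP, ML, DV order
    (head-referenced axes). ``axis_map`` records the orientation correction
    that has been applied, so a mis-mounted sensor is traceable.
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    rate: float
    axis_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("non-monotonic timestamps")
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.shape != (self.timestamps.size, 3):
                raise ValueError(f"{name} must be (n_samples, 3)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class PoseTrack:
    """Per-frame keypoint coordinates with tracking likelihoods."""

    frame_times: np.ndarray
    keypoints: dict  # bodypart -> (n_frames, 2) xy in px
    likelihood: dict  # bodypart -> (n_frames,) in [0, 1]
    fps: float
    axial_only: bool = False

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        for part in self.keypoints:
            xy = np.asarray(self.keypoints[part], dtype=float)
            lik = np.asarray(self.likelihood[part], dtype=float)
            if xy.shape != (self.frame_times.size, 2):
                raise ValueError(f"keypoints[{part}] must be (n_frames, 2)")
            if lik.shape != (self.frame_times.size,):
                raise ValueError(f"likelihood[{part}] must be (n_frames,)")
            if np.any((lik < 0) | (lik > 1)):
                raise ValueError("likelihood out of range")
            self.keypoints[part] = xy
            self.likelihood[part] = lik

    @property
    def bodyparts(self) -> tuple:
        return tuple(self.keypoints)


@dataclass
class AnnotationTrack:
    """Dyskinesia annotation intervals plus their combination partition.

    ``intervals`` holds the raw (start, end, label) entries with label in
    {axial, limb}. ``combination_intervals`` partitions annotated time into
    axial_alone / limb_alone / axial_limb (overlap of the two raw labels).
    """

    intervals: list  # of (start, end, label)
    combination_intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if end < start:
                raise ValueError(f"interval end {end} before start {start}")
            if label not in ANNOTATION_LABELS:
                raise ValueError(f"unknown annotation label {label!r}")
        if not self.combination_intervals:
            self.combination_intervals = _combine_intervals(self.intervals)

    def frame_labels(self, times: np.ndarray) -> np.ndarray:
        """Label each query time; unannotated time is the explicit 'none'."""
        times = np.asarray(times, dtype=float)
        out = np.full(times.size, "none", dtype=object)
        for start, end, label in self.combination_intervals:
            out[(times >= start) & (times < end)] = label
        return out

    def total_annotated(self) -> float:
        return float(sum(e - s for s, e, _ in self.combination_intervals))


@dataclass
class CalciumSession:
    """Per-neuron raw fluorescence traces with footprint centroids."""

    frame_times: np.ndarray
    traces: np.ndarray  # (n_neurons, n_frames) C_raw
    centroids_um: np.ndarray  # (n_neurons, 2)
    event_trains: list | None = None  # per-neuron event times (s)
    neuron_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        self.centroids_um = np.asarray(self.centroids_um, dtype=float)
        n = self.traces.shape[0]
        if self.traces.shape[1] != self.frame_times.size:
            raise ValueError("traces and frame_times length mismatch")
        if self.centroids_um.shape != (n, 2):
            raise ValueError("centroids must be (n_neurons, 2)")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(n)
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def fps(self) -> float:
        return 1.0 / float(np.median(np.diff(self.frame_times)))


@dataclass
class AlignedSession:
    """All streams resampled onto the IMU master clock.

    ``pose_index`` / ``calcium_index`` map each master sample to the index of
    the most recent native frame of the respective stream; ``provenance``
    records each stream's native rate.
    """

    times: np.ndarray
    imu: ImuSession
    pose: PoseTrack | None = None
    annotations: AnnotationTrack | None = None
    calcium: CalciumSession | None = None
    pose_index: np.ndarray | None = None
    calcium_index: np.ndarray | None = None
    annotation_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def _combine_intervals(intervals: list) -> list:
    """Partition annotated time into axial_alone/limb_alone/axial_limb."""
    if not intervals:
        return []
    edges = sorted({t for s, e, _ in intervals for t in (s, e)})
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (lo + hi)
        has = {lab for s, e, lab in intervals if s <= mid < e}
        if has == {"axial"}:
            lab = "axial_alone"
        elif has == {"limb"}:
            lab = "limb_alone"
        elif has == {"axial", "limb"}:
            lab = "axial_limb"
        else:
            continue
        # merge with previous piece when contiguous and same label
        if out and out[-1][1] == lo and out[-1][2] == lab:
            out[-1] = (out[-1][0], hi, lab)
        else:
            out.append((lo, hi, lab))
    return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _apply_axis_map(arr: np.ndarray, axis_map: dict | None) -> np.ndarray:
    """Permute/sign-flip AP, ML, DV columns per an orientation spec.

    ``axis_map`` maps target axis -> source spec, e.g. ``{"ap": "-ml"}``
    means the corrected AP channel is the negated recorded ML channel.
    """
    if not axis_map:
        return arr
    order = {"ap": 0, "ml": 1, "dv": 2}
    out = arr.copy()
    for target, source in axis_map.items():
        sign = 1.0
        src = source.lower().strip()
        if src.startswith(("+", "-")):
            sign = -1.0 if src[0] == "-" else 1.0
            src = src[1:]
        out[:, order[target.lower()]] = sign * arr[:, order[src]]
    return out


def read_imu(path, axis_map: dict | None = None) -> ImuSession:
    """Read a 6-channel IMU CSV (header ``time,acc_*,gyro_*``)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing channel(s): {missing}")
    t = df["time"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotonic timestamps")
    accel = _apply_axis_map(df[["acc_ap", "acc_ml", "acc_dv"]].to_numpy(float), axis_map)
    gyro = _apply_axis_map(df[["gyro_ap", "gyro_ml", "gyro_dv"]].to_numpy(float), axis_map)
    rate = 1.0 / float(np.median(np.diff(t)))
    return ImuSession(t, accel, gyro, rate=rate, axis_map=dict(axis_map or {}))


def write_imu(path, session: ImuSession) -> None:
    df = pd.DataFrame(
        np.column_stack([session.timestamps, session.accel, session.gyro]),
        columns=list(IMU_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_pose(path) -> PoseTrack:
    """Read a keypoint CSV with ``<part>_x,<part>_y,<part>_likelihood`` triplets."""
    df = pd.read_csv(path, float_precision="round_trip")
    parts = []
    for col in df.columns:
        if col.endswith("_x"):
            parts.append(col[:-2])
    known = set(BODYPARTS_FULL)
    unknown = [p for p in parts if p not in known]
    if unknown:
        raise ValueError(f"unknown bodypart names: {unknown}")
    t = df["time"].to_numpy(float) if "time" in df.columns else None
    keypoints, likelihood = {}, {}
    for p in parts:
        keypoints[p] = df[[f"{p}_x", f"{p}_y"]].to_numpy(float)
        likelihood[p] = df[f"{p}_likelihood"].to_numpy(float)
    n = len(df)
    if t is None:
        t = np.arange(n) / 40.0
    fps = 1.0 / float(np.median(np.diff(t)))
    axial_only = set(parts) == set(BODYPARTS_AXIAL)
    return PoseTrack(t, keypoints, likelihood, fps=fps, axial_only=axial_only)


def write_pose(path, track: PoseTrack) -> None:
    data = {"time": track.frame_times}
    for p in track.bodyparts:
        data[f"{p}_x"] = track.keypoints[p][:, 0]
        data[f"{p}_y"] = track.keypoints[p][:, 1]
        data[f"{p}_likelihood"] = track.likelihood[p]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_annotations(path) -> AnnotationTrack:
    """Read annotation intervals CSV ``start,end,label``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return AnnotationTrack(intervals=[])
    intervals = [
        (float(r.start), float(r.end), str(r.label)) for r in df.itertuples(index=False)
    ]
    return AnnotationTrack(intervals=intervals)


def write_annotations(path, track: AnnotationTrack) -> None:
    pd.DataFrame(track.intervals, columns=["start", "end", "label"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_calcium(path) -> CalciumSession:
    """Read a calcium session from HDF5 (``frame_times``, ``C_raw``, ``centroids_um``)."""
    with h5py.File(path, "r") as f:
        frame_times = f["frame_times"][()]
        traces = f["C_raw"][()]
        centroids = f["centroids_um"][()]
        events = None
        if "events" in f:
            grp = f["events"]
            events = [grp[str(i)][()] for i in range(len(grp))]
        ids = f["neuron_ids"][()] if "neuron_ids" in f else None
    return CalciumSession(frame_times, traces, centroids, event_trains=events, neuron_ids=ids)


def write_calcium(path, session: CalciumSession) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frame_times", data=session.frame_times)
        f.create_dataset("C_raw", data=session.traces)
        f.create_dataset("centroids_um", data=session.centroids_um)
        f.create_dataset("neuron_ids", data=session.neuron_ids)
        if session.event_trains is not None:
            grp = f.create_group("events")
            for i, ev in enumerate(session.event_trains):
                grp.create_dataset(str(i), data=np.asarray(ev, dtype=float))


def load_config(path) -> dict:
    """Load the YAML analysis configuration (thresholds and parameters)."""
    with open(path) as f:
        return yaml.safe_load(f) or {}


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def nearest_preceding_index(master: np.ndarray, native: np.ndarray) -> np.ndarray:
    """Index of the most recent native sample at or before each master time."""
    idx = np.searchsorted(native, master, side="right") - 1
    return np.clip(idx, 0, native.size - 1)


def align_streams(
    imu: ImuSession,
    pose: PoseTrack | None = None,
    annotations: AnnotationTrack | None = None,
    calcium: CalciumSession | None = None,
) -> AlignedSession:
    """Align all streams on the IMU clock over their common time interval.

    Raises ``ValueError`` if the streams share no overlap. Lower-rate streams
    are mapped by nearest-preceding sample; no stream is extrapolated beyond
    its native bounds.
    """
    t0 = imu.timestamps[0]
    t1 = imu.timestamps[-1]
    provenance = {"imu": imu.rate}
    if pose is not None:
        t0 = max(t0, pose.frame_times[0])
        t1 = min(t1, pose.frame_times[-1])
        provenance["pose"] = pose.fps
    if calcium is not None:
        t0 = max(t0, calcium.frame_times[0])
        t1 = min(t1, calcium.frame_times[-1])
        provenance["calcium"] = calcium.fps
    if t1 <= t0:
        raise ValueError("streams have empty temporal overlap")

    keep = (imu.timestamps >= t0) & (imu.timestamps <= t1)
    times = imu.timestamps[keep]
    imu_cut = replace(imu, timestamps=times, accel=imu.accel[keep], gyro=imu.gyro[keep])

    pose_index = calcium_index = labels = None
    if pose is not None:
        pose_index = nearest_preceding_index(times, pose.frame_times)
    if calcium is not None:
        calcium_index = nearest_preceding_index(times, calcium.frame_times)
    if annotations is not None:
        labels = annotations.frame_labels(times)

    return AlignedSession(
        times=times,
        imu=imu_cut,
        pose=pose,
        annotations=annotations,
        calcium=calcium,
        pose_index=pose_index,
        calcium_index=calcium_index,
        annotation_labels=labels,
        provenance=provenance,
    )
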