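"""Seeded synthetic sessions with known ground truth.

The generator emits the same stream types the readers produce — IMU, pose,
annotations, calcium — from a semi-Markov behavioral state process with
explicit dwell times. Each state prescribes feature-level targets (body
acceleration regime, anteroposterior gravity level, head-rotation event
statistics, axial bending angle) chosen so that distinct states occupy
distinct symbol profiles under the default discretization. Calcium activity
is state-modulated inhomogeneous Poisson events convolved with a GCaMP-like
exponential kernel plus drift and noise, optionally with a spatially
correlated shared drive so that pairwise correlations decay with
inter-neuronal distance.

What this emulates: piecewise-stationary multi-feature behavior, annotation
tracks aligned to states, behavior-tuned neural populations. What it does
not: biomechanics, video, or any within-state temporal structure beyond
band-limited noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .imu import compute_features
from .io import AnnotationTrack, CalciumSession, ImuSession, PoseTrack

IMU_RATE = 200.0
POSE_FPS = 40.0
CALCIUM_FPS = 20.0


@dataclass
class StateSpec:
    """Generative targets of one behavioral state.

    ``ba_level`` is the target mean total body acceleration (g) as measured
    by the inertial pipeline; ``ga_ap`` the anteroposterior gravity level;
    rotation events are half-sine gyro pulses whose total angle is
    ``rotation_angle`` degrees (signed), occurring at ``rotation_rate``
    events/s; ``theta_axial`` the mean axial bending angle (deg).
    """

    name: str
    ba_level: float = 0.1
    ga_ap: float = -0.2
    rotation_rate: float = 0.0
    rotation_angle: float = 0.0
    rotation_velocity: float = 0.0  # deg/s sustained throughout the state
    theta_axial: float = 160.0
    axial_jitter: float = 4.0
    dwell_mean: float = 2.0
    annotation: str | None = None  # None | "axial" | "limb" | "axial_limb"

    def __post_init__(self) -> None:
        if self.dwell_mean < 0.3:
            raise ValueError("dwell_mean must be >= 0.3 s for detectable segments")
        if not 0 < self.theta_axial <= 180:
            raise ValueError("theta_axial must be in (0, 180]")
        if abs(self.ga_ap) > 1:
            raise ValueError("|ga_ap| cannot exceed 1 g")
        if self.ba_level < 0:
            raise ValueError("ba_level must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows: per-sample state, change-points, events."""

    states: list
    state_per_sample: np.ndarray  # index into states, IMU clock
    change_points: np.ndarray  # s
    rate: float
    tuned_neurons: np.ndarray | None = None
    event_frames: list | None = None
    extras: dict = field(default_factory=dict)

    def state_intervals(self) -> list:
        """(start_s, end_s, state_index) runs of the state sequence."""
        s = self.state_per_sample
        bounds = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [s.size]])
        return [(a / self.rate, b / self.rate, int(s[a])) for a, b in zip(starts, ends)]


def _semi_markov_sequence(
    n_states: int, duration: float, rng: np.random.Generator, dwell_means: np.ndarray,
    rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit-dwell state sequence on the IMU clock."""
    n = int(round(duration * rate))
    state_per_sample = np.empty(n, dtype=int)
    change_points = []
    t_idx = 0
    current = int(rng.integers(n_states))
    while t_idx < n:
        dwell = max(0.3, rng.gamma(4.0, dwell_means[current] / 4.0))
        n_dwell = min(n - t_idx, max(1, int(round(dwell * rate))))
        state_per_sample[t_idx : t_idx + n_dwell] = current
        t_idx += n_dwell
        if t_idx < n:
            change_points.append(t_idx / rate)
            if n_states > 1:
                choices = [s for s in range(n_states) if s != current]
                current = int(rng.choice(choices))
    return state_per_sample, np.asarray(change_points)


def _rotation_velocity(
    state_per_sample: np.ndarray, states: list, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Gyro DV channel: half-sine pulses within states that rotate."""
    n = state_per_sample.size
    gyro = rng.normal(0.0, 2.0, n)  # sub-threshold background, deg/s
    s = state_per_sample
    bounds = np.concatenate([[0], np.flatnonzero(np.diff(s)) + 1, [n]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        spec = states[s[a]]
        if spec.rotation_velocity != 0.0:
            gyro[a:b] += spec.rotation_velocity * rng.uniform(0.9, 1.1)
        if spec.rotation_rate <= 0 or spec.rotation_angle == 0:
            continue
        dwell_s = (b - a) / rate
        n_events = rng.poisson(spec.rotation_rate * dwell_s)
        # non-overlapping pulses: overlap would sum cumulative angles past
        # the intended per-event magnitude (e.g. into the pathological bin)
        cursor = a
        for _ in range(n_events):
            dur = rng.uniform(0.4, 0.8)
            m = int(dur * rate)
            lo = cursor
            if lo + m >= b:
                break
            start = lo + int(rng.uniform(0, max(1, (b - lo) - m)))
            m = min(m, n - start)
            if m < 4:
                continue
            angle = spec.rotation_angle * rng.uniform(0.85, 1.15)
            peak = angle * np.pi / (2.0 * (m / rate))  # half-sine of that area
            gyro[start : start + m] += peak * np.sin(np.pi * np.arange(m) / m)
            cursor = start + m
    return gyro


def generate_behavior_session(
    states: list,
    duration: float = 600.0,
    seed: int = 0,
    rate: float = IMU_RATE,
    fps: float = POSE_FPS,
    bad_likelihood_fraction: float = 0.02,
    schedule: list | None = None,
) -> tuple[ImuSession, PoseTrack, AnnotationTrack, GroundTruth]:
    """Generate one synthetic session (IMU + pose + annotations + truth).

    By default the state sequence is semi-Markov with gamma dwell times;
    ``schedule`` — a list of (state_index, duration_s) — plants an explicit
    sequence instead (e.g. to control the exact number of transitions).

    The body-acceleration noise amplitude is calibrated per state against
    the measurement pipeline itself (two correction passes), so the realized
    mean BA per state tracks each state's ``ba_level`` target.
    """
    if not states:
        raise ValueError("need at least one state")
    rng = np.random.default_rng(seed)
    if schedule is not None:
        pieces = [np.full(int(round(d * rate)), int(k)) for k, d in schedule]
        state_per_sample = np.concatenate(pieces)
        change_points = np.cumsum([p.size for p in pieces[:-1]]) / rate
        duration = state_per_sample.size / rate
    else:
        dwell_means = np.array([s.dwell_mean for s in states])
        state_per_sample, change_points = _semi_markov_sequence(
            len(states), duration, rng, dwell_means, rate
        )
    n = state_per_sample.size
    times = np.arange(n) / rate

    # --- gravity: unit-norm vector with the state's AP component
    ga_ap_t = np.array([states[s].ga_ap for s in state_per_sample])
    ga_ap_t = gaussian_filter1d(ga_ap_t, 0.05 * rate)
    ga = np.column_stack([ga_ap_t, np.zeros(n), np.sqrt(1.0 - ga_ap_t**2)])

    # --- body acceleration: narrowband quadrature oscillation (circular
    # head motion at ~4 Hz) with a slowly varying log-normal envelope plus a
    # small band-limited residual. The quadrature pair keeps |BA| near the
    # envelope, so the movement regime is stable within a state instead of
    # flickering through the 0.05 g threshold.
    ba_target = np.array([s.ba_level for s in states])
    phase = 2 * np.pi * 4.0 * times + np.cumsum(rng.normal(0, 0.05, n))
    env_mod = gaussian_filter1d(rng.standard_normal(n), 0.5 * rate, mode="reflect")
    env_mod /= max(env_mod.std(), 1e-12)
    resid = gaussian_filter1d(rng.standard_normal((n, 3)), 0.01 * rate, axis=0,
                              mode="reflect")
    resid *= 0.15 / resid.std(axis=0, keepdims=True)
    quad = np.column_stack([np.cos(phase), np.sin(phase), np.zeros(n)])
    gyro_dv = _rotation_velocity(state_per_sample, states, rate, rng)
    gyro = np.column_stack([rng.normal(0, 2.0, n), rng.normal(0, 2.0, n), gyro_dv])

    def build(scale_per_state: np.ndarray) -> ImuSession:
        env = scale_per_state[state_per_sample] * np.exp(0.1 * env_mod)
        accel = ga + env[:, None] * (quad + resid)
        return ImuSession(times, accel, gyro, rate=rate)

    # two fixed-point iterations against the measurement pipeline: the median
    # filter makes the map from noise amplitude to realized BA only
    # approximately linear, so one pass leaves a ~10% bias
    scale = ba_target.copy()
    session = build(scale)
    for _ in range(2):
        feats = compute_features(session)
        realized = np.array(
            [
                np.mean(feats.ba[state_per_sample == k])
                if np.any(state_per_sample == k)
                else 1.0
                for k in range(len(states))
            ]
        )
        scale = scale * np.where(
            realized > 0, ba_target / np.maximum(realized, 1e-12), 1.0
        )
        session = build(scale)

    pose = _generate_pose(state_per_sample, states, rate, fps, duration, rng,
                          bad_likelihood_fraction)
    annotations = _generate_annotations(state_per_sample, states, rate)
    truth = GroundTruth(
        states=list(states),
        state_per_sample=state_per_sample,
        change_points=change_points,
        rate=rate,
    )
    return session, pose, annotations, truth


def _generate_pose(
    state_per_sample: np.ndarray,
    states: list,
    rate: float,
    fps: float,
    duration: float,
    rng: np.random.Generator,
    bad_fraction: float,
) -> PoseTrack:
    """Keypoints on a body skeleton parameterized by the target axial angle."""
    n_frames = int(round(duration * fps))
    frame_times = np.arange(n_frames) / fps
    imu_idx = np.minimum((frame_times * rate).astype(int), state_per_sample.size - 1)
    s = state_per_sample[imu_idx]
    theta = np.array([states[k].theta_axial for k in s])
    jitter = np.array([states[k].axial_jitter for k in s])
    theta = np.clip(theta + rng.normal(0, 1, n_frames) * jitter, 5.0, 180.0)

    heading = np.cumsum(rng.normal(0, 0.02, n_frames))  # slow wander, rad
    center = 300.0 + np.cumsum(rng.normal(0, 0.5, (n_frames, 2)), axis=0)
    l_nose, l_tail, half_width = 40.0, 35.0, 8.0
    phi_tail = heading + np.pi  # tail opposite the heading
    sign = np.where(rng.random(n_frames) < 0.5, 1.0, -1.0)
    # bend to a fixed side within each state run so frames are coherent
    runs = np.concatenate([[0], np.flatnonzero(np.diff(s)) + 1, [n_frames]])
    for a, b in zip(runs[:-1], runs[1:]):
        sign[a:b] = sign[a]
    phi_nose = phi_tail + sign * np.radians(theta)

    def unit(phi):
        return np.column_stack([np.cos(phi), np.sin(phi)])

    tail = center + l_tail * unit(phi_tail)
    nose = center + l_nose * unit(phi_nose)
    perp = unit(heading + np.pi / 2.0)
    lhl = center + half_width * perp
    rhl = center - half_width * perp

    keypoints, likelihood = {}, {}
    px_noise = 0.3
    for name, xy in (
        ("nose", nose), ("tail_base", tail), ("left_hindlimb", lhl), ("right_hindlimb", rhl),
    ):
        keypoints[name] = xy + rng.normal(0, px_noise, xy.shape)
        lik = rng.uniform(0.85, 1.0, n_frames)
        bad = rng.random(n_frames) < bad_fraction
        lik[bad] = rng.uniform(0.0, 0.5, bad.sum())
        likelihood[name] = lik
    return PoseTrack(frame_times, keypoints, likelihood, fps=fps, axial_only=True)


def _generate_annotations(
    state_per_sample: np.ndarray, states: list, rate: float
) -> AnnotationTrack:
    intervals = []
    s = state_per_sample
    bounds = np.concatenate([[0], np.flatnonzero(np.diff(s)) + 1, [s.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        ann = states[s[a]].annotation
        if ann is None:
            continue
        start, end = a / rate, b / rate
        if ann == "axial_limb":
            intervals.append((start, end, "axial"))
            intervals.append((start, end, "limb"))
        else:
            intervals.append((start, end, ann))
    return AnnotationTrack(intervals=sorted(intervals))


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------


def generate_calcium(
    truth: GroundTruth,
    n_neurons: int = 100,
    baseline_rate: float = 0.1,
    multipliers: np.ndarray | None = None,
    fps: float = CALCIUM_FPS,
    tau_decay: float = 0.4,
    noise_sd: float = 0.05,
    drift_amplitude: float = 0.1,
    shared_drive: float = 0.0,
    spatial_length_um: float = 40.0,
    field_um: float = 600.0,
    seed: int = 0,
) -> tuple[CalciumSession, GroundTruth]:
    """State-modulated Poisson events convolved with an exponential kernel.

    ``multipliers`` is an (n_neurons, n_states) rate-multiplier matrix
    (default all ones = homogeneous Poisson at ``baseline_rate``).
    ``shared_drive`` > 0 adds a latent trace component shared between
    neurons with spatial covariance exp(-d / spatial_length_um), giving a
    distance-decaying pairwise correlation profile.
    """
    rng = np.random.default_rng(seed)
    n_states = len(truth.states)
    if multipliers is None:
        multipliers = np.ones((n_neurons, n_states))
    multipliers = np.asarray(multipliers, dtype=float)
    if multipliers.shape != (n_neurons, n_states):
        raise ValueError("multipliers must be (n_neurons, n_states)")
    if np.any(multipliers < 0) or baseline_rate < 0:
        raise ValueError("rates must be non-negative")

    duration = truth.state_per_sample.size / truth.rate
    n_frames = int(round(duration * fps))
    frame_times = np.arange(n_frames) / fps
    imu_idx = np.minimum((frame_times * truth.rate).astype(int),
                         truth.state_per_sample.size - 1)
    state_f = truth.state_per_sample[imu_idx]

    rates = baseline_rate * multipliers[:, state_f]  # (n_neurons, n_frames)
    counts = rng.poisson(rates / fps)
    event_frames = [np.flatnonzero(counts[i]) for i in range(n_neurons)]

    kernel_len = max(2, int(round(5 * tau_decay * fps)))
    kernel = np.exp(-np.arange(kernel_len) / (tau_decay * fps))
    traces = np.empty((n_neurons, n_frames))
    phase = rng.uniform(0, 2 * np.pi, n_neurons)
    for i in range(n_neurons):
        conv = np.convolve(counts[i].astype(float), kernel)[:n_frames]
        traces[i] = conv + drift_amplitude * np.sin(
            2 * np.pi * frame_times / max(duration, 1.0) + phase[i]
        ) + rng.normal(0, noise_sd, n_frames)

    centroids = rng.uniform(0, field_um, size=(n_neurons, 2))
    if shared_drive > 0:
        d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
        cov = np.exp(-d / spatial_length_um) + 1e-9 * np.eye(n_neurons)
        chol = np.linalg.cholesky(cov)
        z = gaussian_filter1d(rng.standard_normal((n_neurons, n_frames)),
                              0.2 * fps, axis=1)
        z /= z.std(axis=1, keepdims=True)
        traces += shared_drive * (chol @ z)

    session = CalciumSession(frame_times, traces, centroids, event_trains=None)
    tuned = np.flatnonzero(np.any(multipliers > 1.0, axis=1))
    truth_out = GroundTruth(
        states=truth.states,
        state_per_sample=truth.state_per_sample,
        change_points=truth.change_points,
        rate=truth.rate,
        tuned_neurons=tuned,
        event_frames=event_frames,
        extras={"multipliers": multipliers, "baseline_rate": baseline_rate, "fps": fps},
    )
    return session, truth_out


# ---------------------------------------------------------------------------
# canonical state sets and the four-condition mini-study
# ---------------------------------------------------------------------------


def well_separated_states() -> list:
    """Four states, each pair differing in at least two features.

    Feature levels sit deep inside their discretization bins and only the
    temporally fast features (body acceleration, axial angle, sustained
    rotation) differ between states — the postural GA component settles too
    slowly (0.5 Hz low-pass) to give clean state boundaries — so each state
    occupies an essentially degenerate symbol profile. This is the benchmark
    condition for clustering recovery.
    """
    return [
        StateSpec("quiet_straight", ba_level=0.01, ga_ap=-0.2, theta_axial=160.0,
                  axial_jitter=3.0),
        StateSpec("active_rotating", ba_level=0.25, ga_ap=-0.2, theta_axial=160.0,
                  rotation_velocity=-250.0, axial_jitter=3.0),
        StateSpec("active_bent", ba_level=0.25, ga_ap=-0.2, theta_axial=60.0,
                  axial_jitter=3.0),
        StateSpec("quiet_bent_rotating", ba_level=0.01, ga_ap=-0.2, theta_axial=60.0,
                  rotation_velocity=-250.0, axial_jitter=3.0),
    ]


def sharp_transition_states() -> list:
    """Three states whose transitions are carried by fast features.

    Body acceleration and the axial angle respond within tens of
    milliseconds of a state switch, whereas the gravitational component is
    smeared over ~1 s by the 0.5 Hz postural low-pass; holding GA constant
    across states keeps every planted transition temporally sharp — the
    benchmark condition for change-point localization.
    """
    return [
        StateSpec("quiet_straight", ba_level=0.01, ga_ap=-0.2, theta_axial=160.0,
                  axial_jitter=3.0),
        StateSpec("active_bent", ba_level=0.25, ga_ap=-0.2, theta_axial=60.0,
                  axial_jitter=3.0),
        StateSpec("active_straight", ba_level=0.25, ga_ap=-0.2, theta_axial=160.0,
                  axial_jitter=3.0),
    ]


def normal_states() -> list:
    """Open-field repertoire of a non-dyskinetic mouse (distinct symbol profiles)."""
    return [
        StateSpec("rest", ba_level=0.012, ga_ap=-0.2, theta_axial=168.0, dwell_mean=3.0),
        StateSpec("locomotion", ba_level=0.15, ga_ap=-0.2, theta_axial=160.0),
        StateSpec("rearing", ba_level=0.09, ga_ap=0.35, theta_axial=150.0),
        StateSpec("turning", ba_level=0.12, ga_ap=-0.2, rotation_rate=0.8,
                  rotation_angle=-60.0, theta_axial=140.0),
    ]


def dyskinetic_states() -> list:
    """Les-LD repertoire: dyskinesia states plus pathological rotations."""
    return [
        StateSpec("locomotion", ba_level=0.15, ga_ap=-0.2, theta_axial=160.0),
        StateSpec("turning", ba_level=0.12, ga_ap=-0.2, rotation_rate=0.8,
                  rotation_angle=-60.0, theta_axial=140.0),
        StateSpec("axial_limb_dyskinesia", ba_level=0.07, ga_ap=-0.2,
                  theta_axial=68.0, dwell_mean=2.5, annotation="axial_limb"),
        StateSpec("axial_alone_dyskinesia", ba_level=0.18, ga_ap=-0.55,
                  rotation_rate=1.0, rotation_angle=-220.0, theta_axial=82.0,
                  dwell_mean=2.5, annotation="axial"),
        StateSpec("limb_alone_dyskinesia", ba_level=0.07, ga_ap=-0.55,
                  theta_axial=125.0, dwell_mean=2.0, annotation="limb"),
        StateSpec("path_rot", ba_level=0.3, ga_ap=-0.2,
                  rotation_velocity=-300.0, theta_axial=150.0, dwell_mean=2.0),
    ]


def paper_like_scenario(
    seed: int = 0,
    duration: float = 240.0,
    n_mice: dict | None = None,
    include_calcium: bool = False,
    n_neurons: int = 60,
) -> dict:
    """Four-condition mini-study: intact/lesioned x vehicle/L-DOPA cohorts.

    Each mouse contributes one session; lesioned+L-DOPA mice draw from the
    dyskinetic repertoire (extra states mapped to axial+limb, axial-alone,
    limb-alone annotations and pathological rotations), all other cohorts
    from the normal repertoire. With ``include_calcium``, lesioned-L-DOPA
    mice also carry a baseline (normal-repertoire) session with the same
    neuron population, 20% of which is tuned (3x rate) to each dyskinetic
    state.
    """
    n_mice = n_mice or {"int_veh": 3, "int_ld": 3, "les_veh": 3, "les_ld": 4}
    root = np.random.default_rng(seed)
    study = {}
    for cond, n in n_mice.items():
        states = dyskinetic_states() if cond == "les_ld" else normal_states()
        mice = []
        for m in range(n):
            mouse_seed = int(root.integers(2**31 - 1))
            imu, pose, ann, truth = generate_behavior_session(
                states, duration=duration, seed=mouse_seed
            )
            mouse = {
                "mouse_id": f"{cond}_{m}",
                "imu": imu,
                "pose": pose,
                "annotations": ann,
                "truth": truth,
            }
            if include_calcium and cond == "les_ld":
                n_states = len(states)
                mult = np.ones((n_neurons, n_states))
                rng_m = np.random.default_rng(mouse_seed + 1)
                dysk_idx = [i for i, s in enumerate(states) if s.annotation or s.name == "path_rot"]
                for si in dysk_idx:
                    tuned = rng_m.choice(n_neurons, size=max(1, n_neurons // 5), replace=False)
                    mult[tuned, si] = 3.0
                ca, ca_truth = generate_calcium(
                    truth, n_neurons=n_neurons, baseline_rate=0.15,
                    multipliers=mult, seed=mouse_seed + 2,
                )
                bl_imu, bl_pose, bl_ann, bl_truth = generate_behavior_session(
                    normal_states(), duration=duration, seed=mouse_seed + 3
                )
                bl_ca, bl_ca_truth = generate_calcium(
                    bl_truth, n_neurons=n_neurons, baseline_rate=0.15,
                    seed=mouse_seed + 4,
                )
                mouse.update(
                    calcium=ca, calcium_truth=ca_truth,
                    baseline={"imu": bl_imu, "pose": bl_pose, "annotations": bl_ann,
                              "truth": bl_truth, "calcium": bl_ca,
                              "calcium_truth": bl_ca_truth},
                )
            mice.append(mouse)
        study[cond] = mice
    return study
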