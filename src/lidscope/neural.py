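"""Striatal ensemble analysis on calcium traces and event trains.

Event trains come either from an external deconvolution (accepted as-is) or
from the built-in simplified detector: slow running-percentile baseline
subtraction (the multiplicative-drift idea), matched filtering with the
GCaMP-like exponential kernel (tau_decay 400 ms), and peak picking above a
robust noise threshold. Downstream statistics: move/rest event rates (rest
bouts must last >= 500 ms to count), behavior-related ("tuned") neuron
identification against a circular-shift null, ensemble overlap with shuffle
correction, distance-binned pairwise trace correlations (nine log bins over
15-750 um), event-triggered averages, and EMD similarity of the baseline
clusters during which dyskinesia-tuned neurons are positively modulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d, percentile_filter
from scipy.spatial.distance import pdist, squareform

from .ethogram import DiscretizationScheme, cross_emd

DEFAULT_TAU_DECAY = 0.4  # s, GCaMP6f-like decay
DEFAULT_DRIFT = 0.2
DEFAULT_MIN_REST_BOUT = 0.5  # s
SPATIAL_BIN_RANGE_UM = (15.0, 750.0)
N_SPATIAL_BINS = 9


@dataclass
class EventDetectionParams:
    """Parameters of the simplified event detector.

    ``drift`` sets the running-baseline window as a fraction of the trace
    (larger = slower baseline); ``k_mad`` the detection threshold in robust
    noise units.
    """

    tau_decay: float = DEFAULT_TAU_DECAY
    drift: float = DEFAULT_DRIFT
    offset_correction: bool = True
    k_mad: float = 3.0

    def __post_init__(self) -> None:
        if self.tau_decay <= 0:
            raise ValueError("tau_decay must be positive")


def spatial_bin_edges() -> np.ndarray:
    """Nine logarithmically spaced distance bins over 15-750 um."""
    lo, hi = SPATIAL_BIN_RANGE_UM
    return np.logspace(np.log10(lo), np.log10(hi), N_SPATIAL_BINS + 1)


# ---------------------------------------------------------------------------
# event detection and rates
# ---------------------------------------------------------------------------


def detect_events(
    traces: np.ndarray,
    fps: float,
    params: EventDetectionParams | None = None,
) -> list:
    """Detect calcium events on each trace; returns per-neuron frame indices.

    Pipeline per trace: offset so values are strictly positive, subtract a
    slow running 20th-percentile baseline, matched-filter with the
    normalized exponential decay kernel, and keep local maxima exceeding
    ``k_mad`` times the MAD-estimated noise of the filtered trace, at least
    one kernel time constant apart. A flat trace yields no events.
    """
    params = params or EventDetectionParams()
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if not np.all(np.isfinite(traces)):
        raise ValueError("traces must be finite")
    n_frames = traces.shape[1]
    kernel_len = max(2, int(round(5 * params.tau_decay * fps)))
    t = np.arange(kernel_len) / fps
    kernel = np.exp(-t / params.tau_decay)
    kernel /= np.linalg.norm(kernel)
    base_win = max(3, int(round(params.drift * n_frames)) | 1)
    min_dist = max(1, int(round(params.tau_decay * fps)))

    events = []
    for trace in traces:
        x = trace - trace.min() + 1e-12 if params.offset_correction else trace.copy()
        baseline = percentile_filter(x, percentile=20, size=base_win, mode="nearest")
        resid = x - baseline
        # matched filter: filt[t] = sum_j resid[t+j] * kernel[j], peaks at
        # onsets; band-limited to half the transient timescale so that
        # noise-driven local maxima above threshold become rare. The
        # residual rides above zero (percentile baseline), so the threshold
        # is centered on the median of the statistic.
        filt = np.correlate(resid, kernel, mode="full")[kernel_len - 1 :]
        filt = gaussian_filter1d(filt, 0.5 * params.tau_decay * fps)
        mad = stats.median_abs_deviation(filt, scale="normal")
        if mad == 0:
            events.append(np.array([], dtype=int))
            continue
        thr = params.k_mad * mad
        peaks, _ = signal.find_peaks(
            filt, height=np.median(filt) + thr, distance=min_dist, prominence=thr
        )
        events.append(peaks)
    return events


def rest_bouts(moving: np.ndarray, fps: float, min_bout: float = DEFAULT_MIN_REST_BOUT):
    """Boolean mask of frames inside rest bouts of at least ``min_bout`` s."""
    moving = np.asarray(moving, dtype=bool)
    ok = np.zeros(moving.size, dtype=bool)
    min_frames = int(np.ceil(min_bout * fps))
    i = 0
    while i < moving.size:
        if moving[i]:
            i += 1
            continue
        j = i
        while j < moving.size and not moving[j]:
            j += 1
        if j - i >= min_frames:
            ok[i:j] = True
        i = j
    return ok


def event_rates(
    event_train: np.ndarray,
    moving: np.ndarray,
    fps: float,
    min_rest_bout: float = DEFAULT_MIN_REST_BOUT,
) -> dict:
    """Event rate (events/s) while moving and during qualifying rest bouts.

    The resting rate counts only rest bouts lasting at least 500 ms; it is
    NaN when no bout qualifies (the fully dyskinetic case). The moving rate
    is NaN when there is no moving time.
    """
    ev = np.asarray(event_train, dtype=int)
    moving = np.asarray(moving, dtype=bool)
    resting_ok = rest_bouts(moving, fps, min_rest_bout)
    move_t = moving.sum() / fps
    rest_t = resting_ok.sum() / fps
    out = {}
    if move_t > 0:
        out["rate_moving"] = float(np.sum(moving[ev])) / move_t
    else:
        warnings.warn("no moving time; moving rate undefined")
        out["rate_moving"] = float("nan")
    out["rate_resting"] = (
        float(np.sum(resting_ok[ev])) / rest_t if rest_t > 0 else float("nan")
    )
    out["moving_duration"] = move_t
    out["resting_duration"] = rest_t
    return out


# ---------------------------------------------------------------------------
# behavior-related neurons
# ---------------------------------------------------------------------------


def _event_counts(event_trains: list, n_frames: int) -> np.ndarray:
    counts = np.zeros((len(event_trains), n_frames))
    for i, ev in enumerate(event_trains):
        np.add.at(counts[i], np.asarray(ev, dtype=int), 1.0)
    return counts


@dataclass
class TunedNeuronSet:
    """Neurons significantly positively tuned to one cluster group."""

    group: str
    neuron_ids: np.ndarray
    r: np.ndarray  # per-neuron correlation (all neurons)
    pvalue: np.ndarray
    percent_of_population: float
    n_excluded_silent: int = 0


def behavior_related_neurons(
    event_trains: list,
    occupancy: np.ndarray,
    fps: float,
    group: str = "",
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    min_shift_s: float = 10.0,
    random_state: int = 0,
) -> TunedNeuronSet:
    """Identify neurons positively correlated with a cluster-group occupancy.

    Per neuron, Pearson r between the per-frame event counts and the binary
    occupancy series; the null distribution comes from circular shifts of
    the neuron's own event train (independent lags per neuron, at least
    ``min_shift_s`` away from zero). A neuron is behavior-related when its
    r exceeds the (1 - alpha) quantile of its own null. Silent neurons are
    excluded and counted.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    n_frames = occupancy.size
    counts = _event_counts(event_trains, n_frames)
    n = counts.shape[0]
    active = counts.sum(axis=1) > 0
    if np.std(occupancy) == 0:
        raise ValueError("occupancy series is constant")

    rng = np.random.default_rng(random_state)
    min_shift = max(1, int(min_shift_s * fps))
    if 2 * min_shift >= n_frames:
        min_shift = max(1, n_frames // 10)

    c = counts - counts.mean(axis=1, keepdims=True)
    c_norm = np.linalg.norm(c, axis=1)
    c_norm[c_norm == 0] = np.inf
    o = (occupancy - occupancy.mean()) / np.linalg.norm(occupancy - occupancy.mean())
    r_obs = (c @ o) / c_norm
    # r at every circular lag via FFT cross-correlation, then sample
    # n_shuffle random admissible lags independently per neuron
    cc = np.fft.irfft(
        np.fft.rfft(c, axis=1) * np.conj(np.fft.rfft(o))[None, :], n=n_frames, axis=1
    ) / c_norm[:, None]
    lags = rng.integers(min_shift, n_frames - min_shift, size=(n, n_shuffle))
    r_null = np.take_along_axis(cc, lags, axis=1)
    pvals = (1 + np.sum(r_null >= r_obs[:, None], axis=1)) / (1 + n_shuffle)
    significant = active & (r_obs > 0) & (pvals <= alpha)
    ids = np.where(significant)[0]
    n_active = int(active.sum())
    return TunedNeuronSet(
        group=group,
        neuron_ids=ids,
        r=r_obs,
        pvalue=pvals,
        percent_of_population=100.0 * ids.size / n_active if n_active else float("nan"),
        n_excluded_silent=int(n - n_active),
    )


# ---------------------------------------------------------------------------
# ensemble overlap
# ---------------------------------------------------------------------------


def ensemble_overlap(
    set_a,
    set_b,
    population_size: int,
    n_shuffle: int = 1000,
    random_state: int = 0,
) -> dict:
    """Raw and shuffle-corrected overlap between two neuron sets.

    Raw overlap = 100 * |A n B| / |A u B| (Jaccard; 100% = identical sets).
    The shuffle overlap is the mean raw overlap of random sets of the same
    sizes drawn from the population; corrected = raw - shuffle mean.
    """
    a = set(np.asarray(list(set_a)).tolist())
    b = set(np.asarray(list(set_b)).tolist())
    if not a or not b:
        warnings.warn("empty neuron set; overlap undefined")
        return {"raw": float("nan"), "shuffle_mean": float("nan"), "corrected": float("nan")}
    if max(a | b) >= population_size:
        raise ValueError("sets must index into the population")
    raw = 100.0 * len(a & b) / len(a | b)
    rng = np.random.default_rng(random_state)
    pop = np.arange(population_size)
    sh = np.empty(n_shuffle)
    for i in range(n_shuffle):
        ra = set(rng.choice(pop, size=len(a), replace=False).tolist())
        rb = set(rng.choice(pop, size=len(b), replace=False).tolist())
        sh[i] = 100.0 * len(ra & rb) / len(ra | rb)
    return {
        "raw": raw,
        "shuffle_mean": float(sh.mean()),
        "corrected": raw - float(sh.mean()),
        "shuffle_sd": float(sh.std(ddof=1)),
    }


# ---------------------------------------------------------------------------
# spatial correlation profile
# ---------------------------------------------------------------------------


@dataclass
class DistanceCorrelationProfile:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    mean_correlation: np.ndarray  # per bin; NaN where empty
    n_pairs: np.ndarray
    n_excluded: int


def spatial_crosscorrelation(
    traces: np.ndarray, centroids_um: np.ndarray
) -> DistanceCorrelationProfile:
    """Pairwise trace correlation binned by inter-neuronal distance.

    All pairwise Pearson correlations of the raw traces are averaged in
    nine logarithmic distance bins over 15-750 um; pairs outside that range
    are excluded and counted.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    centroids = np.asarray(centroids_um, dtype=float)
    if traces.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    corr = np.corrcoef(traces)
    dist = squareform(pdist(centroids))
    iu = np.triu_indices(traces.shape[0], k=1)
    d, r = dist[iu], corr[iu]
    edges = spatial_bin_edges()
    inside = (d >= edges[0]) & (d <= edges[-1])
    idx = np.clip(np.digitize(d[inside], edges) - 1, 0, N_SPATIAL_BINS - 1)
    mean_corr = np.full(N_SPATIAL_BINS, np.nan)
    n_pairs = np.zeros(N_SPATIAL_BINS, dtype=int)
    for b in range(N_SPATIAL_BINS):
        sel = idx == b
        n_pairs[b] = sel.sum()
        if n_pairs[b]:
            mean_corr[b] = float(np.mean(r[inside][sel]))
    return DistanceCorrelationProfile(
        bin_edges=edges,
        bin_centers=np.sqrt(edges[:-1] * edges[1:]),
        mean_correlation=mean_corr,
        n_pairs=n_pairs,
        n_excluded=int(np.sum(~inside)),
    )


# ---------------------------------------------------------------------------
# event-triggered average
# ---------------------------------------------------------------------------


def event_triggered_average(
    traces: np.ndarray,
    onsets: np.ndarray,
    fps: float,
    window: tuple = (-2.0, 2.0),
    pre_interval: tuple = (-1.0, -0.1),
    post_interval: tuple = (0.1, 1.0),
) -> dict:
    """Population response aligned to behavior onsets.

    Traces are z-scored per neuron over the session; onsets too close to the
    session edge are dropped (and counted). Returns the (n_onsets, n_lags)
    population-mean matrix, the lag axis, and a t-test comparing the mean
    z-scored activity in ``pre_interval`` vs ``post_interval`` across onsets.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 1:
        raise ValueError("need at least one onset")
    sd = traces.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (traces - traces.mean(axis=1, keepdims=True)) / sd
    pop = z.mean(axis=0)
    n_frames = pop.size
    lo = int(np.floor(window[0] * fps))
    hi = int(np.ceil(window[1] * fps))
    lags = np.arange(lo, hi + 1)
    rows, dropped = [], 0
    for t_on in onsets:
        i = int(round(t_on * fps))
        if i + lo < 0 or i + hi >= n_frames:
            dropped += 1
            continue
        rows.append(pop[i + lags])
    if not rows:
        raise ValueError("all onsets fall too close to the session edge")
    mat = np.stack(rows)
    lag_s = lags / fps
    pre = mat[:, (lag_s >= pre_interval[0]) & (lag_s <= pre_interval[1])].mean(axis=1)
    post = mat[:, (lag_s >= post_interval[0]) & (lag_s <= post_interval[1])].mean(axis=1)
    if mat.shape[0] < 2:
        tstat, p = float("nan"), float("nan")
        flag = "under-powered"
    else:
        tstat, p = stats.ttest_ind(post, pre)
        flag = "ok"
    return {
        "aligned": mat,
        "lags_s": lag_s,
        "mean_response": mat.mean(axis=0),
        "pre_mean": float(pre.mean()),
        "post_mean": float(post.mean()),
        "tstat": float(tstat),
        "pvalue": float(p),
        "n_onsets_used": mat.shape[0],
        "n_onsets_dropped": dropped,
        "flag": flag,
    }


# ---------------------------------------------------------------------------
# baseline similarity of tuned clusters
# ---------------------------------------------------------------------------


def posmod_baseline_similarity(
    ld_cluster_hist: np.ndarray,
    tuned_neurons,
    baseline_exemplars: np.ndarray,
    baseline_occupancies: np.ndarray,
    baseline_event_trains: list,
    fps: float,
    scheme: DiscretizationScheme | None = None,
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    random_state: int = 0,
) -> dict:
    """EMD of a dyskinesia cluster to baseline clusters hosting its neurons.

    Baseline clusters are split into "pos mod" (the pooled activity of the
    tuned neuron set is significantly positively modulated during that
    cluster, same circular-shift test as for behavior-related neurons) and
    "other". Reports the EMD between the dyskinesia-cluster exemplar and
    each baseline exemplar, grouped, plus a rank-sum comparison.
    """
    scheme = scheme or DiscretizationScheme()
    tuned = np.asarray(list(tuned_neurons), dtype=int)
    if tuned.size == 0:
        warnings.warn("empty tuned set; comparison undefined")
        return {"flag": "undefined-empty-set"}
    pooled = np.concatenate([np.asarray(baseline_event_trains[i]) for i in tuned])
    if pooled.size == 0:
        warnings.warn("tuned neurons never active at baseline; comparison undefined")
        return {"flag": "undefined-silent"}
    pooled_train = [pooled.astype(int)]
    pos_mod = []
    for occ in np.atleast_2d(baseline_occupancies):
        res = behavior_related_neurons(
            pooled_train, occ, fps, n_shuffle=n_shuffle, alpha=alpha,
            random_state=random_state,
        )
        pos_mod.append(res.neuron_ids.size > 0)
    pos_mod = np.asarray(pos_mod, dtype=bool)
    emds = cross_emd(
        np.atleast_2d(ld_cluster_hist), np.atleast_2d(baseline_exemplars), scheme
    )[0]
    out = {
        "emd_pos_mod": emds[pos_mod],
        "emd_other": emds[~pos_mod],
        "pos_mod_mask": pos_mod,
        "flag": "ok",
    }
    if pos_mod.any() and (~pos_mod).any():
        stat = stats.mannwhitneyu(emds[pos_mod], emds[~pos_mod], alternative="less")
        out["pvalue"] = float(stat.pvalue)
    else:
        out["pvalue"] = float("nan")
    return out
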