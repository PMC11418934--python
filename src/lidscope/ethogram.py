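"""Behavioral segmentation and ethogram clustering.

The four features (total body acceleration BA, anteroposterior gravitational
acceleration GA_AP, head rotation angle theta_head, axial bending angle
theta_axial) are discretized against fixed thresholds, histogrammed in
250 ms sliding windows (80% overlap), and the earth mover's distance (EMD)
between consecutive windows yields a change signal whose peaks are
behavioral change-points. The blocks between change-points ("behavioral
segments", minimum 100 ms) are clustered by affinity propagation on the
negative pairwise EMD of their feature histograms; exemplars with rest/move
labels form a reusable cluster library to which new sessions are matched by
closest EMD.

All histograms are per-feature (one simplex per feature); the total EMD
between two segments or windows is the unweighted sum of the four 1-D EMDs
with unit ground distance between adjacent ordered bins. Because the bins
are ordered and unit-spaced, each 1-D EMD is the L1 norm of the difference
of cumulative histograms (exact, no linear program needed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AffinityPropagation

from .imu import DEFAULT_MOVEMENT_THRESHOLD_G, FeatureSet

FEATURE_NAMES = ("ba", "ga_ap", "theta_head", "theta_axial")

DEFAULT_WINDOW_S = 0.25
DEFAULT_OVERLAP = 0.8
DEFAULT_MIN_SEGMENT_S = 0.1


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscretizationScheme:
    """Ordered bin edges per feature; boundary values go to the upper bin.

    Defaults follow the open-field thresholds: BA split at the 0.05 g
    movement threshold; GA_AP at -0.4 and 0 (head down / forward / up);
    theta_axial at 90 deg (torsioned vs straight trunk); theta_head at
    +/-25 deg for ordinary head deviations and +/-165 deg for strong
    pathological rotations (5 bins).
    """

    ba: tuple = (DEFAULT_MOVEMENT_THRESHOLD_G,)
    ga_ap: tuple = (-0.4, 0.0)
    theta_head: tuple = (-165.0, -25.0, 25.0, 165.0)
    theta_axial: tuple = (90.0,)

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            edges = np.asarray(getattr(self, name), dtype=float)
            if edges.size and np.any(np.diff(edges) <= 0):
                raise ValueError(f"{name} edges must be strictly increasing")

    @property
    def n_bins(self) -> tuple:
        return tuple(len(getattr(self, name)) + 1 for name in FEATURE_NAMES)

    @property
    def slices(self) -> tuple:
        """Column slices of each feature in the stacked histogram layout."""
        offs = np.concatenate([[0], np.cumsum(self.n_bins)])
        return tuple(slice(int(a), int(b)) for a, b in zip(offs[:-1], offs[1:]))

    def to_dict(self) -> dict:
        return {name: list(getattr(self, name)) for name in FEATURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(**{k: tuple(v) for k, v in d.items()})


def discretize(features: FeatureSet, scheme: DiscretizationScheme | None = None) -> np.ndarray:
    """Per-sample bin index for each feature, shape (n_samples, 4).

    Values exactly on an edge go to the upper bin. A NaN axial angle (no
    pose stream) falls in the upper (straight-trunk) bin.
    """
    scheme = scheme or DiscretizationScheme()
    mat = features.as_matrix()
    out = np.empty(mat.shape, dtype=np.int64)
    for k, name in enumerate(FEATURE_NAMES):
        edges = np.asarray(getattr(scheme, name), dtype=float)
        col = mat[:, k]
        if name == "theta_axial":
            col = np.where(np.isnan(col), 180.0, col)
        out[:, k] = np.digitize(col, edges, right=False)
    return out


# ---------------------------------------------------------------------------
# histograms and EMD
# ---------------------------------------------------------------------------


def _stacked_histogram(symbols: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Normalized per-feature histograms of a block of symbols, concatenated."""
    n_bins = scheme.n_bins
    parts = []
    n = symbols.shape[0]
    for k, b in enumerate(n_bins):
        counts = np.bincount(symbols[:, k], minlength=b).astype(float)
        parts.append(counts / n)
    return np.concatenate(parts)


@dataclass
class WindowHistograms:
    """Sliding-window feature histograms on a regular grid."""

    centers: np.ndarray  # window center times, s
    hists: np.ndarray  # (n_windows, sum n_bins) stacked per-feature histograms
    scheme: DiscretizationScheme
    window: float
    step: float


def window_histograms(
    symbols: np.ndarray,
    rate: float,
    t0: float = 0.0,
    window: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    scheme: DiscretizationScheme | None = None,
) -> WindowHistograms:
    """Histogram the symbol series in sliding windows (250 ms, 80% overlap)."""
    scheme = scheme or DiscretizationScheme()
    n = symbols.shape[0]
    w = int(round(window * rate))
    step = int(round(window * (1.0 - overlap) * rate))
    if n < w:
        raise ValueError("session shorter than one window")
    starts = np.arange(0, n - w + 1, step)
    hists = np.empty((starts.size, sum(scheme.n_bins)))
    for i, s in enumerate(starts):
        hists[i] = _stacked_histogram(symbols[s : s + w], scheme)
    centers = t0 + (starts + w / 2.0) / rate
    return WindowHistograms(centers, hists, scheme, window=window, step=step / rate)


def emd_1d(p: np.ndarray, q: np.ndarray) -> float:
    """Earth mover's distance between two histograms on ordered unit-spaced bins."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("histograms must share bin structure")
    sp, sq = p.sum(), q.sum()
    if not (np.isclose(sp, 1.0) and np.isclose(sq, 1.0)):
        warnings.warn("unnormalized histograms; normalizing")
        p, q = p / sp, q / sq
    return float(np.abs(np.cumsum(p - q)).sum())


def emd(
    hist_a: np.ndarray, hist_b: np.ndarray, scheme: DiscretizationScheme | None = None
) -> float:
    """Total EMD between stacked per-feature histograms (unweighted sum)."""
    scheme = scheme or DiscretizationScheme()
    return sum(emd_1d(hist_a[sl], hist_b[sl]) for sl in scheme.slices)


def pairwise_emd(hists: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Dense (n, n) matrix of total EMDs between stacked histograms."""
    n = hists.shape[0]
    dist = np.zeros((n, n))
    for sl in scheme.slices:
        cum = np.cumsum(hists[:, sl], axis=1)[:, :-1]  # last column is ~1 for all
        for k in range(cum.shape[1]):
            dist += np.abs(cum[:, k][:, None] - cum[:, k][None, :])
    return dist


def cross_emd(
    hists_a: np.ndarray, hists_b: np.ndarray, scheme: DiscretizationScheme
) -> np.ndarray:
    """(n_a, n_b) matrix of total EMDs between two stacked-histogram sets."""
    out = np.zeros((hists_a.shape[0], hists_b.shape[0]))
    for sl in scheme.slices:
        ca = np.cumsum(hists_a[:, sl], axis=1)[:, :-1]
        cb = np.cumsum(hists_b[:, sl], axis=1)[:, :-1]
        for k in range(ca.shape[1]):
            out += np.abs(ca[:, k][:, None] - cb[:, k][None, :])
    return out


# ---------------------------------------------------------------------------
# change-point segmentation
# ---------------------------------------------------------------------------


@dataclass
class BehavioralSegment:
    """A change-point-delimited block with its stacked feature histogram."""

    start: float
    end: float
    start_idx: int
    end_idx: int  # exclusive
    hist: np.ndarray

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_histogram(
    symbols: np.ndarray, start_idx: int, end_idx: int, scheme: DiscretizationScheme
) -> np.ndarray:
    """Stacked normalized per-feature histogram over a sample span."""
    if end_idx <= start_idx:
        raise ValueError("empty span")
    return _stacked_histogram(symbols[start_idx:end_idx], scheme)


def change_signal(windows: WindowHistograms) -> tuple[np.ndarray, np.ndarray]:
    """EMD between consecutive windows and the associated times.

    Entry i compares windows i and i+1; its time is the midpoint of the two
    window centers.
    """
    h = windows.hists
    d = np.array([emd(h[i], h[i + 1], windows.scheme) for i in range(h.shape[0] - 1)])
    times = 0.5 * (windows.centers[:-1] + windows.centers[1:])
    return d, times


def detect_changepoints(
    windows: WindowHistograms,
    symbols: np.ndarray,
    rate: float,
    t0: float = 0.0,
    threshold: float | None = None,
    min_duration: float = DEFAULT_MIN_SEGMENT_S,
) -> tuple[np.ndarray, list[BehavioralSegment]]:
    """Detect behavioral change-points and build the segment tiling.

    The change signal is the EMD between consecutive sliding windows; its
    peaks (local maxima) above ``threshold`` are change-points. By default
    the threshold is the session mean of the change signal (data-adaptive;
    a fixed constant such as 0.005 may be passed instead). Segments shorter
    than ``min_duration`` are merged into the neighbor with the more similar
    histogram. Segments tile the session exactly.
    """
    if windows.hists.shape[0] < 3:
        raise ValueError("need at least 3 windows")
    d, times = change_signal(windows)
    if threshold is None:
        threshold = float(np.mean(d))
    # change-points closer than one window length are not resolvable: keep
    # only the highest peak within any window-sized neighborhood
    min_sep = max(1, int(round(windows.window / windows.step)))
    peaks, _ = signal.find_peaks(d, height=threshold, distance=min_sep)
    cp_times = times[peaks]

    n = symbols.shape[0]
    cp_idx = np.clip(np.round((cp_times - t0) * rate).astype(int), 1, n - 1)
    bounds = np.unique(np.concatenate([[0], cp_idx, [n]]))
    scheme = windows.scheme
    segs = [
        BehavioralSegment(
            start=t0 + a / rate,
            end=t0 + b / rate,
            start_idx=int(a),
            end_idx=int(b),
            hist=segment_histogram(symbols, a, b, scheme),
        )
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    segs = _merge_short_segments(segs, symbols, scheme, rate, t0, min_duration)
    cp_times = np.array([s.start for s in segs[1:]])
    return cp_times, segs


def _merge_short_segments(
    segs: list[BehavioralSegment],
    symbols: np.ndarray,
    scheme: DiscretizationScheme,
    rate: float,
    t0: float,
    min_duration: float,
) -> list[BehavioralSegment]:
    min_samples = int(round(min_duration * rate))

    def rebuild(a: int, b: int) -> BehavioralSegment:
        return BehavioralSegment(
            start=t0 + a / rate,
            end=t0 + b / rate,
            start_idx=a,
            end_idx=b,
            hist=segment_histogram(symbols, a, b, scheme),
        )

    while len(segs) > 1:
        lengths = [s.end_idx - s.start_idx for s in segs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_samples:
            break
        cand = []
        if i > 0:
            cand.append((emd(segs[i].hist, segs[i - 1].hist, scheme), i - 1))
        if i < len(segs) - 1:
            cand.append((emd(segs[i].hist, segs[i + 1].hist, scheme), i + 1))
        _, j = min(cand)
        a = min(segs[i].start_idx, segs[j].start_idx)
        b = max(segs[i].end_idx, segs[j].end_idx)
        lo, hi = min(i, j), max(i, j)
        segs = segs[:lo] + [rebuild(a, b)] + segs[hi + 1 :]
    return segs


# ---------------------------------------------------------------------------
# clustering (sklearn-style estimator) and the library
# ---------------------------------------------------------------------------


class EthogramClustering(ClusterMixin, BaseEstimator):
    """Affinity-propagation clustering of behavioral segments by EMD.

    X is the (n_segments, n_bins_total) matrix of stacked per-feature
    histograms. The similarity fed to affinity propagation is the negative
    total EMD; the preference defaults to the median similarity (cluster
    count is therefore data-dependent, as with any exemplar method).

    Attributes (after fit): ``labels_``, ``cluster_centers_`` (exemplar
    histograms), ``exemplar_indices_``, ``n_clusters_``, ``converged_``.
    ``predict`` assigns new histograms to the cluster of the closest
    exemplar by EMD — the a-posteriori library matching procedure.
    """

    def __init__(
        self,
        scheme: DiscretizationScheme | None = None,
        preference: float | None = None,
        damping: float = 0.9,
        max_iter: int = 1000,
        random_state: int = 0,
    ):
        self.scheme = scheme
        self.preference = preference
        self.damping = damping
        self.max_iter = max_iter
        self.random_state = random_state

    def _scheme(self) -> DiscretizationScheme:
        return self.scheme or DiscretizationScheme()

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 segments to cluster")
        scheme = self._scheme()
        dist = pairwise_emd(X, scheme)
        sim = -dist
        pref = self.preference
        if pref is None:
            pref = float(np.median(sim))
        ap = AffinityPropagation(
            affinity="precomputed",
            preference=pref,
            damping=self.damping,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        ap.fit(sim)
        if ap.cluster_centers_indices_ is None or len(ap.cluster_centers_indices_) == 0:
            raise RuntimeError(
                "affinity propagation did not converge "
                f"(damping={self.damping}, max_iter={self.max_iter}); "
                "raise damping or max_iter"
            )
        self.converged_ = ap.n_iter_ < self.max_iter
        if not self.converged_:
            warnings.warn(
                f"affinity propagation hit max_iter={self.max_iter} "
                f"(damping={self.damping}); treat assignments with caution"
            )
        self.exemplar_indices_ = np.asarray(ap.cluster_centers_indices_)
        self.labels_ = ap.labels_
        self.cluster_centers_ = X[self.exemplar_indices_]
        self.n_clusters_ = self.exemplar_indices_.size
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = cross_emd(X, self.cluster_centers_, self._scheme())
        return np.argmin(d, axis=1)


@dataclass
class ClusterLibrary:
    """Exemplar library: cluster exemplars, rest/move labels, presence flags."""

    scheme: DiscretizationScheme
    exemplar_hists: np.ndarray  # (n_clusters, n_bins_total)
    labels: np.ndarray  # segment -> cluster id, for the sessions that built it
    rest_move: dict = field(default_factory=dict)  # cluster id -> "rest"|"move"
    presence: dict = field(default_factory=dict)  # condition -> list of present ids
    rest_probability: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return self.exemplar_hists.shape[0]

    def moving_clusters(self) -> list:
        return [c for c in range(self.n_clusters) if self.rest_move.get(c) == "move"]

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme.to_dict(),
            "exemplar_hists": self.exemplar_hists.tolist(),
            "labels": np.asarray(self.labels).tolist(),
            "rest_move": {str(k): v for k, v in self.rest_move.items()},
            "presence": {k: sorted(v) for k, v in self.presence.items()},
            "rest_probability": {str(k): v for k, v in self.rest_probability.items()},
        }
        with open(path, "w") as f:
            json.dump(payload, f)

    @classmethod
    def from_json(cls, path) -> "ClusterLibrary":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            scheme=DiscretizationScheme.from_dict(payload["scheme"]),
            exemplar_hists=np.asarray(payload["exemplar_hists"]),
            labels=np.asarray(payload["labels"]),
            rest_move={int(k): v for k, v in payload["rest_move"].items()},
            presence={k: list(v) for k, v in payload["presence"].items()},
            rest_probability={int(k): v for k, v in payload.get("rest_probability", {}).items()},
        )


def cluster_segments(
    segments: list[BehavioralSegment],
    scheme: DiscretizationScheme | None = None,
    preference: float | None = None,
    damping: float = 0.9,
    max_iter: int = 1000,
    random_state: int = 0,
) -> tuple[ClusterLibrary, EthogramClustering]:
    """Cluster segments with affinity propagation; returns library + estimator."""
    if len(segments) < 10:
        raise ValueError("need at least 10 segments to build a library")
    scheme = scheme or DiscretizationScheme()
    X = np.stack([s.hist for s in segments])
    est = EthogramClustering(
        scheme=scheme,
        preference=preference,
        damping=damping,
        max_iter=max_iter,
        random_state=random_state,
    ).fit(X)
    lib = ClusterLibrary(
        scheme=scheme, exemplar_hists=est.cluster_centers_, labels=est.labels_
    )
    return lib, est


def label_rest_move(
    library: ClusterLibrary,
    segments: list[BehavioralSegment],
    ba: np.ndarray,
    threshold: float = DEFAULT_MOVEMENT_THRESHOLD_G,
) -> dict:
    """Per-cluster rest/move label from the probability of sub-threshold BA.

    A cluster is "rest" when the fraction of its member samples below the
    movement threshold exceeds 0.5, "move" otherwise.
    """
    sub = np.asarray(ba) < threshold
    counts = {c: [0, 0] for c in range(library.n_clusters)}  # [rest samples, total]
    for seg, c in zip(segments, library.labels):
        span = sub[seg.start_idx : seg.end_idx]
        counts[int(c)][0] += int(span.sum())
        counts[int(c)][1] += int(span.size)
    for c, (nrest, ntot) in counts.items():
        p_rest = nrest / ntot if ntot else 0.0
        library.rest_probability[c] = p_rest
        library.rest_move[c] = "rest" if p_rest > 0.5 else "move"
    return library.rest_move


def roc_separability(
    segments_hists: np.ndarray,
    labels: np.ndarray,
    scheme: DiscretizationScheme | None = None,
    max_pairs: int = 200_000,
    random_state: int = 0,
) -> dict:
    """Same/different-cluster separability from a single EMD threshold.

    Over segment pairs, classify "same cluster" vs "different cluster" by
    thresholding the pairwise EMD; reports the best balanced accuracy over
    all thresholds, plus the same statistic after random permutation of the
    cluster labels (null ~ 0.5).
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 clusters for ROC separability")
    scheme = scheme or DiscretizationScheme()
    rng = np.random.default_rng(random_state)
    n = segments_hists.shape[0]
    iu = np.triu_indices(n, k=1)
    if iu[0].size > max_pairs:
        keep = rng.choice(iu[0].size, size=max_pairs, replace=False)
        iu = (iu[0][keep], iu[1][keep])
    dist = pairwise_emd(np.asarray(segments_hists, dtype=float), scheme)[iu]

    def best_balanced_accuracy(lab: np.ndarray) -> float:
        same = lab[iu[0]] == lab[iu[1]]
        if same.all() or not same.any():
            raise ValueError("degenerate pair labels")
        order = np.argsort(dist)
        same_sorted = same[order]
        tp = np.concatenate([[0], np.cumsum(same_sorted)])
        fp = np.concatenate([[0], np.cumsum(~same_sorted)])
        tpr = tp / tp[-1]
        fpr = fp / fp[-1]
        return float(np.max((tpr + 1 - fpr) / 2.0))

    acc = best_balanced_accuracy(labels)
    acc_shuffled = best_balanced_accuracy(rng.permutation(labels))
    return {"accuracy": acc, "accuracy_shuffled": acc_shuffled, "n_pairs": iu[0].size}


def match_to_library(
    hists: np.ndarray,
    library: ClusterLibrary,
    scheme: DiscretizationScheme | None = None,
    random_state: int = 0,
) -> dict:
    """Assign each histogram to the library cluster with the closest exemplar.

    Match quality compares the matched EMDs with EMDs to randomly assigned
    exemplars (rank-sum test); a good match has systematically smaller EMD
    than shuffle.
    """
    scheme = scheme or library.scheme
    if scheme.to_dict() != library.scheme.to_dict():
        raise ValueError("discretization scheme mismatch with library")
    hists = np.atleast_2d(np.asarray(hists, dtype=float))
    d = cross_emd(hists, library.exemplar_hists, scheme)
    assignments = np.argmin(d, axis=1)
    matched = d[np.arange(d.shape[0]), assignments]
    rng = np.random.default_rng(random_state)
    shuffled_assign = rng.integers(0, library.n_clusters, size=d.shape[0])
    shuffled = d[np.arange(d.shape[0]), shuffled_assign]
    if np.allclose(matched, shuffled):
        p = 1.0
    else:
        p = float(mannwhitneyu(matched, shuffled, alternative="less").pvalue)
    return {
        "assignments": assignments,
        "matched_emd": matched,
        "shuffled_emd": shuffled,
        "pvalue_vs_shuffle": p,
    }


def cluster_presence(
    occupancy: dict,
    min_time: float = 3.0,
    session_duration: float | None = 600.0,
) -> dict:
    """Presence flags per condition from mean per-session cluster occupancy.

    ``occupancy`` maps condition -> list of per-session dicts
    {cluster_id: seconds}. A cluster is present in a condition when its mean
    occupancy across that condition's sessions reaches ``min_time`` (3 s for
    600 s sessions = 0.5% of the duration; scaled accordingly when a
    different ``session_duration`` is given).
    """
    if session_duration is not None:
        min_time = min_time * (session_duration / 600.0)
    presence = {}
    for condition, sessions in occupancy.items():
        clusters = {c for sess in sessions for c in sess}
        present = []
        for c in sorted(clusters):
            mean_occ = np.mean([sess.get(c, 0.0) for sess in sessions])
            if mean_occ >= min_time:
                present.append(c)
        presence[condition] = present
    return presence


# ---------------------------------------------------------------------------
# convenience pipeline
# ---------------------------------------------------------------------------


def segment_session(
    features: FeatureSet,
    scheme: DiscretizationScheme | None = None,
    window: float = DEFAULT_WINDOW_S,
    overlap: float = DEFAULT_OVERLAP,
    threshold: float | None = None,
    min_duration: float = DEFAULT_MIN_SEGMENT_S,
) -> tuple[np.ndarray, list[BehavioralSegment], np.ndarray]:
    """Discretize, window, and segment one session.

    Returns (change-point times, segments, symbol series).
    """
    scheme = scheme or DiscretizationScheme()
    symbols = discretize(features, scheme)
    windows = window_histograms(
        symbols, features.rate, t0=float(features.times[0]), window=window,
        overlap=overlap, scheme=scheme,
    )
    cps, segs = detect_changepoints(
        windows, symbols, features.rate, t0=float(features.times[0]),
        threshold=threshold, min_duration=min_duration,
    )
    return cps, segs, symbols
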