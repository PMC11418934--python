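"""Cohort-level orchestration: library building, group mapping, classification.

Mirrors the experimental design: four conditions (intact/lesioned x
vehicle/L-DOPA), one session per mouse. Sessions are segmented
independently, a cluster library is built by affinity propagation over the
pooled segments of the library cohort, every session is matched to it, and
clusters are mapped to dyskinesia groups from per-mouse annotation
correlations plus intact-vehicle presence. The group-occupancy features
then feed the leave-one-mouse-out dyskinesia-type classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dyskinesia import (
    COMBINATIONS,
    assign_cluster_groups,
    cluster_annotation_correlation,
    dyskinesia_classifier,
)
from .ethogram import ClusterLibrary, DiscretizationScheme, cluster_segments, segment_session
from .imu import DEFAULT_MOVEMENT_THRESHOLD_G
from .pipeline import occupancy_seconds, segment_label_series, session_features

INTACT_VEHICLE = "int_veh"


@dataclass
class SessionResult:
    """One processed session: features, segments, per-sample cluster labels."""

    condition: str
    mouse_id: str
    features: object
    segments: list
    symbols: np.ndarray
    assignments: np.ndarray | None = None
    annotations: object = None

    @property
    def rate(self) -> float:
        return self.features.rate

    def label_series(self) -> np.ndarray:
        return segment_label_series(
            self.segments, self.assignments, self.symbols.shape[0]
        )

    def moving_mask(self, threshold: float = DEFAULT_MOVEMENT_THRESHOLD_G) -> np.ndarray:
        return self.features.ba >= threshold


def process_study(study: dict, scheme: DiscretizationScheme | None = None,
                  **segment_kwargs) -> list[SessionResult]:
    """Extract features and segments for every session of the study dict."""
    results = []
    for condition, mice in study.items():
        for m in mice:
            feats = session_features(m["imu"], m["pose"])
            _, segs, symbols = segment_session(feats, scheme=scheme, **segment_kwargs)
            results.append(
                SessionResult(
                    condition=condition,
                    mouse_id=m["mouse_id"],
                    features=feats,
                    segments=segs,
                    symbols=symbols,
                    annotations=m.get("annotations"),
                )
            )
    return results


def build_library(
    sessions: list[SessionResult],
    scheme: DiscretizationScheme | None = None,
    movement_threshold: float = DEFAULT_MOVEMENT_THRESHOLD_G,
    random_state: int = 0,
    **ap_kwargs,
) -> ClusterLibrary:
    """Cluster the pooled segments and annotate the library.

    Fills per-session assignments on each ``SessionResult``, per-cluster
    rest/move labels (probability of sub-threshold BA over member samples),
    and presence flags per condition (mean occupancy >= 0.5% of session
    duration).
    """
    scheme = scheme or DiscretizationScheme()
    all_segs = [s for sess in sessions for s in sess.segments]
    library, est = cluster_segments(
        all_segs, scheme=scheme, random_state=random_state, **ap_kwargs
    )
    offset = 0
    for sess in sessions:
        k = len(sess.segments)
        sess.assignments = est.labels_[offset : offset + k]
        offset += k

    # rest/move from pooled member samples
    rest = {c: [0, 0] for c in range(library.n_clusters)}
    for sess in sessions:
        sub = sess.features.ba < movement_threshold
        for seg, c in zip(sess.segments, sess.assignments):
            rest[int(c)][0] += int(sub[seg.start_idx : seg.end_idx].sum())
            rest[int(c)][1] += seg.end_idx - seg.start_idx
    for c, (nrest, ntot) in rest.items():
        p = nrest / ntot if ntot else 0.0
        library.rest_probability[c] = p
        library.rest_move[c] = "rest" if p > 0.5 else "move"

    # presence per condition
    occupancy = {}
    for sess in sessions:
        labels = sess.label_series()
        occupancy.setdefault(sess.condition, []).append(
            occupancy_seconds(labels, sess.rate)
        )
    duration = sessions[0].symbols.shape[0] / sessions[0].rate
    from .ethogram import cluster_presence

    library.presence = cluster_presence(occupancy, session_duration=duration)
    return library


def map_cluster_groups(
    sessions: list[SessionResult],
    library: ClusterLibrary,
    annotated_condition: str = "les_ld",
    bin_s: float = 0.05,
    n_boot: int = 1000,
    alpha: float = 0.001,
    random_state: int = 0,
):
    """Per-mouse cluster-annotation correlations and cohort group assignment.

    Only moving clusters are mapped; the per-mouse correlation uses binary
    occupancy series on the ``bin_s`` grid with a circular-shift null.
    """
    from .pipeline import binarize_on_grid

    moving = library.moving_clusters()
    results = {}
    rng = np.random.default_rng(random_state)
    for sess in sessions:
        if sess.condition != annotated_condition or sess.annotations is None:
            continue
        labels = sess.label_series()
        ann = sess.annotations.frame_labels(sess.features.times)
        ann_series = {
            comb: binarize_on_grid(ann, sess.rate, comb, bin_s) for comb in COMBINATIONS
        }
        for c in moving:
            occ = binarize_on_grid(labels, sess.rate, c, bin_s)
            for comb in COMBINATIONS:
                results[(sess.mouse_id, c, comb)] = cluster_annotation_correlation(
                    occ,
                    ann_series[comb],
                    n_boot=n_boot,
                    alpha=alpha,
                    random_state=int(rng.integers(2**31 - 1)),
                )
    present_int_veh = [
        c for c in library.presence.get(INTACT_VEHICLE, []) if c in moving
    ]
    assignment = assign_cluster_groups(results, present_int_veh)
    return assignment, results


def classifier_windows(
    sess: SessionResult,
    assignment,
    window_s: float = 1.0,
    min_annotated: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window group-occupancy features and annotation labels.

    Each non-overlapping ``window_s`` window yields the fractional occupancy
    of the axial+limb and axial-alone cluster groups; windows in which one
    of the two annotation types covers at least ``min_annotated`` of the
    samples are labeled with it, others are dropped.
    """
    labels = sess.label_series()
    ann = sess.annotations.frame_labels(sess.features.times)
    ids_al = assignment.clusters_in("axial_limb")
    ids_aa = assignment.clusters_in("axial_alone")
    step = int(round(window_s * sess.rate))
    n_win = labels.size // step
    X, y = [], []
    for w in range(n_win):
        sl = slice(w * step, (w + 1) * step)
        frac_al = float(np.isin(labels[sl], ids_al).mean())
        frac_aa = float(np.isin(labels[sl], ids_aa).mean())
        ann_w = ann[sl]
        for comb in ("axial_limb", "axial_alone"):
            if np.mean(ann_w == comb) >= min_annotated:
                X.append([frac_al, frac_aa])
                y.append(comb)
                break
    return np.asarray(X, dtype=float), np.asarray(y)


def run_dyskinesia_classifier(
    sessions: list[SessionResult],
    assignment,
    annotated_condition: str = "les_ld",
    n_subsample: int = 200,
    window_s: float = 1.0,
    permute_labels: bool = False,
    random_state: int = 0,
) -> dict:
    """Leave-one-mouse-out classification over the annotated cohort."""
    features_by_mouse, labels_by_mouse = {}, {}
    for sess in sessions:
        if sess.condition != annotated_condition or sess.annotations is None:
            continue
        X, y = classifier_windows(sess, assignment, window_s=window_s)
        if X.size:
            features_by_mouse[sess.mouse_id] = X
            labels_by_mouse[sess.mouse_id] = y
    return dyskinesia_classifier(
        features_by_mouse,
        labels_by_mouse,
        n_subsample=n_subsample,
        permute_labels=permute_labels,
        random_state=random_state,
    )
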