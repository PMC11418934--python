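"""Relating behavioral clusters to dyskinesia annotations.

Clusters are tied to manually annotated dyskinesia (axial alone, limb
alone, axial+limb) through per-mouse Pearson correlations between cluster
occupancy and annotation occupancy on a common 50 ms grid, with a
circular-shift bootstrap null (shifting preserves both series'
autocorrelation and marginals). Cohort-level cluster groups follow the
two-mouse rule: a cluster joins a dyskinesia group when significantly
positively correlated in at least two mice, and the number of positive mice
exceeds the number of negative mice by at least two. Remaining moving
clusters are "other N" when present in the intact-vehicle condition and
"path rot" (pathological rotation) otherwise. A linear support-vector
classifier over group-occupancy features, evaluated with leave-one-mouse-out
cross-validation and balanced subsampling, quantifies how well annotation
type is predicted from the cluster groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC

COMBINATIONS = ("axial_limb", "axial_alone", "limb_alone")
DYSKINESIA_GROUPS = COMBINATIONS + ("path_rot", "other_n")

DEFAULT_ALPHA = 0.001
DEFAULT_N_BOOT = 1000


# ---------------------------------------------------------------------------
# cluster-annotation correlation
# ---------------------------------------------------------------------------


@dataclass
class ClusterAnnotationResult:
    """Per (mouse, cluster, combination) correlation with its bootstrap null."""

    r: float
    pvalue: float
    direction: str  # "positive" | "negative" | "none"


def occupancy_series(
    labels: np.ndarray, target, grid: np.ndarray | None = None
) -> np.ndarray:
    """Binary series marking samples whose label is (in) ``target``."""
    targets = (target,) if isinstance(target, (str, int)) else tuple(target)
    return np.isin(labels, targets).astype(float)


def cluster_annotation_correlation(
    cluster_occ: np.ndarray,
    annotation_occ: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    alpha: float = DEFAULT_ALPHA,
    min_shift: int | None = None,
    random_state: int = 0,
) -> ClusterAnnotationResult:
    """Pearson r between binary occupancy series with a circular-shift null.

    The null distribution is built from ``n_boot`` uniformly random circular
    shifts of the annotation series (shifts at least ``min_shift`` bins away
    from zero; default one tenth of the series). Significance is one-sided
    in each direction at ``alpha``: positive if the observed r exceeds the
    (1 - alpha) null quantile, negative if below the alpha quantile.
    """
    x = np.asarray(cluster_occ, dtype=float)
    y = np.asarray(annotation_occ, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    if np.std(x) == 0 or np.std(y) == 0:
        return ClusterAnnotationResult(r=np.nan, pvalue=np.nan, direction="none")
    r = float(pearsonr(x, y)[0])
    n = x.size
    if min_shift is None:
        min_shift = max(1, n // 10)
    rng = np.random.default_rng(random_state)
    shifts = rng.integers(min_shift, n - min_shift, size=n_boot)
    xc = (x - x.mean()) / (x.std() * np.sqrt(n))
    yc = (y - y.mean()) / (y.std() * np.sqrt(n))
    null = np.array([float(np.dot(xc, np.roll(yc, s))) for s in shifts])
    p_pos = (1 + np.sum(null >= r)) / (1 + n_boot)
    p_neg = (1 + np.sum(null <= r)) / (1 + n_boot)
    if r > 0 and p_pos <= alpha:
        return ClusterAnnotationResult(r=r, pvalue=p_pos, direction="positive")
    if r < 0 and p_neg <= alpha:
        return ClusterAnnotationResult(r=r, pvalue=p_neg, direction="negative")
    return ClusterAnnotationResult(r=r, pvalue=min(p_pos, p_neg), direction="none")


# ---------------------------------------------------------------------------
# cohort-level group assignment
# ---------------------------------------------------------------------------


@dataclass
class GroupAssignment:
    """Cluster id -> cluster group, with per-combination vote provenance."""

    groups: dict  # cluster id -> group name
    votes: dict = field(default_factory=dict)  # (cluster, combination) -> (n_pos, n_neg)

    def clusters_in(self, group: str) -> list:
        return sorted(c for c, g in self.groups.items() if g == group)


def assign_cluster_groups(
    results: dict,
    present_in_intact_vehicle,
    min_positive: int = 2,
    margin: int = 2,
) -> GroupAssignment:
    """Cohort rule mapping clusters to dyskinesia groups.

    ``results`` maps (mouse, cluster, combination) -> ClusterAnnotationResult.
    A cluster joins a combination's group when at least ``min_positive`` mice
    show significant positive correlation and positives outnumber negatives
    by at least ``margin``. Ties between eligible combinations break by
    larger positive count, then larger mean r. Unassigned moving clusters
    become "other_n" if present in the intact-vehicle condition, otherwise
    "path_rot".
    """
    present = set(present_in_intact_vehicle)
    clusters = sorted({c for (_, c, _) in results})
    groups, votes = {}, {}
    for c in clusters:
        candidates = []
        for comb in COMBINATIONS:
            entries = [v for (m, cc, co), v in results.items() if cc == c and co == comb]
            n_pos = sum(1 for e in entries if e.direction == "positive")
            n_neg = sum(1 for e in entries if e.direction == "negative")
            votes[(c, comb)] = (n_pos, n_neg)
            if n_pos >= min_positive and n_pos >= n_neg + margin:
                mean_r = float(np.mean([e.r for e in entries if e.direction == "positive"]))
                candidates.append((n_pos, mean_r, comb))
        if candidates:
            candidates.sort(reverse=True)
            groups[c] = candidates[0][2]
        else:
            groups[c] = "other_n" if c in present else "path_rot"
    return GroupAssignment(groups=groups, votes=votes)


def group_occupancy(
    assignment: GroupAssignment,
    segment_labels: np.ndarray,
    moving: np.ndarray,
    moving_clusters=None,
) -> dict:
    """Percent of moving time spent in each cluster group.

    ``segment_labels`` holds the per-sample cluster id; only samples flagged
    moving (and, when given, belonging to ``moving_clusters``) enter the
    denominator. Percentages sum to 100 over groups.
    """
    labels = np.asarray(segment_labels)
    moving = np.asarray(moving, dtype=bool)
    keep = moving.copy()
    if moving_clusters is not None:
        keep &= np.isin(labels, list(moving_clusters))
    total = int(keep.sum())
    if total == 0:
        warnings.warn("no moving time; group occupancy undefined")
        return {g: float("nan") for g in DYSKINESIA_GROUPS}
    out = {}
    for g in DYSKINESIA_GROUPS:
        ids = assignment.clusters_in(g)
        out[g] = 100.0 * float(np.sum(keep & np.isin(labels, ids))) / total
    return out


# ---------------------------------------------------------------------------
# AIM score correlation
# ---------------------------------------------------------------------------


@dataclass
class AimScoreTable:
    """Per-session abnormal-involuntary-movement severity scores (0-4).

    One row per (mouse, session); axial/limb/orofacial on the integer 0-4
    scale (half-points excluded). Orofacial scores are carried but never
    mapped to clusters (no frame-wise annotation exists for them).
    """

    mouse_ids: list
    axial: np.ndarray
    limb: np.ndarray
    orofacial: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.axial = np.asarray(self.axial, dtype=float)
        self.limb = np.asarray(self.limb, dtype=float)
        if self.orofacial is not None:
            self.orofacial = np.asarray(self.orofacial, dtype=float)
        for name in ("axial", "limb", "orofacial"):
            arr = getattr(self, name)
            if arr is None:
                continue
            if arr.shape != (len(self.mouse_ids),):
                raise ValueError(f"{name} scores must align with mouse_ids")
            if not np.all(np.isin(arr[~np.isnan(arr)], [0, 1, 2, 3, 4])):
                raise ValueError(f"{name} scores must be integers 0-4")

    def scores(self, aim_type: str) -> np.ndarray:
        return getattr(self, aim_type)


def aims_cluster_correlation(time_in_cluster, aim_scores) -> dict:
    """Spearman rank correlation between per-session cluster time and AIM score.

    AIM severity is the 0-4 integer scale per body part. Requires at least
    5 paired observations; an all-ties input is flagged undefined.
    """
    x = np.asarray(time_in_cluster, dtype=float)
    y = np.asarray(aim_scores, dtype=float)
    if x.size != y.size:
        raise ValueError("paired observations required")
    if x.size < 5:
        raise ValueError("need at least 5 paired observations")
    if not np.all(np.isin(y[~np.isnan(y)], [0, 1, 2, 3, 4])):
        raise ValueError("AIM scores must be integers 0-4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return {"rho": float("nan"), "pvalue": float("nan"), "flag": "ties-only"}
    rho, p = spearmanr(x, y)
    return {"rho": float(rho), "pvalue": float(p), "flag": "ok"}


# ---------------------------------------------------------------------------
# dyskinesia-type classifier
# ---------------------------------------------------------------------------


class DyskinesiaTypeClassifier(ClassifierMixin, BaseEstimator):
    """Linear SVC over cluster-group occupancy features, class-balanced.

    A thin sklearn-style wrapper used inside the leave-one-mouse-out
    evaluation: each fit draws a balanced subsample of the training windows
    (equal class counts) before fitting the linear margin.
    """

    def __init__(self, C: float = 1.0, max_per_class: int = 500, random_state: int = 0):
        self.C = C
        self.max_per_class = max_per_class
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("need both classes in training data")
        rng = np.random.default_rng(self.random_state)
        n_take = min(counts.min(), self.max_per_class)
        idx = np.concatenate(
            [rng.choice(np.where(y == c)[0], size=n_take, replace=False) for c in classes]
        )
        self.svc_ = LinearSVC(C=self.C).fit(X[idx], y[idx])
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, dtype=float))


def dyskinesia_classifier(
    features_by_mouse: dict,
    labels_by_mouse: dict,
    n_subsample: int = 5000,
    test_fraction: float = 0.2,
    max_per_class: int = 500,
    permute_labels: bool = False,
    random_state: int = 0,
) -> dict:
    """Leave-one-mouse-out classification of annotation type from group occupancy.

    For each held-out mouse, ``n_subsample`` draws each build a balanced
    train/test split (0.8/0.2 within the respective mice, equal class
    counts), fit the linear SVC, and score the held-out windows; fold
    accuracy is the average over draws. Folds whose held-out mouse lacks a
    class are skipped with a warning. With ``permute_labels`` the class
    labels are randomly permuted first, giving the chance level.
    """
    mice = sorted(features_by_mouse)
    if len(mice) < 3:
        raise ValueError("need at least 3 mice for leave-one-mouse-out")
    rng = np.random.default_rng(random_state)
    labels_by_mouse = {m: np.asarray(labels_by_mouse[m]) for m in mice}
    if permute_labels:
        labels_by_mouse = {
            m: rng.permutation(labels_by_mouse[m]) for m in mice
        }
    all_classes = np.unique(np.concatenate([labels_by_mouse[m] for m in mice]))
    if all_classes.size < 2:
        raise ValueError("both classes must be present in the cohort")

    fold_acc, per_class, skipped = {}, {c: [] for c in all_classes}, []
    for held_out in mice:
        y_test_all = labels_by_mouse[held_out]
        if np.unique(y_test_all).size < all_classes.size:
            warnings.warn(f"mouse {held_out!r} lacks a class; fold skipped")
            skipped.append(held_out)
            continue
        X_test_all = np.asarray(features_by_mouse[held_out], dtype=float)
        X_train = np.concatenate(
            [np.asarray(features_by_mouse[m], dtype=float) for m in mice if m != held_out]
        )
        y_train = np.concatenate([labels_by_mouse[m] for m in mice if m != held_out])
        accs = []
        class_hits = {c: [] for c in all_classes}
        n_test = max(
            1, int(test_fraction / (1 - test_fraction) * min(
                np.bincount(np.searchsorted(all_classes, y_test_all)).min(), max_per_class
            ))
        )
        for _ in range(n_subsample):
            clf = DyskinesiaTypeClassifier(
                max_per_class=max_per_class,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(X_train, y_train)
            test_idx = np.concatenate(
                [
                    rng.choice(np.where(y_test_all == c)[0], size=n_test, replace=False)
                    for c in all_classes
                ]
            )
            pred = clf.predict(X_test_all[test_idx])
            truth = y_test_all[test_idx]
            accs.append(float(np.mean(pred == truth)))
            for c in all_classes:
                sel = truth == c
                class_hits[c].append(float(np.mean(pred[sel] == c)))
        fold_acc[held_out] = float(np.mean(accs))
        for c in all_classes:
            per_class[c].append(float(np.mean(class_hits[c])))
    if not fold_acc:
        raise ValueError("all folds skipped; no mouse carries both classes")
    return {
        "accuracy": float(np.mean(list(fold_acc.values()))),
        "fold_accuracy": fold_acc,
        "per_class_accuracy": {c: float(np.mean(v)) for c, v in per_class.items()},
        "skipped_mice": skipped,
    }
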