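"""Deep clustering of windowed FC into recurring connectivity states.

Pooled windows from all subjects are encoded by the autoencoder (see
:mod:`dynconn.autoencoder`) and clustered with a two-stage exemplar-initialized
k-means: 128 k-means++ repetitions (max 1000 iterations) on exemplar windows —
windows at local maxima of per-window feature variance — then a single k-means
run on all windows (max 10000 iterations) seeded with the best exemplar
centroids. The number of states is chosen with an elbow rule on the
within-cluster to between-centroid distance ratio. Per-subject temporal
metrics: mean dwell time (seconds) and fractional occupancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .windows import WindowSpec, WindowedFC

__all__ = [
    "StateModel",
    "StateMetrics",
    "select_exemplars",
    "cluster_states",
    "elbow_select_k",
    "state_metrics",
    "match_states",
]

logger = logging.getLogger(__name__)


@dataclass
class StateModel:
    """k cluster centroids in the encoded space plus per-window assignments (1-based)."""

    k: int
    centroids: np.ndarray        # (k, bottleneck)
    assignments: np.ndarray      # (W_total,) labels in 1..k
    inertia: float
    within_between_ratio: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments)
        if a.size and (a.min() < 1 or a.max() > self.k):
            raise ValueError("assignments must be labels in 1..k")


@dataclass
class StateMetrics:
    """Per subject x state temporal metrics and median state FC matrices."""

    dwell_time: pd.DataFrame            # seconds; NaN where state never visited
    fractional_occupancy: pd.DataFrame  # in [0, 1], rows sum to 1
    visited: pd.DataFrame               # bool
    subject_state_fc: dict[tuple[str, int], np.ndarray]  # (subject, state) -> edge vector


def select_exemplars(windows: np.ndarray, min_fallback: int = 8) -> tuple[np.ndarray, bool]:
    """Indices of one subject's windows at strict local maxima of feature variance.

    Per window the variance across its E edge features is computed; indices
    where that series is strictly greater than both neighbours are returned.
    A series with no interior maxima (monotone or constant) falls back to
    evenly spaced exemplars, flagged by the second return value.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim != 2 or w.shape[0] < 3:
        raise ValueError("need at least 3 windows per subject")
    var = w.var(axis=1)
    interior = np.arange(1, var.size - 1)
    is_max = (var[interior] > var[interior - 1]) & (var[interior] > var[interior + 1])
    idx = interior[is_max]
    if idx.size == 0:
        n = min(min_fallback, w.shape[0])
        idx = np.unique(np.linspace(0, w.shape[0] - 1, n).round().astype(int))
        logger.warning("no local variance maxima; falling back to %d evenly spaced exemplars", n)
        return idx, True
    return idx, False


def cluster_states(
    encoded: np.ndarray,
    encoded_exemplars: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 128,
    exemplar_max_iter: int = 1000,
    full_max_iter: int = 10_000,
) -> StateModel:
    """Two-stage exemplar-initialized k-means on encoded windows.

    Stage 1: ``n_init`` k-means++ repetitions on the exemplar windows keep the
    centroid set with the lowest sum of squared errors. Stage 2: those
    centroids initialize one k-means run over all windows.
    """
    encoded = np.asarray(encoded, dtype=float)
    exemplars = np.asarray(encoded_exemplars, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > exemplars.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of exemplar windows ({exemplars.shape[0]})"
        )
    if k == 1:
        centroid = encoded.mean(axis=0, keepdims=True)
        inertia = float(((encoded - centroid) ** 2).sum())
        return StateModel(1, centroid, np.ones(encoded.shape[0], dtype=int), inertia)
    stage1 = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init,
        max_iter=exemplar_max_iter, random_state=seed,
    ).fit(exemplars)
    stage2 = KMeans(
        n_clusters=k, init=stage1.cluster_centers_, n_init=1,
        max_iter=full_max_iter, random_state=seed,
    ).fit(encoded)
    return StateModel(
        k=k,
        centroids=stage2.cluster_centers_,
        assignments=stage2.labels_ + 1,
        inertia=float(stage2.inertia_),
    )


def within_between_ratio(encoded: np.ndarray, model: StateModel) -> float:
    """Mean point-to-own-centroid distance over mean pairwise centroid distance."""
    d_within = np.linalg.norm(
        encoded - model.centroids[model.assignments - 1], axis=1
    ).mean()
    cc = model.centroids
    iu = np.triu_indices(model.k, k=1)
    d_between = np.linalg.norm(cc[iu[0]] - cc[iu[1]], axis=1).mean()
    return float(d_within / d_between)


def elbow_select_k(
    encoded: np.ndarray,
    encoded_exemplars: np.ndarray,
    k_range: range = range(2, 10),
    seed: int = 0,
    confidence_threshold: float = 1 / 3,
    **cluster_kwargs,
) -> tuple[int, dict[int, float], dict[int, StateModel], bool]:
    """Choose the number of states at the elbow of the within/between ratio curve.

    The ratio r(k) (mean within-cluster distance / mean between-centroid
    distance) decreases with k. The elbow is the interior k whose point lies
    furthest below the chord joining the curve's endpoints — the standard
    maximum-distance-to-chord (kneedle) formalization. (A maximum-second-
    difference rule was considered and rejected: on the smooth convex curves
    that overlapping sliding windows produce, the discrete curvature always
    peaks at the first interior k, regardless of where the true bend is.)
    If the ratio rises immediately after the smallest candidate — splitting a
    true cluster pushes centroids together — that smallest k is the elbow.
    Confidence: the bow depth (maximal distance below the chord) must exceed
    ``confidence_threshold`` of the curve's range; a featureless smoothly
    decaying curve (no real cluster structure) bows less than that and the
    selection is flagged low-confidence (returned flag False).

    Returns (k, ratio curve, fitted models, confident).
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate values of k")
    models: dict[int, StateModel] = {}
    ratios: dict[int, float] = {}
    for k in ks:
        m = cluster_states(encoded, encoded_exemplars, k, seed=seed, **cluster_kwargs)
        ratios[k] = within_between_ratio(encoded, m)
        models[k] = m
    r = np.array([ratios[k] for k in ks])
    span = float(r.max() - r.min())
    if r[0] < r[1]:
        # the ratio rises as soon as a true cluster is split: the smallest
        # candidate is itself the elbow (chord distance cannot flag endpoints)
        k_sel = ks[0]
        confident = span > 0 and float(r[1] - r[0]) > confidence_threshold * span
        return k_sel, ratios, models, confident
    # distance below the chord from (ks[0], r[0]) to (ks[-1], r[-1])
    chord = r[0] + (r[-1] - r[0]) * (np.array(ks) - ks[0]) / (ks[-1] - ks[0])
    below = chord - r
    best_interior = 1 + int(np.argmax(below[1:-1]))
    k_sel = ks[best_interior]
    confident = span > 0 and float(below[best_interior]) > confidence_threshold * span
    return k_sel, ratios, models, confident


def _run_lengths(labels: np.ndarray) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    for b, e in zip(starts, ends):
        out.setdefault(int(labels[b]), []).append(int(e - b))
    return out


def state_metrics(
    assignments: dict[str, np.ndarray],
    spec: WindowSpec,
    k: int,
    windowed: dict[str, WindowedFC] | None = None,
) -> StateMetrics:
    """Dwell time, fractional occupancy and median state FC per subject.

    Dwell time of a state = mean contiguous run length of its label times the
    window step duration (seconds); fractional occupancy = fraction of windows
    assigned to it. States a subject never visits get occupancy 0 and
    undefined (NaN) dwell time — they are not imputed as zero. When
    ``windowed`` is given, the element-wise median of each subject's windows
    in each visited state is returned as that subject's state FC.
    """
    subjects = list(assignments)
    states = list(range(1, k + 1))
    dwell = pd.DataFrame(np.nan, index=subjects, columns=[f"state_{s}" for s in states])
    occ = pd.DataFrame(0.0, index=subjects, columns=[f"state_{s}" for s in states])
    vis = pd.DataFrame(False, index=subjects, columns=[f"state_{s}" for s in states])
    med: dict[tuple[str, int], np.ndarray] = {}
    for sid in subjects:
        labels = np.asarray(assignments[sid])
        runs = _run_lengths(labels)
        for s in states:
            col = f"state_{s}"
            n_in_state = int((labels == s).sum())
            occ.loc[sid, col] = n_in_state / labels.size
            if n_in_state:
                vis.loc[sid, col] = True
                dwell.loc[sid, col] = float(np.mean(runs[s])) * spec.step_seconds
                if windowed is not None:
                    med[(sid, s)] = np.median(
                        windowed[sid].windows[labels == s], axis=0
                    )
    return StateMetrics(
        dwell_time=dwell, fractional_occupancy=occ, visited=vis, subject_state_fc=med
    )


def match_states(
    estimated: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of estimated to reference state vectors by correlation.

    Both inputs are (k x features). Returns (permutation, matched absolute
    correlations): permutation[j] is the estimated row assigned to reference
    row j.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    k_ref = ref.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ref, est)[:k_ref, k_ref:]
    corr = np.nan_to_num(corr)  # constant vectors have undefined correlation
    row, col = linear_sum_assignment(-np.abs(corr))
    return col, np.abs(corr[row, col])
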