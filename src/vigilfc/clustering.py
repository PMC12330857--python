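"""Two-state decomposition of windowed FC maps by city-block k-medians,
silhouette-based model selection, and the state-vs-vigilance test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score

from .inference import CorrelationSample, LmeFit, ModelError, fit_lme_two_state


@dataclass
class ClusterAssignment:
    labels: np.ndarray        # per-window state label in 1..k
    centroids: np.ndarray     # k x d component-wise medians
    inertia: float            # summed city-block distance to own centroid
    k: int
    seed: int | None


@dataclass
class StateVigilanceSummary:
    state_means: dict[int, float]
    fit: LmeFit
    proportions: dict[int, dict[str, float]]  # per state: alert/int/drowsy


def _lloyd_l1(X: np.ndarray, init_idx: np.ndarray, max_iter: int,
              rng) -> tuple[np.ndarray, np.ndarray, float]:
    k = len(init_idx)
    centroids = X[init_idx].copy()
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d = cdist(X, centroids, metric="cityblock")
        new_labels = d.argmin(axis=1)
        for c in range(k):
            members = new_labels == c
            if not members.any():   # re-seed empty cluster at farthest point
                far = d.min(axis=1).argmax()
                centroids[c] = X[far]
                new_labels[far] = c
                members = new_labels == c
            centroids[c] = np.median(X[members], axis=0)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    d = cdist(X, centroids, metric="cityblock")
    labels = d.argmin(axis=1)
    inertia = float(d[np.arange(len(labels)), labels].sum())
    return labels, centroids, inertia


def kmedians_cluster(window_maps: np.ndarray, k: int = 2,
                     restarts: int = 20, seed=0,
                     max_iter: int = 200) -> ClusterAssignment:
    """Lloyd-style k-medians (L1 distance, component-wise median
    centroids); best of ``restarts`` random initializations by inertia.
    """
    X = np.asarray(window_maps, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available windows")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(restarts):
        init = rng.choice(n, size=k, replace=False)
        labels, centroids, inertia = _lloyd_l1(X, init, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    return ClusterAssignment(labels=labels + 1, centroids=centroids,
                             inertia=inertia, k=k, seed=seed)


def silhouette_select_k(window_maps: np.ndarray, k_range=range(2, 7),
                        seed=0, restarts: int = 10
                        ) -> tuple[int, dict[int, float]]:
    """Mean silhouette width under city-block distance per k; argmax."""
    X = np.asarray(window_maps, dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all windows identical")
    scores = {}
    for k in k_range:
        if k > len(X) - 1:
            continue
        labels = kmedians_cluster(X, k=k, restarts=restarts, seed=seed).labels
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(X, labels, metric="cityblock"))
    if not scores:
        raise ValueError("k_range too large for the available windows")
    best_k = max(scores, key=scores.get)
    return best_k, scores


def canonicalize_states(assignment: ClusterAssignment,
                        metric: np.ndarray) -> ClusterAssignment:
    """Renumber states so higher numbers have lower mean vigilance metric
    (state 2 is the drowsier one for k = 2)."""
    metric = np.asarray(metric, dtype=float)
    means = {s: np.nanmean(metric[assignment.labels == s])
             for s in np.unique(assignment.labels)}
    order = sorted(means, key=means.get, reverse=True)  # descending metric
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[s] for s in assignment.labels])
    centroids = assignment.centroids[[o - 1 for o in order]]
    return ClusterAssignment(labels=labels, centroids=centroids,
                             inertia=assignment.inertia, k=assignment.k,
                             seed=assignment.seed)


def state_vigilance_test(assignment: ClusterAssignment, metric: np.ndarray,
                         subject_ids, z_thresh: float = 1.5
                         ) -> StateVigilanceSummary:
    """Two-state LME of the per-window vigilance metric on the
    (canonicalized) state label, with a subject random intercept.

    Also reports per-state alert/intermediate/drowsy proportions from
    thresholding the metric at +/- ``z_thresh``.
    """
    metric = np.asarray(metric, dtype=float)
    labels = assignment.labels
    states = np.unique(labels)
    if len(states) < 2:
        raise ModelError("assignment contains a single state")
    if len(states) > 2:
        raise ModelError("vigilance test defined for two states")
    canon = canonicalize_states(assignment, metric)
    labels = canon.labels
    samples = [
        CorrelationSample(r=float(metric[i]), subject_id=str(subject_ids[i]),
                          state=int(labels[i] == 2))
        for i in range(len(metric))
    ]
    fit = fit_lme_two_state(samples)
    state_means = {int(s): float(np.nanmean(metric[labels == s]))
                   for s in (1, 2)}
    proportions = {}
    for s in (1, 2):
        m = metric[labels == s]
        proportions[int(s)] = {
            "alert": float(np.mean(m > z_thresh)),
            "drowsy": float(np.mean(m < -z_thresh)),
            "intermediate": float(np.mean((m >= -z_thresh) & (m <= z_thresh))),
        }
    return StateVigilanceSummary(state_means=state_means, fit=fit,
                                 proportions=proportions)
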