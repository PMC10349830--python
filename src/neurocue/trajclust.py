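"""Trajectory k-means: cluster entities (contacts or RNN units) by their
temporal trajectories across a condition space.

Each entity is represented by its condition x time matrix of trial-averaged,
z-scored activity (the z-score is taken per entity over the concatenated
values of all conditions and timepoints).  The distance between two
trajectories is the sum of time-point-by-time-point Manhattan distances
across conditions — an order-preserving L1 distance, with no temporal
warping.  Lloyd iterations therefore use the element-wise *median* as the
centroid update (the L1-optimal center); the best of ``n_restarts`` random
restarts by within-cluster inertia is returned, and the number of clusters
is selected by the mean silhouette score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples as _sk_silhouette_samples


@dataclass
class ConditionTrajectory:
    """One entity's z-scored condition x time activity matrix."""

    entity_id: str
    matrix: np.ndarray              # (n_conditions, n_times)
    condition_labels: list[str]
    times_ms: np.ndarray


@dataclass
class ClusterSolution:
    """A fitted trajectory k-means partition."""

    k: int
    assignments: np.ndarray         # entity -> cluster index
    centroids: np.ndarray           # (k, n_conditions, n_times)
    inertia: float
    silhouette_mean: float
    silhouette_values: np.ndarray
    seed: int
    n_restarts: int
    n_iter: int = 0

    def members(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.assignments == cluster)[0]

    def to_json(self) -> str:
        return json.dumps({
            "k": self.k, "seed": self.seed, "n_restarts": self.n_restarts,
            "inertia": self.inertia, "silhouette_mean": self.silhouette_mean,
            "assignments": self.assignments.tolist(),
        })


class MissingCellError(ValueError):
    pass


def zscore_trajectory(matrix: np.ndarray) -> np.ndarray:
    """z-score over the concatenated conditions x time values; a
    zero-variance entity maps to all zeros rather than NaN."""
    m = np.asarray(matrix, dtype=float)
    sd = m.std()
    if sd == 0:
        return np.zeros_like(m)
    return (m - m.mean()) / sd


def build_trajectories(cond_means: np.ndarray, entity_ids: list[str],
                       condition_labels: list[str],
                       times_ms: np.ndarray,
                       window_ms: tuple[float, float] | None = None,
                       zscore: bool = True) -> list[ConditionTrajectory]:
    """Build per-entity condition trajectories from trial-averaged activity.

    ``cond_means`` is (n_entities, n_conditions, n_times).  Cells containing
    NaN (an empty condition cell) raise :class:`MissingCellError` naming the
    entity and cell.  If ``window_ms`` is given the time axis is restricted
    before z-scoring.
    """
    cond_means = np.asarray(cond_means, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    if window_ms is not None:
        sel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
        cond_means = cond_means[..., sel]
        times_ms = times_ms[sel]
    out = []
    for i, eid in enumerate(entity_ids):
        m = cond_means[i]
        if np.isnan(m).any():
            c = int(np.nonzero(np.isnan(m).any(axis=1))[0][0])
            raise MissingCellError(
                f"entity {eid!r} has an empty condition cell {condition_labels[c]!r}")
        out.append(ConditionTrajectory(
            eid, zscore_trajectory(m) if zscore else m,
            list(condition_labels), times_ms))
    return out


def trajectories_from_contacts(ds, window_ms=None) -> list[ConditionTrajectory]:
    """Eight-condition (2x2x2) trajectories from a :class:`ContactDataset`."""
    from .synth import SIDE_LEVELS, VALIDITY_LEVELS, REPORT_LEVELS
    m = ds.condition_means()                    # (n, 2, 2, 2, T)
    n = m.shape[0]
    labels = [f"{s}/{v}/{r}" for s in SIDE_LEVELS for v in VALIDITY_LEVELS
              for r in REPORT_LEVELS]
    flat = m.reshape(n, 8, -1)
    return build_trajectories(flat, ds.contact_ids, labels, ds.times_ms,
                              window_ms=window_ms)


def trajectory_distance(a, b) -> float:
    """Sum over conditions and timepoints of absolute differences."""
    am = a.matrix if isinstance(a, ConditionTrajectory) else np.asarray(a)
    bm = b.matrix if isinstance(b, ConditionTrajectory) else np.asarray(b)
    if am.shape != bm.shape:
        raise ValueError(f"shape mismatch {am.shape} vs {bm.shape}")
    return float(np.abs(am - bm).sum())


def _stack(trajectories: list[ConditionTrajectory]) -> np.ndarray:
    return np.stack([t.matrix.ravel() for t in trajectories])


def _assign(X: np.ndarray, centroids: np.ndarray):
    """Nearest-centroid assignment under the L1 trajectory distance; ties
    break deterministically to the lowest cluster index."""
    D = cdist(X, centroids, metric="cityblock")
    labels = D.argmin(axis=1)
    return labels, D[np.arange(len(X)), labels].sum()


def fit_kmeans(trajectories: list[ConditionTrajectory], k: int,
               n_restarts: int = 20, max_iter: int = 300,
               seed: int = 0, centroid_update: str = "median") -> ClusterSolution:
    """L1 trajectory k-means, best of ``n_restarts`` random restarts.

    Lloyd alternation with Manhattan distance and element-wise median
    centroid update (``centroid_update='mean'`` is available as a dialect).
    Empty clusters are repaired by re-seeding their centroid at the entity
    farthest from its assigned centroid.  Deterministic under ``seed``.
    """
    X = _stack(trajectories)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds n_entities={n}")
    if centroid_update not in ("median", "mean"):
        raise ValueError("centroid_update must be 'median' or 'mean'")
    update = np.median if centroid_update == "median" else np.mean
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(n_restarts):
        centroids = X[rng.choice(n, size=k, replace=False)].copy()
        labels, inertia = _assign(X, centroids)
        prev_inertia = np.inf
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            for c in range(k):
                mask = labels == c
                if mask.any():
                    centroids[c] = update(X[mask], axis=0)
                else:  # repair: farthest entity becomes the new centroid
                    D = cdist(X, centroids, metric="cityblock")
                    far = D[np.arange(n), D.argmin(axis=1)].argmax()
                    centroids[c] = X[far]
            new_labels, inertia = _assign(X, centroids)
            # L1-optimal updates never increase inertia
            assert inertia <= prev_inertia + 1e-9 * max(1.0, abs(prev_inertia))
            prev_inertia = inertia
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        if best is None or inertia < best[1]:
            best = (labels.copy(), inertia, centroids.copy(), n_iter)

    labels, inertia, centroids, n_iter = best
    shape = trajectories[0].matrix.shape
    if 2 <= len(np.unique(labels)) <= n - 1:
        sil_vals = silhouette_values(trajectories, labels)
        sil_mean = float(sil_vals.mean())
    else:
        sil_vals = np.full(n, np.nan)
        sil_mean = float("nan")
    return ClusterSolution(k, labels, centroids.reshape(k, *shape),
                           float(inertia), sil_mean, sil_vals,
                           seed, n_restarts, n_iter)


def silhouette_values(trajectories: list[ConditionTrajectory],
                      assignments: np.ndarray) -> np.ndarray:
    """Per-entity silhouette s(i) = (b - a)/max(a, b) under the trajectory
    (Manhattan) distance.  Requires >= 2 non-empty clusters."""
    labels = np.asarray(assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    return _sk_silhouette_samples(_stack(trajectories), labels, metric="cityblock")


def silhouette(trajectories: list[ConditionTrajectory],
               assignments: np.ndarray) -> tuple[np.ndarray, float]:
    vals = silhouette_values(trajectories, assignments)
    return vals, float(vals.mean())


@dataclass
class SelectKResult:
    best_k: int
    solutions: dict[int, ClusterSolution]
    silhouettes: dict[int, float]
    stability: pd.DataFrame = field(default=None, repr=False)


def select_k(trajectories: list[ConditionTrajectory],
             k_range=range(2, 13), n_restarts: int = 20,
             max_iter: int = 300, seed: int = 0) -> SelectKResult:
    """Sweep k, select the solution with the highest mean silhouette, and
    report cluster-membership stability (Jaccard overlap of best-matching
    clusters between consecutive k solutions)."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    solutions, sils = {}, {}
    for i, k in enumerate(k_range):
        sol = fit_kmeans(trajectories, k, n_restarts=n_restarts,
                         max_iter=max_iter, seed=seed + 1000 * i)
        solutions[k] = sol
        sils[k] = sol.silhouette_mean
    best_k = max(sils, key=lambda k: (sils[k], -k))
    rows = []
    for k0, k1 in zip(k_range[:-1], k_range[1:]):
        a, b = solutions[k0], solutions[k1]
        for c in range(k0):
            ma = set(a.members(c).tolist())
            if not ma:
                continue
            best_j = max(
                (len(ma & set(b.members(c2).tolist()))
                 / len(ma | set(b.members(c2).tolist()))
                 for c2 in range(k1) if len(b.members(c2))), default=0.0)
            rows.append({"k_from": k0, "k_to": k1, "cluster": c,
                         "jaccard": best_j, "size": len(ma)})
    return SelectKResult(best_k, solutions, sils, pd.DataFrame(rows))
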