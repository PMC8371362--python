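"""K-means over Big-Five personality vectors (macro level).

Plain Lloyd iterations: nearest-centroid assignment by squared
Euclidean distance, centroid update as the member mean, repeated until
the assignment is stable.  Restarts keep the lowest-distortion fit.
Utilities for the elbow curve over candidate cluster counts and for
routing held-out subjects to their nearest fitted centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PersonalityProfile",
    "ClusterFit",
    "fit_kmeans",
    "elbow_curve",
    "assign_cluster",
]

PERSONALITY_DIM = 5  # O, C, E, A, N


@dataclass(frozen=True)
class PersonalityProfile:
    subject_id: str
    p: tuple  # 5 OCEAN scores

    def __post_init__(self):
        vec = np.asarray(self.p, dtype=np.float64)
        if vec.shape != (PERSONALITY_DIM,) or not np.all(np.isfinite(vec)):
            raise ValueError("personality must be 5 finite components (O,C,E,A,N)")
        object.__setattr__(self, "p", tuple(float(v) for v in vec))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.p)


@dataclass
class ClusterFit:
    n_clusters: int
    centroids: np.ndarray            # (P, 5)
    assignment: dict[str, int]       # subject_id -> cluster index
    distortion: float                # sum of squared distances to assigned centroid
    n_iter: int
    seed: int


def _assign(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)  # argmin takes the lowest index on ties


def _distortion(X: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centroids[labels]) ** 2).sum())


def _lloyd(X: np.ndarray, P: int, rng: np.random.Generator, max_iter: int):
    n = X.shape[0]
    centroids = X[rng.choice(n, size=P, replace=False)].copy()
    labels = _assign(X, centroids)
    for it in range(1, max_iter + 1):
        for j in range(P):
            members = labels == j
            if members.any():
                centroids[j] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster with the point farthest from its centroid
                far = ((X - centroids[j]) ** 2).sum(axis=1).argmax()
                centroids[j] = X[far]
        new_labels = _assign(X, centroids)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return centroids, labels, it


def fit_kmeans(profiles, P: int, seed: int = 0, n_restarts: int = 10,
               max_iter: int = 300, standardize: bool = False) -> ClusterFit:
    """Best-of-restarts Lloyd fit on the subjects' OCEAN vectors.

    No feature scaling by default; ``standardize`` z-scores each
    dimension first (centroids are reported in the original units).
    """
    profiles = list(profiles)
    ids = [pr.subject_id for pr in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_ids in profiles")
    if not 1 <= P <= len(profiles):
        raise ValueError(f"need 1 <= P <= n_subjects, got P={P}, n={len(profiles)}")
    X = np.stack([pr.vector for pr in profiles])
    scale = np.ones(PERSONALITY_DIM)
    offset = np.zeros(PERSONALITY_DIM)
    if standardize:
        offset = X.mean(axis=0)
        scale = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Z = (X - offset) / scale
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        centroids, labels, n_iter = _lloyd(Z, P, rng, max_iter)
        dist = _distortion(Z, centroids, labels)
        if best is None or dist < best[0] - 1e-15:
            best = (dist, centroids, labels, n_iter)
    dist, centroids, labels, n_iter = best
    return ClusterFit(
        n_clusters=P,
        centroids=centroids * scale + offset,
        assignment={sid: int(lab) for sid, lab in zip(ids, labels)},
        distortion=dist,
        n_iter=n_iter,
        seed=seed,
    )


def elbow_curve(profiles, P_values, seed: int = 0, n_restarts: int = 10):
    """Distortion per candidate cluster count; shared seed policy."""
    profiles = list(profiles)
    P_values = list(P_values)
    if sorted(P_values) != P_values:
        raise ValueError("P_values must be sorted ascending")
    return [(P, fit_kmeans(profiles, P, seed=seed, n_restarts=n_restarts).distortion)
            for P in P_values]


def assign_cluster(fit: ClusterFit, profile: PersonalityProfile) -> int:
    """Nearest fitted centroid (squared Euclidean); ties -> lowest index."""
    d2 = ((fit.centroids - profile.vector) ** 2).sum(axis=1)
    return int(d2.argmin())
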