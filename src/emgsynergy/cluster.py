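"""Bootstrap confidence intervals for spatial and temporal modules via
repeated extraction and cannot-link constrained k-means.

Synergies are extracted many times from random cycle subsamples; the
resulting weight vectors are clustered with k-means under cosine distance
and a cannot-link constraint: the k synergies of one replicate may never
share a cluster.  The assignment step therefore solves, per replicate,
the optimal one-to-one matching of its synergies to the k centroids
(Hungarian algorithm), which satisfies the constraint by construction.
Percentile bounds across replicates give 95% CIs per matched cluster,
for both muscle weights and cycle-averaged activation profiles.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nmf
from .exceptions import ParameterError
from .features import temporal_profile
from .preprocess import normalize
from .types import CycleTensor


def replicate_extract(
    cycles: CycleTensor,
    N: int,
    n_boot: int = 1000,
    subsample: int = 20,
    seed=None,
    nmf_params: dict = None,
    divisor: str = "range",
):
    """Extract N synergies from ``n_boot`` random ``subsample``-cycle draws.

    Each replicate is normalized on its own subsample, factorized, and the
    unit-variance scaling reverted (weights multiplied by the replicate's
    per-muscle sigma).  Returns a list of SynergySet.
    """
    if subsample > cycles.n_cycles:
        raise ParameterError("subsample exceeds the available cycles")
    nmf_params = dict(
        dict(n_restarts=2, max_iter=500, tol=1e-5) if nmf_params is None else nmf_params
    )
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_boot):
        chosen = rng.choice(cycles.n_cycles, size=subsample, replace=False)
        norm = normalize(cycles.subset(chosen), divisor=divisor)
        S = nmf.extract(norm.matrix, N, seed=rng.integers(2**31), **nmf_params)
        replicates.append(nmf.rescale_weights(S, norm.sigma))
    return replicates


@dataclass
class ClusteredSynergies:
    """Constrained k-means solution over replicate synergies."""

    k: int
    assignments: np.ndarray  # (n_replicates, k): cluster id per synergy
    centroid_W: np.ndarray  # (n_muscles, k), unit-norm columns
    ci_W_low: np.ndarray  # (n_muscles, k) 2.5th percentile
    ci_W_high: np.ndarray  # 97.5th percentile
    centroid_C: np.ndarray  # (151, k) mean cycle-averaged activation
    ci_C_low: np.ndarray
    ci_C_high: np.ndarray
    total_distance: float  # final within-cluster cosine distance sum


def _normalized_mean(vectors: np.ndarray) -> np.ndarray:
    m = vectors.mean(axis=0)
    n = np.linalg.norm(m)
    return m / n if n > 0 else m


def constrained_kmeans(
    replicates, k: int, seed=None, max_iter: int = 100
) -> ClusteredSynergies:
    """Cannot-link k-means over replicate weight vectors.

    Distance is 1 - cosine similarity.  Initial centroids are the
    synergies of one randomly chosen replicate; each iteration assigns
    every replicate's synergies to centroids by optimal bipartite
    matching (so cluster ids within a replicate are always a
    permutation of 0..k-1), then recomputes centroids as normalized
    means.  Iterates until the assignment stabilizes.
    """
    for S in replicates:
        if S.N != k:
            raise ParameterError(
                f"every replicate must contribute exactly {k} synergies (got {S.N})"
            )
    # (R, k, m) unit vectors
    V = np.stack([(S.W / np.linalg.norm(S.W, axis=0)).T for S in replicates])
    R = V.shape[0]
    rng = np.random.default_rng(seed)
    centroids = V[rng.integers(R)].copy()  # (k, m)
    assignments = np.full((R, k), -1, dtype=int)
    total = np.inf
    for _ in range(max_iter):
        new_assignments = np.empty_like(assignments)
        new_total = 0.0
        for r in range(R):
            cost = 1.0 - V[r] @ centroids.T  # (k synergies, k centroids)
            rows, cols = linear_sum_assignment(cost)
            new_assignments[r, rows] = cols
            new_total += float(cost[rows, cols].sum())
        if np.array_equal(new_assignments, assignments):
            total = new_total
            break
        assignments, total = new_assignments, new_total
        for j in range(k):
            members = np.stack([V[r, np.where(assignments[r] == j)[0][0]] for r in range(R)])
            centroids[j] = _normalized_mean(members)

    profiles = np.stack([temporal_profile(S.C) for S in replicates])  # (R, k, 151)
    n_muscles = V.shape[2]
    centroid_W = np.empty((n_muscles, k))
    ci_W_low = np.empty((n_muscles, k))
    ci_W_high = np.empty((n_muscles, k))
    n_pts = profiles.shape[2]
    centroid_C = np.empty((n_pts, k))
    ci_C_low = np.empty((n_pts, k))
    ci_C_high = np.empty((n_pts, k))
    for j in range(k):
        idx = [np.where(assignments[r] == j)[0][0] for r in range(R)]
        w = np.stack([V[r, i] for r, i in enumerate(idx)])  # (R, m)
        p = np.stack([profiles[r, i] for r, i in enumerate(idx)])  # (R, 151)
        centroid_W[:, j] = _normalized_mean(w)
        ci_W_low[:, j] = np.percentile(w, 2.5, axis=0)
        ci_W_high[:, j] = np.percentile(w, 97.5, axis=0)
        centroid_C[:, j] = p.mean(axis=0)
        ci_C_low[:, j] = np.percentile(p, 2.5, axis=0)
        ci_C_high[:, j] = np.percentile(p, 97.5, axis=0)
    return ClusteredSynergies(
        k=k,
        assignments=assignments,
        centroid_W=centroid_W,
        ci_W_low=ci_W_low,
        ci_W_high=ci_W_high,
        centroid_C=centroid_C,
        ci_C_low=ci_C_low,
        ci_C_high=ci_C_high,
        total_distance=total,
    )
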