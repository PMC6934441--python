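"""Partitioning Around Medoids (PAM) with random restarts.

Classic BUILD + SWAP k-medoids on a precomputed distance matrix: BUILD
greedily seeds medoids to minimize total assignment cost (here replaced by
random seeding per restart, which with enough restarts explores more of the
solution space), then SWAP exchanges a medoid with a non-medoid whenever
the exchange lowers the total distance of points to their nearest medoid,
until no improving swap exists.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = ["pam"]


def _total_cost(dist: np.ndarray, medoids: np.ndarray) -> Tuple[float, np.ndarray]:
    sub = dist[:, medoids]
    assign = sub.argmin(axis=1)
    return float(sub.min(axis=1).sum()), medoids[assign]


def _swap_phase(dist: np.ndarray, medoids: np.ndarray, max_iter: int = 100) -> np.ndarray:
    n = dist.shape[0]
    medoids = medoids.copy()
    best_cost, _ = _total_cost(dist, medoids)
    for _ in range(max_iter):
        improved = False
        med_set = set(medoids.tolist())
        for mi in range(len(medoids)):
            for h in range(n):
                if h in med_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                cost, _ = _total_cost(dist, trial)
                if cost < best_cost - 1e-12:
                    best_cost = cost
                    medoids = trial
                    med_set = set(medoids.tolist())
                    improved = True
        if not improved:
            break
    return medoids


def pam(
    dist: np.ndarray,
    k: int,
    restarts: int = 20,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray, float]:
    """k-medoids on a symmetric distance matrix.

    Returns ``(labels, medoid_indices, total_cost)`` for the best of
    ``restarts`` randomly seeded SWAP runs.  Labels are 0..k-1 in order of
    the sorted medoid indices, so the labelling is deterministic for a
    given rng state.
    """
    n = dist.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    rng = np.random.default_rng() if rng is None else rng
    best: Tuple[float, np.ndarray] | None = None
    for _ in range(restarts):
        seed_medoids = rng.choice(n, size=k, replace=False)
        medoids = _swap_phase(dist, seed_medoids)
        cost, _ = _total_cost(dist, medoids)
        if best is None or cost < best[0] - 1e-12:
            best = (cost, np.sort(medoids))
    cost, medoids = best
    labels = dist[:, medoids].argmin(axis=1)
    return labels, medoids, cost
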