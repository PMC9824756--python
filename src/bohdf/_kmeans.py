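"""Lloyd's k-means with greedy farthest-point seeding.

Implemented in-package because the vocabulary construction is part of the
method's contract: the objective (within-cluster sum of squared distances)
must be observably non-increasing across iterations and the final assignment
must satisfy the nearest-centroid argmin, with deterministic lowest-index
tie-breaking.  The per-iteration inertia history is recorded for exactly
that audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KMeansResult:
    centroids: np.ndarray          # (k, d)
    labels: np.ndarray             # (n,)
    inertia: float
    inertia_history: list[float]   # objective after each assignment step
    n_iter: int


def _pairwise_sq(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances (n, k); clipped at zero against rounding."""
    d = (X * X).sum(1)[:, None] - 2.0 * X @ C.T + (C * C).sum(1)[None, :]
    return np.maximum(d, 0.0)


def _greedy_seed(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Spread-maximising seeding: a random first centre, then repeatedly the
    point farthest from its nearest chosen centre (lowest index on ties)."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d_min = _pairwise_sq(X, X[chosen])[:, 0]
    while len(chosen) < k:
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, _pairwise_sq(X, X[[nxt]])[:, 0])
    return X[chosen].copy()


def kmeans(X: np.ndarray, k: int, seed: int = 0, max_iter: int = 300,
           tol: float = 1e-6) -> KMeansResult:
    """Cluster rows of X into k groups.

    Convergence: maximum centroid displacement below ``tol`` relative to the
    data scale, or ``max_iter`` iterations.  Empty clusters are reseeded at
    the point farthest from its assigned centroid.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n_samples, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    C = _greedy_seed(X, k, rng)
    scale = max(1.0, float(np.abs(X).max()))
    history: list[float] = []
    labels = np.zeros(n, dtype=np.int64)
    for it in range(max_iter):
        d = _pairwise_sq(X, C)
        labels = np.argmin(d, axis=1)          # argmin takes the lowest index on ties
        history.append(float(d[np.arange(n), labels].sum()))
        new_C = C.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_C[j] = X[members].mean(axis=0)
            else:
                new_C[j] = X[int(np.argmax(d[np.arange(n), labels]))]
        shift = float(np.abs(new_C - C).max())
        C = new_C
        if shift < tol * scale:
            break
    d = _pairwise_sq(X, C)
    labels = np.argmin(d, axis=1)
    inertia = float(d[np.arange(n), labels].sum())
    history.append(inertia)
    return KMeansResult(centroids=C, labels=labels, inertia=inertia,
                        inertia_history=history, n_iter=len(history) - 1)
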