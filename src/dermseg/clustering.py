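"""K-means and fuzzy C-means on per-pixel feature vectors.

K-means alternates the argmin assignment

    i = argmin_k ||x_j - m_k||^2

with the centroid update m_i = mean{x_j : x_j in C_i}.  Fuzzy C-means (FCM)
replaces the hard assignment with graded memberships mu_ij in [0, 1]
(columns summing to 1 over clusters) and minimizes

    E = sum_j sum_i mu_ij^k ||x_i - c_j||^2,

alternating the closed-form membership update

    mu_ij = 1 / sum_m (||x_i - c_j|| / ||x_i - c_m||)^(2/(k-1))

with the mu^k-weighted center update.  The fuzziness exponent k > 1 controls
membership softness (k -> 1 approaches hard clustering; default 2).

Determinism conventions, fixed so repeated runs are bit-identical:

- argmin ties go to the lowest cluster index;
- default K-means initialization is farthest-point seeding started from the
  point closest to the global mean (no randomness; the ``seed`` argument only
  matters for the optional randomized-restart initialization);
- default FCM initialization places centers equidistantly across the data
  range (the same seeding the cluster-preselection stage uses);
- an emptied K-means cluster is re-seeded at the point farthest from its
  centroid;
- a point coinciding with one or more centers splits its membership uniformly
  over the coinciding centers (the limiting case of the update).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KMeansResult",
    "FCMState",
    "kmeans",
    "fcm",
    "fcm_membership",
    "fcm_centers",
    "fcm_objective",
]


@dataclass
class KMeansResult:
    centroids: np.ndarray  # (K, d)
    assignment: np.ndarray  # (N,) cluster indices, 0-based
    iterations: int
    inertia: float  # within-cluster sum of squares at convergence


@dataclass
class FCMState:
    memberships: np.ndarray  # (C, N), columns sum to 1
    centers: np.ndarray  # (C, d)
    fuzziness: float
    objective: float
    iterations: int
    objective_history: np.ndarray  # E after every iteration, non-increasing


def _as_points(points: np.ndarray) -> np.ndarray:
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError(f"points must be a non-empty N x d array, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("points contain non-finite values")
    return X


def _sq_dists(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """(C, N) squared Euclidean distances."""
    diff = centers[:, None, :] - X[None, :, :]
    return np.einsum("cnd,cnd->cn", diff, diff)


def _farthest_point_init(X: np.ndarray, K: int) -> np.ndarray:
    """Deterministic seeding: start at the point closest to the global mean,
    then repeatedly add the point farthest from its nearest chosen seed."""
    mean = X.mean(axis=0)
    first = int(np.argmin(((X - mean) ** 2).sum(axis=1)))
    chosen = [first]
    for _ in range(1, K):
        d = _sq_dists(X[chosen], X).min(axis=0)
        chosen.append(int(np.argmax(d)))
    return X[chosen].copy()


def kmeans(
    points: np.ndarray,
    K: int,
    init_centroids: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
    n_restarts: int = 0,
) -> KMeansResult:
    """Lloyd's K-means with deterministic conventions.

    Stops when no centroid moves more than ``tol`` (Euclidean) or after
    ``max_iter`` iterations.  ``n_restarts > 0`` adds that many runs from
    random point subsets drawn with ``seed``, keeping the lowest-inertia
    result; the default is the single deterministic run.
    """
    X = _as_points(points)
    N = X.shape[0]
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > N:
        raise ValueError(f"K={K} exceeds the number of points N={N}")

    def one_run(centroids: np.ndarray) -> KMeansResult:
        c = np.array(centroids, dtype=float, copy=True)
        if c.shape != (K, X.shape[1]):
            raise ValueError(f"init centroids must be {K} x {X.shape[1]}, got {c.shape}")
        labels = np.zeros(N, dtype=int)
        for it in range(1, max_iter + 1):
            labels = np.argmin(_sq_dists(X, c), axis=0)  # argmin -> lowest index on ties
            new_c = c.copy()
            for k in range(K):
                members = labels == k
                if members.any():
                    new_c[k] = X[members].mean(axis=0)
                else:
                    far = int(np.argmax(((X - c[k]) ** 2).sum(axis=1)))
                    new_c[k] = X[far]
            shift = np.sqrt(((new_c - c) ** 2).sum(axis=1)).max()
            c = new_c
            if shift <= tol:
                break
        labels = np.argmin(_sq_dists(X, c), axis=0)
        inertia = float(((X - c[labels]) ** 2).sum())
        return KMeansResult(centroids=c, assignment=labels, iterations=it, inertia=inertia)

    if init_centroids is not None:
        return one_run(np.asarray(init_centroids, dtype=float))

    best = one_run(_farthest_point_init(X, K))
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            idx = rng.choice(N, size=K, replace=False)
            cand = one_run(X[idx])
            if cand.inertia < best.inertia:
                best = cand
    return best


def fcm_membership(points: np.ndarray, centers: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Closed-form membership update; columns sum to 1.

    Points coinciding with a center get the limiting memberships: uniform
    over all coinciding centers, zero elsewhere.
    """
    if k <= 1:
        raise ValueError(f"fuzziness k must be > 1, got {k}")
    X = _as_points(points)
    C = np.atleast_2d(np.asarray(centers, dtype=float))
    if C.shape[1] != X.shape[1]:
        C = C.reshape(-1, X.shape[1])
    d2 = _sq_dists(X, C)  # (C, N)
    zero = d2 == 0.0
    hit = zero.any(axis=0)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (k - 1.0))
    inv[:, hit] = 0.0
    u = np.where(hit[None, :], zero / np.maximum(zero.sum(axis=0), 1), 0.0)
    ok = ~hit
    u[:, ok] = inv[:, ok] / inv[:, ok].sum(axis=0)
    return u


def fcm_centers(
    points: np.ndarray,
    memberships: np.ndarray,
    k: float = 2.0,
    prev_centers: np.ndarray | None = None,
) -> np.ndarray:
    """mu^k-weighted means of the points, one per cluster.

    A cluster whose memberships are identically zero (degenerate input) is
    re-seeded at the point farthest from its previous center, or from the
    global mean when no previous centers are known.
    """
    X = _as_points(points)
    U = np.asarray(memberships, dtype=float)
    w = U**k
    denom = w.sum(axis=1)
    centers = np.empty((U.shape[0], X.shape[1]))
    for j in range(U.shape[0]):
        if denom[j] > 0:
            centers[j] = w[j] @ X / denom[j]
        else:
            ref = prev_centers[j] if prev_centers is not None else X.mean(axis=0)
            centers[j] = X[int(np.argmax(((X - ref) ** 2).sum(axis=1)))]
    return centers


def fcm_objective(
    points: np.ndarray,
    memberships: np.ndarray,
    centers: np.ndarray,
    k: float = 2.0,
) -> float:
    """E = sum_ij mu_ij^k ||x_i - c_j||^2 (nonnegative)."""
    X = _as_points(points)
    U = np.asarray(memberships, dtype=float)
    C = np.asarray(centers, dtype=float).reshape(U.shape[0], -1)
    return float((U**k * _sq_dists(X, C)).sum())


def _equidistant_init(X: np.ndarray, C: int) -> np.ndarray:
    """Centers spread evenly across each coordinate's range: the j-th center
    sits at lo + j * (hi - lo) / C per dimension, j = 1..C."""
    lo, hi = X.min(axis=0), X.max(axis=0)
    j = np.arange(1, C + 1)[:, None]
    return lo[None, :] + j * (hi - lo)[None, :] / C


def fcm(
    points: np.ndarray,
    C: int,
    k: float = 2.0,
    init_centers: np.ndarray | None = None,
    seed: int = 0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> FCMState:
    """Alternate membership and center updates until |dE| <= tol.

    The objective is recorded after every full iteration and is
    non-increasing.  Deterministic: the default initialization is the
    equidistant-range seeding, and every update is closed-form.
    """
    X = _as_points(points)
    if C < 1:
        raise ValueError(f"C must be >= 1, got {C}")
    if C > X.shape[0]:
        raise ValueError(f"C={C} exceeds the number of points N={X.shape[0]}")
    if k <= 1:
        raise ValueError(f"fuzziness k must be > 1, got {k}")
    centers = (
        np.asarray(init_centers, dtype=float).reshape(C, X.shape[1])
        if init_centers is not None
        else _equidistant_init(X, C)
    )
    history: list[float] = []
    U = fcm_membership(X, centers, k)
    for it in range(1, max_iter + 1):
        centers = fcm_centers(X, U, k, prev_centers=centers)
        U = fcm_membership(X, centers, k)
        E = fcm_objective(X, U, centers, k)
        history.append(E)
        if it > 1 and abs(history[-2] - E) <= tol:
            break
    return FCMState(
        memberships=U,
        centers=centers,
        fuzziness=k,
        objective=history[-1],
        iterations=it,
        objective_history=np.asarray(history),
    )
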