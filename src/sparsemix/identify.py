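"""Model identification via the point-process representation.

The mixture likelihood is invariant under permutations of the component
labels, so raw MCMC draws are unidentified component-wise.  Viewing the
per-sweep set of component-mean draws as an unordered point set (the
point-process representation) removes the labeling: the identification
pipeline

1. keeps only sweeps whose number of non-empty components equals the
   estimated ``K_hat`` and drops draws from empty components,
2. clusters the stacked mean draws into ``K_hat`` groups by K-centroids
   with cluster-specific Mahalanobis distances (which captures elongated,
   elliptical posterior clouds that Euclidean K-means splits),
3. relabels every sweep whose ``K_hat`` draws land in ``K_hat`` distinct
   clusters; sweeps where the assignment is not a permutation are
   discarded, and their fraction ``M0_rho`` (the non-permutation rate) is
   a diagnostic of how well-separated the component posteriors are.

Only the means are clustered; the resulting classification is propagated
to the covariance and weight draws and to the allocations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import linalg

from .sampler import Trace

__all__ = [
    "PointProcessSample",
    "CentroidSet",
    "IdentifiedPosterior",
    "extract_point_process",
    "k_centroids_mahalanobis",
    "relabel_trace",
    "final_partition",
]


@dataclass
class PointProcessSample:
    """Stacked non-empty component-mean draws with provenance."""

    points: np.ndarray  # (K_hat * M0, r)
    sweep_index: np.ndarray  # (K_hat * M0,)
    component: np.ndarray  # (K_hat * M0,) original component label
    sweeps: np.ndarray  # (M0,) contributing sweep indices
    K_hat: int

    @property
    def M0(self) -> int:
        return self.sweeps.shape[0]


@dataclass
class CentroidSet:
    """Centroids, dispersion matrices and the induced assignment.

    ``objective`` is the sum of assigned Mahalanobis distances;
    ``objective_scaled`` additionally weights each distance by
    ``det(S_k)^{1/(2n)}``, which removes the scale degeneracy of the raw
    sum (inflating a dispersion matrix shrinks all its distances) and is
    the criterion used to compare restarts.
    """

    centroids: np.ndarray  # (K, n)
    dispersions: np.ndarray  # (K, n, n)
    assignment: np.ndarray  # (N_points,)
    objective: float
    objective_scaled: float = float("nan")
    objective_path: Optional[np.ndarray] = None


@dataclass
class IdentifiedPosterior:
    """Relabeled draw subset and the final partition of the observations."""

    mu: np.ndarray  # (M_tilde, K_hat, r)
    Sigma: np.ndarray  # (M_tilde, K_hat, r, r)
    eta: np.ndarray  # (M_tilde, K_hat)
    S: Optional[np.ndarray]  # (M_tilde, N) relabeled allocations
    sweeps: np.ndarray  # retained sweep indices
    M0: int
    M0_rho: float

    @property
    def M_tilde(self) -> int:
        return self.mu.shape[0]


# ---------------------------------------------------------------------------


def extract_point_process(trace: Trace, K_hat: int) -> PointProcessSample:
    """Stack the mean draws of non-empty components from sweeps with
    exactly ``K_hat`` non-empty components."""
    K0 = np.asarray(trace.K0)
    sweeps = np.flatnonzero(K0 == K_hat)
    if sweeps.size == 0:
        raise ValueError(f"no sweeps at the estimated K0 = {K_hat}")
    nonempty = trace.Nk[sweeps] > 0  # (M0, K)
    sweep_index = np.repeat(sweeps, K_hat)
    component = np.nonzero(nonempty)[1]
    points = trace.mu[sweeps][nonempty]  # row-major: sweep-by-sweep
    return PointProcessSample(
        points=points,
        sweep_index=sweep_index,
        component=component,
        sweeps=sweeps,
        K_hat=K_hat,
    )


# ---------------------------------------------------------------------------
# Mahalanobis K-centroids
# ---------------------------------------------------------------------------


def _mahalanobis_distances(
    points: np.ndarray, centroids: np.ndarray, dispersions: np.ndarray
) -> np.ndarray:
    """(N, K) matrix of (unsquared) Mahalanobis distances."""
    N = points.shape[0]
    K = centroids.shape[0]
    D = np.empty((N, K))
    for k in range(K):
        L = linalg.cholesky(dispersions[k], lower=True)
        dev = linalg.solve_triangular(L, (points - centroids[k]).T, lower=True)
        D[:, k] = np.sqrt(np.einsum("ji,ji->i", dev, dev))
    return D


def _regularize(S: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    n = S.shape[0]
    tr = np.trace(S)
    if tr <= 0:
        return np.eye(n) * eps
    return S + eps * tr / n * np.eye(n)


def _farthest_point_seed(points: np.ndarray, K: int, start: int) -> np.ndarray:
    """Greedy farthest-point centroid seeding (Euclidean).

    The first seed is the ``start``-th farthest point from the overall
    centroid, which makes the seeding deterministic and independent of
    the ordering of the input points.
    """
    order = np.argsort(-np.linalg.norm(points - points.mean(axis=0), axis=1))
    idx = [int(order[start % points.shape[0]])]
    d = np.linalg.norm(points - points[idx[0]], axis=1)
    for _ in range(K - 1):
        idx.append(int(np.argmax(d)))
        d = np.minimum(d, np.linalg.norm(points - points[idx[-1]], axis=1))
    return points[idx].copy()


def _cluster_moments(
    points: np.ndarray, assignment: np.ndarray, K: int, min_size: int
) -> tuple:
    n = points.shape[1]
    centroids = np.empty((K, n))
    dispersions = np.empty((K, n, n))
    overall = _regularize(np.cov(points, rowvar=False).reshape(n, n))
    empty = []
    for k in range(K):
        members = points[assignment == k]
        if members.shape[0] == 0:
            empty.append(k)
            continue
        centroids[k] = members.mean(axis=0)
        if members.shape[0] < max(min_size, n + 1):
            dispersions[k] = overall
        else:
            dispersions[k] = _regularize(
                np.cov(members, rowvar=False).reshape(n, n)
            )
    if empty:
        # re-seed each empty cluster at the point farthest (Euclidean)
        # from the centroid of its current cluster
        occupied = [k for k in range(K) if k not in empty]
        dist_own = np.linalg.norm(points - centroids[occupied][
            np.searchsorted(occupied, assignment)
        ], axis=1) if occupied else np.zeros(points.shape[0])
        order = np.argsort(dist_own)[::-1]
        for j, k in enumerate(empty):
            centroids[k] = points[order[j]]
            dispersions[k] = overall
    return centroids, dispersions


def _scaled_objective(
    points: np.ndarray,
    centroids: np.ndarray,
    dispersions: np.ndarray,
    assignment: np.ndarray,
) -> float:
    """Sum of assigned distances weighted by det(S_k)^{1/(2n)}.

    The raw distance sum is nearly invariant to how points are grouped when
    every cluster is measured by its own covariance (inflating ``S_k``
    shrinks all its distances); the determinant weight makes the distances
    scale-free and configurations comparable, so it is the criterion used
    to rank restarts.
    """
    n = points.shape[1]
    total = 0.0
    for k in range(centroids.shape[0]):
        members = points[assignment == k]
        if not members.shape[0]:
            continue
        L = linalg.cholesky(dispersions[k], lower=True)
        dev = linalg.solve_triangular(L, (members - centroids[k]).T, lower=True)
        d = np.sqrt(np.einsum("ji,ji->i", dev, dev))
        logdet = 2.0 * np.log(np.diagonal(L)).sum()
        total += float(d.sum() * np.exp(logdet / (2.0 * n)))
    return total


def k_centroids_mahalanobis(
    points: np.ndarray,
    K: int,
    init: Optional[CentroidSet] = None,
    max_iter: int = 100,
    seed: int = 0,
    n_restarts: int = 10,
    identity_dispersions: bool = False,
) -> CentroidSet:
    """K-centroids clustering with cluster-specific Mahalanobis distances.

    Alternates (a) assigning each point to the centroid/dispersion pair
    minimizing ``d_k(x) = sqrt((x-c_k)' S_k^{-1} (x-c_k))`` and (b)
    re-estimating ``c_k`` and ``S_k`` as within-cluster mean and
    covariance, until the assignment stabilizes.  Seeding is greedy
    farthest-point; one initial Euclidean assignment converts the seeds
    into within-cluster moments before the Mahalanobis loop starts (raw
    distances under an arbitrary initial metric are not comparable to
    moment-based ones).  Within the loop the objective (the sum of
    assigned distances) is evaluated after every assignment step and the
    iteration stops, keeping the previous configuration, if it would
    increase, so the recorded ``objective_path`` is non-increasing.  The
    best of ``n_restarts`` runs by the determinant-scaled objective is
    returned.

    With ``identity_dispersions=True`` the dispersions are pinned at the
    identity, which reduces the method to Euclidean K-means (used as the
    baseline comparison).

    Restart ``j`` seeds greedily from the ``j``-th farthest point from the
    overall centroid, so the result is deterministic and invariant to the
    ordering of the input points; ``seed`` is kept in the signature for
    API stability but only breaks ties in degenerate inputs.
    """
    points = np.asarray(points, dtype=float)
    N, n = points.shape
    if N < K:
        raise ValueError("need at least K points")
    if np.unique(points, axis=0).shape[0] < K:
        raise ValueError("need at least K distinct points")
    min_size = 2
    eye = np.broadcast_to(np.eye(n), (K, n, n)).copy()

    def _moments(assignment: np.ndarray) -> tuple:
        c, S = _cluster_moments(points, assignment, K, min_size)
        if identity_dispersions:
            S = eye.copy()
        return c, S

    def _run(centroids: np.ndarray, dispersions: np.ndarray) -> CentroidSet:
        assignment = None
        best = None
        path = []
        for _ in range(max_iter):
            D = _mahalanobis_distances(points, centroids, dispersions)
            new_assignment = np.argmin(D, axis=1)
            obj = float(D[np.arange(N), new_assignment].sum())
            if best is not None and obj > best.objective + 1e-9:
                break  # keep the previous configuration: path stays monotone
            path.append(obj)
            best = CentroidSet(
                centroids=centroids.copy(),
                dispersions=dispersions.copy(),
                assignment=new_assignment.copy(),
                objective=obj,
            )
            if assignment is not None and np.array_equal(new_assignment, assignment):
                break
            assignment = new_assignment
            centroids, dispersions = _moments(assignment)
        best.objective_path = np.asarray(path)
        best.objective_scaled = _scaled_objective(
            points, best.centroids, best.dispersions, best.assignment
        )
        return best

    if init is not None:
        return _run(init.centroids.copy(), init.dispersions.copy())

    best = None
    for restart in range(n_restarts):
        seeds = _farthest_point_seed(points, K, restart)
        # Euclidean pre-assignment turns the seeds into cluster moments
        a0 = np.argmin(
            np.linalg.norm(points[:, None, :] - seeds[None, :, :], axis=2), axis=1
        )
        c0, S0 = _moments(a0)
        cand = _run(c0, S0)
        if best is None or cand.objective_scaled < best.objective_scaled:
            best = cand
    return best


# ---------------------------------------------------------------------------
# Relabeling
# ---------------------------------------------------------------------------


def relabel_trace(
    trace: Trace, pps: PointProcessSample, cs: CentroidSet
) -> IdentifiedPosterior:
    """Reorder the draws of every sweep whose cluster assignment is a
    permutation of ``{1..K_hat}``; discard the rest.

    The assignment of the mean draws is propagated to the covariance and
    weight draws and, when stored, to the allocation labels.
    """
    K_hat, M0 = pps.K_hat, pps.M0
    assign = cs.assignment.reshape(M0, K_hat)
    comps = pps.component.reshape(M0, K_hat)
    is_perm = np.array(
        [np.array_equal(np.sort(row), np.arange(K_hat)) for row in assign]
    )
    kept = np.flatnonzero(is_perm)
    M_tilde = kept.size
    r = trace.mu.shape[2]
    mu_id = np.empty((M_tilde, K_hat, r))
    Sigma_id = np.empty((M_tilde, K_hat, r, r))
    eta_id = np.empty((M_tilde, K_hat))
    S_id = (
        np.empty((M_tilde, trace.S.shape[1]), dtype=np.int16)
        if trace.S is not None
        else None
    )
    K = trace.K
    for out, m in enumerate(kept):
        sweep = pps.sweeps[m]
        new_labels = assign[m]  # new label of the t-th non-empty component
        orig = comps[m]
        mu_id[out, new_labels] = trace.mu[sweep, orig]
        Sigma_id[out, new_labels] = trace.Sigma[sweep, orig]
        eta_id[out, new_labels] = trace.eta[sweep, orig]
        if S_id is not None:
            mapping = np.full(K, -1, dtype=np.int16)
            mapping[orig] = new_labels
            S_id[out] = mapping[trace.S[sweep]]
    return IdentifiedPosterior(
        mu=mu_id,
        Sigma=Sigma_id,
        eta=eta_id,
        S=S_id,
        sweeps=pps.sweeps[kept],
        M0=M0,
        M0_rho=float(1.0 - M_tilde / M0),
    )


def final_partition(identified: IdentifiedPosterior) -> tuple:
    """Modal relabeled component per observation over the identified sweeps.

    Returns ``(partition, assignment_freq)`` where ``assignment_freq`` is
    the ``(N, K_hat)`` matrix of per-observation assignment frequencies
    (rows sum to 1).  Ties break toward the smaller label.
    """
    if identified.S is None:
        raise ValueError("allocations were not stored; rerun with store_allocations")
    if identified.M_tilde == 0:
        raise ValueError("no identified sweeps (M_tilde = 0)")
    K_hat = identified.mu.shape[1]
    N = identified.S.shape[1]
    counts = np.empty((N, K_hat), dtype=np.int64)
    for k in range(K_hat):
        counts[:, k] = np.sum(identified.S == k, axis=0)
    partition = np.argmax(counts, axis=1)  # first max -> smaller label
    freq = counts / counts.sum(axis=1, keepdims=True)
    return partition, freq
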