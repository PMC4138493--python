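"""Constraint-satisfaction 2D embedding by the divide-and-concur
difference map.

Each high-dimensional point owns one constraint: its k nearest neighbors in
data space should also be its neighbors on the 2D map.  Every point gets one
2D "replica" per constraint it participates in (its own, plus each
constraint that lists it as a neighbor).  The *divide* projection acts on
each constraint independently, pulling neighbor replicas toward the owner's
replica by a step that grows as the pair gets closer in data space (a soft
constraint, capped so replicas never overshoot the owner).  The *concur*
projection makes all replicas of a point agree by moving them to their mean
map position.  The two are combined by the difference-map update

    x_c = P_c((1 + 1/beta) P_d(x) - (1/beta) x)
    x_d = P_d((1 - 1/beta) P_c(x) + (1/beta) x)
    x  <- x + beta (x_c - x_d)

which escapes the local traps plain alternation falls into.  All steps are
vectorized over the n(k+1) replicas, so one iteration costs O(kn).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors


@dataclass(frozen=True)
class EmbeddingProblem:
    """k-neighbor constraints of one dataset.

    Replica bookkeeping: constraint j owns the slice
    ``[j*(k+1), (j+1)*(k+1))`` of the replica array; position 0 is the
    owner's replica, positions 1..k the neighbors'.  ``replica_point[r]``
    is the point replica r represents.
    """

    points: np.ndarray          # (n, d)
    k: int
    neighbor_lists: np.ndarray  # (n, k) int, self excluded
    data_distances: np.ndarray  # (n, k)
    replica_point: np.ndarray   # (n*(k+1),) int
    tau: float                  # median data-space neighbor distance

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_replicas(self) -> int:
        return self.replica_point.size


def build_problem(points: np.ndarray, k: int) -> EmbeddingProblem:
    """Euclidean k-nearest-neighbor constraints (one constraint per point)."""
    points = np.asarray(points, float)
    n = points.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
    dist, idx = nn.kneighbors(points)
    # drop self (column 0 after sorting by distance; duplicates handled by
    # removing the first occurrence of the point's own index)
    neighbor_lists = np.empty((n, k), dtype=int)
    data_distances = np.empty((n, k))
    for i in range(n):
        row_idx, row_dist = idx[i], dist[i]
        self_pos = np.nonzero(row_idx == i)[0]
        drop = self_pos[0] if self_pos.size else 0
        keep = np.ones(k + 1, bool)
        keep[drop] = False
        neighbor_lists[i] = row_idx[keep]
        data_distances[i] = row_dist[keep]
    replica_point = np.column_stack([np.arange(n), neighbor_lists]).ravel()
    tau = float(np.median(data_distances))
    if tau <= 0:
        tau = 1.0
    return EmbeddingProblem(points=points, k=k, neighbor_lists=neighbor_lists,
                            data_distances=data_distances,
                            replica_point=replica_point, tau=tau)


def concur_project(x: np.ndarray, problem: EmbeddingProblem) -> np.ndarray:
    """Set every replica of a point to the mean of all its replicas.

    An exact projector: idempotent, and the identity on already-concurred
    states.
    """
    n = problem.n_points
    k = problem.k
    counts = np.bincount(problem.replica_point, minlength=n).astype(float)
    # mean computed as owner-replica + mean(deltas): bitwise idempotent,
    # since re-projecting a concurred state gives all-zero deltas
    base = x[np.arange(n) * (k + 1)]
    delta = x - base[problem.replica_point]
    means = np.empty((n, 2))
    for c in range(2):
        means[:, c] = np.bincount(problem.replica_point, weights=delta[:, c],
                                  minlength=n) / counts
    means += base
    return means[problem.replica_point]


def divide_project(
    x: np.ndarray,
    problem: EmbeddingProblem,
    alpha: float,
    pull: str = "near",
) -> np.ndarray:
    """Per-constraint soft neighbor pull.

    Within each constraint, every neighbor replica moves toward the owner's
    replica by ``min(alpha * g(d), current 2D distance)`` along the
    connecting line, where d is the pair's data-space distance and
    ``g(d) = exp(-d/tau)`` (``pull="near"``: closer in data space means a
    stronger pull) or ``g(d) = d/tau`` (``pull="far"``).  The cap makes a
    coincident replica a fixed point, and the owner never moves.
    """
    k = problem.k
    X = x.reshape(problem.n_points, k + 1, 2)
    owners = X[:, :1, :]
    nbrs = X[:, 1:, :]
    diff = owners - nbrs                               # direction of the pull
    d2d = np.linalg.norm(diff, axis=2)
    if pull == "near":
        g = np.exp(-problem.data_distances / problem.tau)
    elif pull == "far":
        g = problem.data_distances / problem.tau
    else:
        raise ValueError("pull must be 'near' or 'far'")
    step = np.minimum(alpha * g, d2d)
    safe = np.where(d2d > 0, d2d, 1.0)
    moved = nbrs + diff * (step / safe)[:, :, None]
    out = np.concatenate([owners, moved], axis=1)
    return out.reshape(-1, 2)


def dm_step(
    x: np.ndarray, problem: EmbeddingProblem, beta: float, alpha: float,
    pull: str = "near",
) -> np.ndarray:
    """One difference-map update; the update is exactly zero when the two
    projections agree (x_c = x_d)."""
    if beta == 0:
        raise ValueError("beta must be nonzero")
    Pd = lambda y: divide_project(y, problem, alpha, pull)
    Pc = lambda y: concur_project(y, problem)
    x_c = Pc((1.0 + 1.0 / beta) * Pd(x) - (1.0 / beta) * x)
    x_d = Pd((1.0 - 1.0 / beta) * Pc(x) + (1.0 / beta) * x)
    return x + beta * (x_c - x_d)


@dataclass(frozen=True)
class EmbeddingResult:
    coords: np.ndarray          # (n, 2) concurred map positions
    history: np.ndarray         # per-iteration mean replica displacement
    stop_reason: str            # "converged" | "oscillating" | "max_iters"
    n_iterations: int


def _init_coords(points: np.ndarray, init, seed: int | None) -> np.ndarray:
    """Deterministic classical-scaling-style initialization ("pca"): project
    centered data onto its top two principal axes, signs fixed so the
    largest-magnitude loading of each axis is positive.  "random" draws
    Gaussian coordinates at the data's scale."""
    n = points.shape[0]
    if init == "pca":
        centered = points - points.mean(axis=0)
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        coords = np.zeros((n, 2))
        m = min(2, s.size)
        for c in range(m):
            v = Vt[c]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, c] = centered @ v
        return coords
    if init == "random":
        rng = np.random.default_rng(seed)
        scale = np.linalg.norm(points.std(axis=0)) or 1.0
        return rng.normal(0.0, scale, size=(n, 2))
    raise ValueError("init must be 'pca' or 'random'")


def embed(
    points: np.ndarray,
    k: int = 10,
    beta: float = 0.9,
    max_iters: int = 500,
    init: str = "pca",
    seed: int | None = None,
    alpha: float | None = None,
    tol: float = 1e-4,
    pull: str = "near",
    window: int = 50,
) -> EmbeddingResult:
    """Embed points into 2D by iterating the difference map on the
    k-neighbor constraints.

    Stops when the mean replica displacement falls below ``tol * tau``
    (converged), when its trailing ``window``-iteration mean stops
    decreasing while still above tolerance (the difference map's signature
    oscillation), or at ``max_iters``.  Bit-reproducible given the same
    initialization spec.
    """
    problem = build_problem(points, k)
    if alpha is None:
        alpha = 0.1 * problem.tau
    x = _init_coords(problem.points, init, seed)[problem.replica_point]
    history = []
    stop_reason = "max_iters"
    threshold = tol * problem.tau
    prev_window_mean = np.inf
    it = 0
    for it in range(1, max_iters + 1):
        x_new = dm_step(x, problem, beta, alpha, pull)
        disp = float(np.mean(np.linalg.norm(x_new - x, axis=1)))
        history.append(disp)
        x = x_new
        if disp < threshold:
            stop_reason = "converged"
            break
        if it % window == 0:
            window_mean = float(np.mean(history[-window:]))
            if window_mean > threshold and (
                    prev_window_mean - window_mean
                    < 1e-3 * max(prev_window_mean, 1e-30)):
                stop_reason = "oscillating"
                break
            prev_window_mean = window_mean
    coords = concur_project(x, problem)[::problem.k + 1]
    return EmbeddingResult(coords=coords, history=np.asarray(history),
                           stop_reason=stop_reason, n_iterations=it)


# ---------------------------------------------------------------------------
# map quality measures


def knn_preservation(points: np.ndarray, map2d: np.ndarray, k: int) -> float:
    """Mean fraction of each point's data-space k-neighbors that are also
    among its k nearest neighbors on the 2D map (in [0, 1])."""
    hi = build_problem(points, k).neighbor_lists
    lo = build_problem(np.asarray(map2d, float), k).neighbor_lists
    shared = [np.intersect1d(hi[i], lo[i]).size for i in range(hi.shape[0])]
    return float(np.mean(shared) / k)


def class_separation(map2d: np.ndarray, labels: np.ndarray) -> float:
    """Between-class centroid distance normalized by the mean within-class
    spread (root-mean-square distance to the class centroid)."""
    map2d = np.asarray(map2d, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("class_separation expects exactly two classes")
    cents, spreads = [], []
    for cls in classes:
        pts = map2d[labels == cls]
        c = pts.mean(axis=0)
        cents.append(c)
        spreads.append(np.sqrt(np.mean(np.sum((pts - c) ** 2, axis=1))))
    return float(np.linalg.norm(cents[0] - cents[1]) / np.mean(spreads))


def severity_axis_correlation(
    map2d: np.ndarray, labels: np.ndarray, severity: np.ndarray
) -> float:
    """Spearman rank correlation between patient severity and position along
    the patient limb of the map (the control-to-patient centroid axis)."""
    from scipy.stats import spearmanr

    map2d = np.asarray(map2d, float)
    labels = np.asarray(labels)
    patients = labels == labels.max()
    axis = map2d[patients].mean(axis=0) - map2d[~patients].mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    coord = map2d[patients] @ axis
    rho = spearmanr(np.asarray(severity)[patients], coord).statistic
    return float(rho)
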