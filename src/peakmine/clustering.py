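"""Clustering of molecule concentration profiles across samples/time.

A peak table with hundreds of molecules cannot be read as hundreds of
trajectories on one plot; molecules are therefore clustered by similarity
of their concentration profiles (one row per molecule) and each cluster is
drawn as a single aggregated trajectory.

Four algorithms: k-means (Lloyd with k-means++ seeding), k-medoids
(PAM build + swap), farthest-first traversal (greedy k-center), and a
self-organizing map (rectangular grid, Gaussian neighborhood, decaying
radius and learning rate; clusters are the occupied best-matching units,
so the effective cluster count is data-driven).

Distances are Euclidean on optionally row-standardized profiles; row
standardization defaults ON so trajectory *shape*, not magnitude, drives
cluster membership.  Cluster indices are contiguous starting at 1.  All
algorithms are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .project_io import PeakTable, SampleMetadata

__all__ = [
    "Profiles",
    "ClusterModel",
    "ClusterTrajectory",
    "profile_matrix",
    "kmeans_cluster",
    "kmedoids_cluster",
    "farthest_first_cluster",
    "som_cluster",
    "cluster_trajectories",
    "cluster_members_detail",
    "ordered_samples",
]


@dataclass
class Profiles:
    """Molecules x samples profile matrix, optionally row-standardized."""

    values: np.ndarray
    molecule_ids: list[str]
    standardized: bool
    constant_rows: np.ndarray  # bool mask: rows that were constant pre-scaling


def profile_matrix(table: PeakTable, standardize: bool = True) -> Profiles:
    """One profile row per molecule; z-score rows when ``standardize``.

    Constant rows cannot be z-scored; they map to all-zeros and are
    flagged in ``constant_rows``.
    """
    if table.n_molecules == 0:
        raise ValueError("empty peak table")
    values = table.values.astype(float).copy()
    constant = np.ptp(values, axis=1) == 0
    if standardize:
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        sd_safe = np.where(sd == 0, 1.0, sd)
        values = (values - mean) / sd_safe
        values[constant] = 0.0
    return Profiles(values, list(table.molecule_ids), standardize, constant)


@dataclass
class ClusterModel:
    """A total partition of molecules into 1-based contiguous clusters."""

    algorithm: str
    assignment: dict[str, int]  # molecule -> cluster index, 1..k
    k: int
    centers: np.ndarray  # cluster centers (k x n_samples); medoid rows for PAM
    medoid_ids: list[str] | None
    standardized: bool
    seed: int
    info: dict = field(default_factory=dict)

    def members(self, cluster_index: int) -> list[str]:
        if not 1 <= cluster_index <= self.k:
            raise IndexError(f"cluster index {cluster_index} out of 1..{self.k}")
        return [m for m, c in self.assignment.items() if c == cluster_index]

    def labels(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[m] for m in order], dtype=int)


def _as_profiles(profiles: Profiles | np.ndarray) -> tuple[np.ndarray, list[str], bool]:
    if isinstance(profiles, Profiles):
        return profiles.values, profiles.molecule_ids, profiles.standardized
    arr = np.asarray(profiles, dtype=float)
    return arr, [str(i) for i in range(len(arr))], False


def _sq_dists(x: np.ndarray, centers: np.ndarray) -> np.ndarray:
    return ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)


def _kmeanspp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    m = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(m)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = x[rng.integers(m)]
            continue
        probs = d2 / total
        centers[j] = x[rng.choice(m, p=probs)]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int):
    m = len(x)
    centers = _kmeanspp(x, k, rng)
    labels = np.zeros(m, dtype=int)
    inertia_trace: list[float] = []
    for _ in range(max_iter):
        d2 = _sq_dists(x, centers)
        new_labels = d2.argmin(axis=1)
        for j in range(k):
            if not np.any(new_labels == j):
                # reseed an empty cluster from the worst-fitting point
                far = int(d2[np.arange(m), new_labels].argmax())
                centers[j] = x[far]
                new_labels[far] = j
        inertia_trace.append(float(((x - centers[new_labels]) ** 2).sum()))
        if np.array_equal(new_labels, labels) and len(inertia_trace) > 1:
            break
        labels = new_labels
        for j in range(k):
            centers[j] = x[labels == j].mean(axis=0)
    return centers, labels, inertia_trace


def kmeans_cluster(
    profiles: Profiles | np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 300,
    n_init: int = 10,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ seeding on Euclidean distance.

    Converges when assignments stabilize.  An emptied cluster is repaired
    by reseeding its center from the point farthest from its own centroid,
    keeping the partition total.  ``n_init`` independent k-means++ starts
    are run and the solution with the lowest within-cluster sum of squares
    is kept (Lloyd converges to local optima; restarts are the standard
    remedy).  Deterministic per seed.  The winning run's per-iteration
    inertia is recorded in ``info["inertia"]`` (non-increasing).
    """
    x, ids, standardized = _as_profiles(profiles)
    m = len(x)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..{m}, got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        centers, labels, trace = _lloyd(x, k, rng, max_iter)
        if best is None or trace[-1] < best[2][-1]:
            best = (centers, labels, trace)
    centers, labels, inertia_trace = best
    assignment = {mol: int(c) + 1 for mol, c in zip(ids, labels)}
    return ClusterModel(
        "kmeans", assignment, k, centers, None, standardized, seed,
        info={"inertia": inertia_trace},
    )


def kmedoids_cluster(
    profiles: Profiles | np.ndarray, k: int, seed: int = 0, max_iter: int = 100
) -> ClusterModel:
    """PAM k-medoids: greedy BUILD then best-improvement SWAP passes.

    Medoids are always input profiles; total absolute Euclidean cost is
    minimized; deterministic (BUILD is greedy, ties break on lowest
    index; the seed only matters for the API surface).
    """
    x, ids, standardized = _as_profiles(profiles)
    m = len(x)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..{m}, got {k}")
    dist = np.sqrt(np.maximum(_sq_dists(x, x), 0.0))

    # BUILD: start with the 1-medoid optimum, then greedily add
    medoids = [int(dist.sum(axis=0).argmin())]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(m):
                if h in medoids:
                    continue
                cand = medoids.copy()
                cand[mi] = h
                c = cost(cand)
                if c < best_cost - 1e-12:
                    medoids, best_cost, improved = cand, c, True
        if not improved:
            break
    medoids = sorted(medoids)
    labels = dist[:, medoids].argmin(axis=1)
    assignment = {mol: int(c) + 1 for mol, c in zip(ids, labels)}
    return ClusterModel(
        "kmedoids", assignment, k, x[medoids].copy(), [ids[i] for i in medoids],
        standardized, seed, info={"cost": best_cost},
    )


def farthest_first_cluster(
    profiles: Profiles | np.ndarray,
    k: int,
    seed: int = 0,
    first_center: int | None = None,
) -> ClusterModel:
    """Greedy k-center traversal (Hochbaum-Shmoys).

    The first center is chosen by the seed (or fixed via
    ``first_center``); each subsequent center is the point farthest from
    all chosen centers (ties to the lowest index); every point joins its
    nearest center.
    """
    x, ids, standardized = _as_profiles(profiles)
    m = len(x)
    if not 1 <= k <= m:
        raise ValueError(f"k must be in 1..{m}, got {k}")
    rng = np.random.default_rng(seed)
    centers = [int(rng.integers(m)) if first_center is None else int(first_center)]
    d = np.sqrt(((x - x[centers[0]]) ** 2).sum(axis=1))
    while len(centers) < k:
        nxt = int(d.argmax())
        centers.append(nxt)
        d = np.minimum(d, np.sqrt(((x - x[nxt]) ** 2).sum(axis=1)))
    labels = _sq_dists(x, x[centers]).argmin(axis=1)
    assignment = {mol: int(c) + 1 for mol, c in zip(ids, labels)}
    return ClusterModel(
        "farthest_first", assignment, k, x[centers].copy(), [ids[i] for i in centers],
        standardized, seed, info={"center_indices": centers},
    )


def som_cluster(
    profiles: Profiles | np.ndarray,
    grid_rows: int = 3,
    grid_cols: int = 3,
    epochs: int | None = None,
    learning_rate: float = 0.5,
    seed: int = 0,
) -> ClusterModel:
    """Self-organizing map; clusters are the occupied grid units.

    A ``grid_rows x grid_cols`` sheet of prototype vectors is trained
    online: each presentation picks a random profile, finds its
    best-matching unit (BMU) and pulls the BMU and its grid neighbors
    toward the profile under a Gaussian neighborhood whose radius decays
    from ``max(grid)/2`` to 0.5 while the learning rate decays from
    ``learning_rate`` to 0.01.  Total presentations default to
    ``100 * n_molecules``.  After training each molecule maps to its BMU;
    occupied units become clusters, so the effective cluster count is
    data-driven (at most the grid size) rather than user-fixed.
    """
    x, ids, standardized = _as_profiles(profiles)
    m, dim = x.shape
    if grid_rows < 1 or grid_cols < 1:
        raise ValueError("grid must be at least 1x1")
    rng = np.random.default_rng(seed)
    n_units = grid_rows * grid_cols
    # prototypes initialized by sampling data rows (with a tiny jitter to
    # keep units distinct when rows repeat)
    init_idx = rng.integers(m, size=n_units)
    weights = x[init_idx] + 1e-6 * rng.standard_normal((n_units, dim))
    grid_pos = np.array([(r, c) for r in range(grid_rows) for c in range(grid_cols)], dtype=float)
    grid_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)

    total = int(epochs) if epochs is not None else 100 * m
    r0 = max(max(grid_rows, grid_cols) / 2.0, 0.5)
    # the radius ends below 1 so that late training is essentially
    # BMU-only (convergence phase); ending at a full unit of radius keeps
    # pulling adjacent units together and can merge distinct clusters
    r1, lr1 = 0.5, 0.01
    qe_checkpoints: list[float] = []
    for step in range(total):
        frac = step / max(total - 1, 1)
        radius = r0 * (r1 / r0) ** frac if r0 > 0 else 1.0
        lr = learning_rate * (lr1 / learning_rate) ** frac
        v = x[rng.integers(m)]
        bmu = int(((weights - v) ** 2).sum(axis=1).argmin())
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))
        weights += lr * h[:, None] * (v - weights)
        if total >= 10 and step % max(total // 10, 1) == 0:
            qe = float(np.sqrt(_sq_dists(x, weights).min(axis=1)).mean())
            qe_checkpoints.append(qe)

    bmus = _sq_dists(x, weights).argmin(axis=1)
    occupied = sorted(set(int(u) for u in bmus))
    remap = {u: i + 1 for i, u in enumerate(occupied)}
    assignment = {mol: remap[int(u)] for mol, u in zip(ids, bmus)}
    return ClusterModel(
        "som", assignment, len(occupied), weights[occupied].copy(), None,
        standardized, seed,
        info={
            "grid": (grid_rows, grid_cols),
            "occupied_units": occupied,
            "quantization_error": qe_checkpoints,
        },
    )


def ordered_samples(metadata: SampleMetadata) -> list[str]:
    """Samples sorted by time point first, then alphabetically by id."""
    if "time" in metadata.feature_names:
        return sorted(metadata.sample_ids, key=lambda s: (metadata.time_of(s), s))
    return sorted(metadata.sample_ids)


@dataclass
class ClusterTrajectory:
    """Per-cluster aggregated concentration per sample, in display order."""

    aggregate: str
    sample_order: list[str]
    trajectories: dict[int, np.ndarray]  # cluster index -> values per sample
    members: dict[int, list[str]]


def _mode(values: np.ndarray) -> float:
    # most frequent value; ties resolve to the smallest value
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[counts.argmax()])


_AGGREGATES = {
    "average": lambda v: float(v.mean()),
    "mode": _mode,
    "max": lambda v: float(v.max()),
    "min": lambda v: float(v.min()),
}


def cluster_trajectories(
    model: ClusterModel,
    table: PeakTable,
    metadata: SampleMetadata,
    aggregate: str = "average",
) -> ClusterTrajectory:
    """Aggregate raw concentrations per cluster per sample.

    The default aggregate is the average; mode, maximum and minimum are
    selectable.  Samples are ordered by (time ascending, then id
    alphabetically).
    """
    if aggregate not in _AGGREGATES:
        raise ValueError(f"unknown aggregate {aggregate!r}; choose from {sorted(_AGGREGATES)}")
    fn = _AGGREGATES[aggregate]
    order = ordered_samples(metadata)
    col = [table.sample_ids.index(s) for s in order]
    trajectories: dict[int, np.ndarray] = {}
    members: dict[int, list[str]] = {}
    for ci in range(1, model.k + 1):
        mols = model.members(ci)
        if not mols:
            continue
        rows = table.values[[table.molecule_index(m) for m in mols]][:, col]
        trajectories[ci] = np.array([fn(rows[:, j]) for j in range(rows.shape[1])])
        members[ci] = mols
    return ClusterTrajectory(aggregate, order, trajectories, members)


def cluster_members_detail(
    model: ClusterModel,
    cluster_index: int,
    table: PeakTable,
    metadata: SampleMetadata | None = None,
) -> pd.DataFrame:
    """Member-molecule profiles of one cluster, samples in display order."""
    mols = model.members(cluster_index)
    order = ordered_samples(metadata) if metadata is not None else list(table.sample_ids)
    col = [table.sample_ids.index(s) for s in order]
    data = table.values[[table.molecule_index(m) for m in mols]][:, col]
    return pd.DataFrame(data, index=mols, columns=order)
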