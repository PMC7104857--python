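"""Unsupervised discovery of biophysical subpopulations.

Per-cell force profiles (or any cell-by-feature table, e.g.
cytoskeletal morphology features) are centred and scaled, reduced by
PCA, and clustered along two parallel routes:

* PAM (partitioning around medoids, k-medoids with BUILD + SWAP) on the
  principal-component scores with a chosen k;
* a k-nearest-neighbour graph on the scores of the *significant*
  principal components (selected by permutation parallel analysis),
  refined into a shared-nearest-neighbour graph weighted by the Jaccard
  overlap of neighbourhoods, and partitioned with Louvain community
  detection.

Projecting clusters along PC1 orders cells on a low-to-high
contractility axis; the Spearman correlation of PC1 rank with mean
traction quantifies how much of the leading axis is force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProfileMatrix",
    "PCAResult",
    "NeighborGraph",
    "ClusterAssignment",
    "standardize",
    "run_pca",
    "significant_pcs",
    "pam_cluster",
    "knn_graph",
    "snn_refine",
    "louvain_cluster",
    "pc1_trajectory",
]


@dataclass
class ProfileMatrix:
    """Standardized cells × features matrix with the scaling audit trail."""

    values: np.ndarray
    cell_ids: list[str]
    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray


@dataclass
class PCAResult:
    scores: np.ndarray                 # cells × PCs
    loadings: np.ndarray               # features × PCs
    explained_variance_ratio: np.ndarray
    n_significant: int | None = None


@dataclass
class NeighborGraph:
    """kNN stage (directed neighbour lists) and optional SNN refinement."""

    knn: np.ndarray                    # (n, k) neighbour indices
    k: int
    snn: nx.Graph | None = None


@dataclass
class ClusterAssignment:
    labels: np.ndarray                 # contiguous from 1
    method: str
    k: int | None = None
    medoids: np.ndarray | None = None  # data indices, PAM only
    resolution: float | None = None


def _as_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame(np.asarray(profiles, dtype=float))


def standardize(profiles) -> ProfileMatrix:
    """Column-wise z-scoring (mean 0, sd 1 with the n−1 convention).

    Raises on constant features, naming them: a constant feature
    carries no information and would divide by zero.
    """
    df = _as_frame(profiles)
    if len(df) < 2:
        raise ValueError("need at least 2 cells")
    if df.isna().any().any():
        raise ValueError("profiles contain missing values")
    x = df.to_numpy(dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    const = np.flatnonzero(sds == 0)
    if const.size:
        names = [str(df.columns[i]) for i in const]
        raise ValueError(f"constant features cannot be scaled: {names}")
    z = (x - means) / sds
    return ProfileMatrix(
        values=z,
        cell_ids=[str(i) for i in df.index],
        feature_names=[str(c) for c in df.columns],
        feature_means=means,
        feature_sds=sds,
    )


def _pca_evr(z: np.ndarray) -> np.ndarray:
    """Explained-variance ratios of a centred matrix via SVD."""
    zc = z - z.mean(axis=0)
    s = np.linalg.svd(zc, compute_uv=False)
    var = s ** 2
    return var / var.sum()


def run_pca(matrix: ProfileMatrix) -> PCAResult:
    """Exact SVD-based PCA of the standardized matrix.

    PCs are capped at min(n−1, p).  Sign convention: within each PC the
    loading of largest magnitude is made positive, so results are
    deterministic across SVD implementations.
    """
    z = matrix.values - matrix.values.mean(axis=0)
    n, p = z.shape
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    ncomp = min(n - 1, p)
    u, s, vt = u[:, :ncomp], s[:ncomp], vt[:ncomp]
    # deterministic sign: largest-|loading| positive per PC
    flip = np.sign(vt[np.arange(ncomp), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    scores = u * s
    var = s ** 2
    total = ((z ** 2).sum())
    return PCAResult(
        scores=scores,
        loadings=vt.T,
        explained_variance_ratio=var / total,
    )


def significant_pcs(
    matrix: ProfileMatrix,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> int:
    """Permutation parallel analysis for the number of significant PCs.

    Each feature column is permuted independently (breaking all
    between-feature structure while keeping marginals), the explained
    variance ratio spectrum recomputed per permutation, and PCs counted
    from the first until one fails to exceed the (1−alpha) null
    quantile of its own rank.
    """
    if n_permutations < 20:
        warnings.warn("fewer than 20 permutations: unstable PC selection", stacklevel=2)
    rng = np.random.default_rng(seed)
    z = matrix.values
    obs = _pca_evr(z)
    null = np.empty((n_permutations, obs.size))
    perm = z.copy()
    for b in range(n_permutations):
        for j in range(perm.shape[1]):
            perm[:, j] = rng.permutation(z[:, j])
        null[b] = _pca_evr(perm)
    q = np.quantile(null, 1.0 - alpha, axis=0)
    count = 0
    for j in range(obs.size):
        if obs[j] > q[j]:
            count += 1
        else:
            break
    return count


def _pam(dist: np.ndarray, k: int, max_iter: int = 200) -> np.ndarray:
    """Classical PAM: greedy BUILD then best-improvement SWAP phases."""
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance; then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        dmin = dist[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    cost = dist[:, medoids].min(axis=1).sum()
    for _ in range(max_iter):
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = dist[:, trial].min(axis=1).sum()
                if cost - c > best[0] + 1e-12:
                    best = (cost - c, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
        cost = dist[:, medoids].min(axis=1).sum()
    return np.asarray(medoids)


def pam_cluster(scores: np.ndarray, k: int = 3, seed: int | None = None) -> ClusterAssignment:
    """Partitioning around medoids on Euclidean distances over scores.

    BUILD+SWAP is deterministic for a given input (ties broken by
    ascending index); ``seed`` is accepted for interface symmetry.
    Labels are contiguous from 1 in order of medoid index.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    from scipy.spatial.distance import squareform, pdist

    dist = squareform(pdist(scores))
    medoids = _pam(dist, k)
    labels = np.argmin(dist[:, medoids], axis=1) + 1
    return ClusterAssignment(labels=labels, method="PAM", k=k, medoids=medoids)


def knn_graph(scores: np.ndarray, k: int) -> NeighborGraph:
    """Directed k-nearest-neighbour lists by Euclidean distance.

    Ties are broken by ascending cell index for determinism.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    from scipy.spatial.distance import squareform, pdist

    dist = squareform(pdist(scores))
    np.fill_diagonal(dist, np.inf)
    idx = np.arange(n)
    order = np.lexsort((np.broadcast_to(idx, (n, n)), dist), axis=1)
    return NeighborGraph(knn=order[:, :k], k=k)


def snn_refine(graph: NeighborGraph, prune_below: float = 0.0) -> NeighborGraph:
    """Shared-nearest-neighbour refinement with Jaccard weights.

    For every pair of cells connected in the kNN stage (either
    direction), the undirected edge weight is the Jaccard overlap of
    their neighbourhoods (each neighbourhood including the cell
    itself); edges with weight ≤ ``prune_below`` are dropped.
    """
    n = graph.knn.shape[0]
    sets = [frozenset(graph.knn[i]) | {i} for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    pairs = {
        (min(i, j), max(i, j))
        for i in range(n)
        for j in graph.knn[i]
        if i != j
    }
    for i, j in sorted(pairs):
        inter = len(sets[i] & sets[j])
        union = len(sets[i] | sets[j])
        w = inter / union
        if w > prune_below:
            g.add_edge(i, j, weight=w)
    return NeighborGraph(knn=graph.knn, k=graph.k, snn=g)


def louvain_cluster(
    graph: NeighborGraph | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
) -> ClusterAssignment:
    """Louvain modularity communities of the SNN graph.

    Labels contiguous from 1, ordered by each community's smallest
    member index; seeded for reproducible node sweeps.
    """
    g = graph.snn if isinstance(graph, NeighborGraph) else graph
    if g is None or g.number_of_nodes() == 0:
        raise ValueError("empty graph (run snn_refine first?)")
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=min)
    labels = np.zeros(g.number_of_nodes(), dtype=int)
    for ci, members in enumerate(comms, start=1):
        for m in members:
            labels[m] = ci
    return ClusterAssignment(
        labels=labels, method="Louvain", resolution=resolution
    )


def pc1_trajectory(
    pca: PCAResult,
    assignment: ClusterAssignment,
    profile_stats: pd.DataFrame,
) -> tuple[pd.DataFrame, float]:
    """Order cells along PC1 and correlate the axis with contractility.

    ``profile_stats`` must carry per-cell ``mean_traction`` and
    ``max_traction`` columns (row order matching the score matrix).
    Returns the ordered table and the Spearman correlation between the
    PC1 score and mean traction.
    """
    pc1 = pca.scores[:, 0]
    df = profile_stats.copy()
    df["pc1"] = pc1
    df["cluster"] = assignment.labels
    df = df.sort_values("pc1")
    rho = float(stats.spearmanr(pc1, profile_stats["mean_traction"]).statistic)
    return df, rho
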