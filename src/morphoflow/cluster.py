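"""De-novo clustering by kNN-density mode seeking, with elbow k selection.

The clustering follows the weighted k-nearest-neighbor density-ascent idea
popularized for cytometry data: estimate the density at every event with the
standard kNN estimator, point each event at the highest-density point among
its k nearest neighbors, and collect the basins of attraction of the density
modes as clusters.  k controls granularity; it is chosen by scanning a grid
(default 5..150) and taking the elbow of the cluster-count-vs-k curve.
A force-directed layout (Fruchterman-Reingold) of the kNN graph gives the
standard 2-D visualization, exportable as graphML.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

DEFAULT_K_GRID = tuple(range(5, 151, 5))


@dataclass
class ClusterResult:
    """Cluster assignments plus the diagnostics around them."""

    cluster_id: np.ndarray                 # per retained event, 0-based, by size
    k_used: int
    k_grid: list[int] = field(default_factory=list)
    n_clusters_per_k: list[int] = field(default_factory=list)
    feature_means: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None     # clusters x samples
    fdl_coords: pd.DataFrame | None = None
    fdl_edges: list[tuple[int, int]] | None = None


def _log_unit_ball_volume(d: int) -> float:
    return (d / 2) * np.log(np.pi) - gammaln(d / 2 + 1)


def knn_density(points: np.ndarray, k: int,
                neighbors: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Standard kNN density estimate: k / (n * V_d * r_k^d).

    ``r_k`` is the distance to the k-th nearest neighbor (self excluded) and
    ``V_d`` the unit-ball volume in d dimensions.  Densities are computed in
    log space internally, so they are usable (as ranks) even when ``r_k^d``
    would over/underflow; duplicate points get r_k floored at a tiny scale
    with a warning.  ``neighbors`` may pass precomputed (distances, indices)
    sorted by distance with self in column 0, to amortize the search across a
    k grid.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    if not 1 <= k < n:
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    if neighbors is None:
        dist, _ = NearestNeighbors(n_neighbors=k + 1).fit(pts).kneighbors(pts)
    else:
        dist = neighbors[0]
    rk = dist[:, k].astype(float)
    if np.any(rk <= 0):
        warnings.warn("duplicate points: r_k == 0 floored at machine epsilon scale")
        scale = max(float(dist.max()), 1.0)
        rk = np.maximum(rk, np.finfo(float).eps * scale)
    logdens = np.log(k) - np.log(n) - _log_unit_ball_volume(d) - d * np.log(rk)
    with np.errstate(over="ignore", under="ignore"):
        return np.exp(logdens)


def _log_knn_density(dist: np.ndarray, k: int, n: int, d: int) -> np.ndarray:
    rk = np.maximum(dist[:, k].astype(float),
                    np.finfo(float).eps * max(float(dist.max()), 1.0))
    return np.log(k) - np.log(n) - _log_unit_ball_volume(d) - d * np.log(rk)


def _ascend(indices: np.ndarray, logdens: np.ndarray, k: int) -> np.ndarray:
    """Density-ascent labels: follow pointers to the mode reached.

    Each point points at the maximum-density point among itself and its k
    nearest neighbors; ties are broken toward the lower index, making the
    (density, -index) order strict and the pointer graph acyclic.
    """
    n = len(logdens)
    # strict total order key: rank by (density, -index)
    order = np.lexsort((-np.arange(n), logdens))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    cand = indices[:, : k + 1]                      # self + k neighbors
    best = cand[np.arange(n), np.argmax(rank[cand], axis=1)]
    pointer = np.where(rank[best] > rank[np.arange(n)], best, np.arange(n))
    # pointer jumping to the root (mode); O(log n) rounds
    root = pointer
    while True:
        nxt = root[root]
        if np.array_equal(nxt, root):
            break
        root = nxt
    return root


def _merge_weak_modes(labels: np.ndarray, logdens: np.ndarray,
                      indices: np.ndarray, k: int,
                      merge_strength: float) -> np.ndarray:
    """Merge mode pairs separated only by estimator noise.

    The log of the kNN density estimate fluctuates with asymptotic standard
    deviation ~1/sqrt(k), so a single smooth population throws off several
    shallow local modes whose separating dip is a few noise-sd deep.  A pair
    of clusters is merged when the log density of the densest cross-boundary
    neighbor pair (the saddle) lies within ``merge_strength / sqrt(k)`` of
    the smaller of the two peak log densities.  Genuine populations are
    separated by valleys whose depth does not shrink with k and are
    untouched; the threshold tightens automatically as larger k smooths the
    estimate.
    """
    ncl = int(labels.max()) + 1
    if ncl <= 1 or merge_strength <= 0:
        return labels
    peak = np.full(ncl, -np.inf)
    np.maximum.at(peak, labels, logdens)
    nb = indices[:, 1:k + 1]
    li = np.repeat(labels, nb.shape[1])
    lj = labels[nb.ravel()]
    sval = np.minimum(np.repeat(logdens, nb.shape[1]), logdens[nb.ravel()])
    cross = li != lj
    S = np.full((ncl, ncl), -np.inf)
    np.maximum.at(S, (li[cross], lj[cross]), sval[cross])
    S = np.maximum(S, S.T)
    np.fill_diagonal(S, -np.inf)
    thr = -merge_strength / np.sqrt(k)
    remap = np.arange(ncl)
    active = np.ones(ncl, dtype=bool)
    while active.sum() > 1:
        gap = S - np.minimum.outer(peak, peak)
        gap[~active] = -np.inf
        gap[:, ~active] = -np.inf
        a, b = np.unravel_index(np.argmax(gap), gap.shape)
        if gap[a, b] < thr:
            break
        S[a] = np.maximum(S[a], S[b])
        S[:, a] = S[a]
        S[a, a] = -np.inf
        peak[a] = max(peak[a], peak[b])
        active[b] = False
        remap[remap == b] = a
    return remap[labels]


def _relabel_by_size(root: np.ndarray) -> np.ndarray:
    modes, inv, counts = np.unique(root, return_inverse=True, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(len(modes), dtype=np.int64)
    remap[order] = np.arange(len(modes))
    return remap[inv]


DEFAULT_MERGE_STRENGTH = 4.0


def xshift_cluster(points: np.ndarray, k: int,
                   neighbors: tuple[np.ndarray, np.ndarray] | None = None,
                   merge_strength: float = DEFAULT_MERGE_STRENGTH) -> np.ndarray:
    """Cluster by kNN-density ascent with weak-mode merging.

    Ids are 0-based, ordered by descending cluster size.  ``merge_strength``
    controls the merge of noise modes in units of the estimator's log-density
    noise scale (see :func:`_merge_weak_modes`); 0 disables merging, leaving
    raw density-ascent basins.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    if neighbors is None:
        dist, idx = NearestNeighbors(n_neighbors=k + 1).fit(pts).kneighbors(pts)
    else:
        dist, idx = neighbors
    logdens = _log_knn_density(dist, k, n, d)
    root = _ascend(idx, logdens, k)
    labels = _relabel_by_size(root)
    labels = _merge_weak_modes(labels, logdens, idx, k, merge_strength)
    return _relabel_by_size(labels)


def precompute_neighbors(points: np.ndarray, k_max: int):
    """(distances, indices) out to k_max neighbors, self in column 0."""
    pts = np.asarray(points, dtype=float)
    return NearestNeighbors(n_neighbors=min(k_max + 1, len(pts))).fit(pts).kneighbors(pts)


def elbow_index(k_grid, n_clusters) -> int:
    """Kneedle-style elbow: index of maximum perpendicular distance from the
    chord joining the curve endpoints, in (log k, log n_clusters) space.
    For a curve made of two joined line segments this is exactly the joint."""
    x = np.log(np.asarray(k_grid, dtype=float))
    y = np.log(np.asarray(n_clusters, dtype=float))
    seg = np.array([x[-1] - x[0], y[-1] - y[0]])
    seg = seg / np.linalg.norm(seg)
    rel = np.column_stack([x - x[0], y - y[0]])
    return int(np.argmax(np.abs(rel[:, 0] * seg[1] - rel[:, 1] * seg[0])))


def elbow_select_k(points: np.ndarray, k_grid=DEFAULT_K_GRID,
                   neighbors=None):
    """Scan k over a grid and pick the elbow of the cluster-count curve.

    The curve (k, n_clusters) is examined in (log k, log n_clusters) space
    and k* is the grid point with maximum perpendicular distance from the
    chord joining the curve's endpoints (kneedle-style).  A flat curve has no
    elbow; the smallest k with the stable count is returned with a warning.

    Returns ``(k_star, curve DataFrame, labels at k_star)``.
    """
    k_grid = sorted(k_grid)
    if len(k_grid) < 4:
        raise ValueError("k grid must have at least 4 points")
    pts = np.asarray(points, dtype=float)
    if neighbors is None:
        neighbors = precompute_neighbors(pts, max(k_grid))
    labels_per_k = {}
    ncl = []
    for k in k_grid:
        lab = xshift_cluster(pts, k, neighbors=neighbors)
        labels_per_k[k] = lab
        ncl.append(int(lab.max()) + 1)
    curve = pd.DataFrame({"k": k_grid, "n_clusters": ncl})
    if len(set(ncl)) == 1:
        warnings.warn("cluster-count curve is flat; returning smallest k")
        k_star = k_grid[0]
    else:
        k_star = int(k_grid[elbow_index(k_grid, ncl)])
    log.info("elbow: k*=%d with %d clusters", k_star,
             int(labels_per_k[k_star].max()) + 1)
    return k_star, curve, labels_per_k[k_star]


# ---------------------------------------------------------------------------
# force-directed layout

def build_fdl(points: np.ndarray, cluster_ids: np.ndarray,
              subsample_cap: int | None = 200, knn_k: int = 10, seed: int = 0,
              iterations: int = 50):
    """Force-directed (Fruchterman-Reingold) layout of the kNN graph.

    At most ``subsample_cap`` events per cluster are laid out.  The graph is
    the union of directed kNN edges with weight 1/(1+distance).  Disconnected
    components are laid out independently and placed side by side.

    Returns ``(coords DataFrame [event index, cluster_id, x, y], graph)``.
    """
    pts = np.asarray(points, dtype=float)
    cluster_ids = np.asarray(cluster_ids)
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(cluster_ids):
        idx = np.flatnonzero(cluster_ids == c)
        if subsample_cap is not None and len(idx) > subsample_cap:
            idx = rng.choice(idx, size=subsample_cap, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    sub = pts[keep]
    kk = min(knn_k + 1, len(sub))
    dist, idx = NearestNeighbors(n_neighbors=kk).fit(sub).kneighbors(sub)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in keep)
    for a in range(len(sub)):
        for b, w in zip(idx[a, 1:], dist[a, 1:]):
            g.add_edge(int(keep[a]), int(keep[b]), weight=1.0 / (1.0 + float(w)))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        warnings.warn(f"kNN graph has {len(comps)} components; laid out side by side")
    pos: dict[int, np.ndarray] = {}
    x_offset = 0.0
    for comp in sorted(comps, key=len, reverse=True):
        sg = g.subgraph(comp)
        p = nx.spring_layout(sg, seed=int(rng.integers(2**31)), iterations=iterations)
        arr = np.array(list(p.values()))
        span = arr[:, 0].max() - arr[:, 0].min() + 1.0
        for node, xy in p.items():
            pos[node] = np.array([xy[0] + x_offset - arr[:, 0].min(), xy[1]])
        x_offset += span + 0.5
    coords = pd.DataFrame({
        "event_index": keep,
        "cluster_id": cluster_ids[keep],
        "x": [pos[int(i)][0] for i in keep],
        "y": [pos[int(i)][1] for i in keep],
    })
    return coords, g


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def cluster_events(table: pd.DataFrame, features: list[str] | None = None,
                   k_grid=DEFAULT_K_GRID, fdl_cap: int | None = 200,
                   fdl_knn: int = 10, seed: int = 0) -> ClusterResult:
    """Full clustering stage on a preprocessed EventTable.

    Selects k by elbow, assigns clusters, summarizes per-cluster feature
    means and per-sample counts, and lays out the FDL graph.
    """
    from .preprocess import feature_columns
    features = features or feature_columns(table)
    pts = table[features].to_numpy(float)
    k_star, curve, labels = elbow_select_k(pts, k_grid=k_grid)
    means, counts, _ = summarize_clusters(table, labels, features)
    coords, edges_graph = build_fdl(pts, labels, subsample_cap=fdl_cap,
                                    knn_k=fdl_knn, seed=seed)
    return ClusterResult(
        cluster_id=labels, k_used=k_star,
        k_grid=list(curve["k"]), n_clusters_per_k=list(curve["n_clusters"]),
        feature_means=means, counts=counts, fdl_coords=coords,
        fdl_edges=[(int(a), int(b)) for a, b in edges_graph.edges])


# ---------------------------------------------------------------------------
# summaries

def summarize_clusters(table: pd.DataFrame, cluster_ids: np.ndarray,
                       features: list[str] | None = None):
    """Per-cluster feature means and the clusters x samples count matrix.

    Returns ``(feature_means DataFrame [clusters x features],
    counts DataFrame [clusters x samples], relative abundances)``.
    """
    from .preprocess import feature_columns
    t = table.copy()
    t["cluster_id"] = np.asarray(cluster_ids)
    features = features or feature_columns(t)
    features = [f for f in features if f != "cluster_id"]
    means = t.groupby("cluster_id")[features].mean()
    counts = (t.groupby(["cluster_id", "sample_id"]).size()
              .unstack(fill_value=0).sort_index())
    rel = counts / counts.sum(axis=0)
    return means, counts, rel
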