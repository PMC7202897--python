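"""Per-condition aggregation and the clustering / embedding analyses.

Condition summaries carry the mean of each of the 11 adhesion shape features
plus mean 2D speed, mean 2D persistence and mean 3D invasion fold change.
The clustering analysis mirrors large-scale adhesion profiling practice:
profiles are mean-centered, distances are 1 - Spearman rank correlation and
agglomeration uses average (mean) linkage. The kNN graph over standardized
single-cell features is the input a force-directed (SPRING-style) layout
consumes; the layout itself is only a visualization hook.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .morphometry import FEATURE_NAMES

__all__ = [
    "ConditionSummary",
    "EmbeddingResult",
    "summarize",
    "summary_frame",
    "cluster_heatmap",
    "knn_graph",
    "pca",
]


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    cell_line: str
    mean_features: dict[str, float]   # the 11 shape means
    mean_speed: float
    mean_persistence: float
    mean_invasion: float              # fold change
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray           # (n_cells, 2)
    edges: list[tuple[int, int]]      # kNN edge list (i -> j, j a neighbor of i)
    k: int
    metric: str = "euclidean"


def summarize(
    features: pd.DataFrame,
    metrics: pd.DataFrame,
    spheroids: pd.DataFrame,
    cell_lines: dict[str, str] | None = None,
) -> list[ConditionSummary]:
    """Aggregate per-cell tables into one summary per condition.

    ``features`` needs `condition` plus the 11 feature columns; ``metrics``
    needs `condition, speed, persistence`; ``spheroids`` needs
    `condition, fold_change`. Conditions missing a modality are dropped with
    a warning; an empty intersection is an error.
    """
    sets = [set(t["condition"].unique()) for t in (features, metrics, spheroids)]
    common = sorted(sets[0] & sets[1] & sets[2])
    if not common:
        raise ValueError("no condition appears in all three tables")
    union = sets[0] | sets[1] | sets[2]
    missing = union - set(common)
    if missing:
        warnings.warn(f"conditions missing a modality were dropped: {sorted(missing)}")
    out = []
    for cond in common:
        f = features[features["condition"] == cond]
        m = metrics[metrics["condition"] == cond]
        s = spheroids[spheroids["condition"] == cond]
        out.append(ConditionSummary(
            condition=cond,
            cell_line=(cell_lines or {}).get(cond, ""),
            mean_features={k: float(f[k].mean()) for k in FEATURE_NAMES},
            mean_speed=float(m["speed"].mean()),
            mean_persistence=float(m["persistence"].mean()),
            mean_invasion=float(s["fold_change"].mean()),
            n_cells=len(f),
        ))
    return out


def summary_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Summaries as a DataFrame indexed by condition."""
    rows = {}
    for s in summaries:
        row = dict(s.mean_features)
        row.update(speed=s.mean_speed, persistence=s.mean_persistence,
                   invasion=s.mean_invasion, n_cells=s.n_cells,
                   cell_line=s.cell_line)
        rows[s.condition] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Rank-correlation / average-linkage clustering


def _spearman_distance_matrix(M: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Spearman rho between rows of M."""
    ranks = np.apply_along_axis(rankdata, 1, M)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("constant row: Spearman correlation undefined")
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    return 1.0 - np.clip(rho, -1.0, 1.0)


def _average_linkage(dist: np.ndarray, labels: list[str]) -> tuple[np.ndarray, list[int]]:
    """Agglomerative average linkage with deterministic tie-breaking.

    Returns a linkage matrix in the SciPy convention (cluster a, cluster b,
    height, size) and the dendrogram leaf order. When two candidate merges
    have exactly equal height, the pair whose (lexicographically smallest
    member label, other member label) sorts first is merged.
    """
    n = len(labels)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}  # cluster id -> leaves
    keys: dict[int, tuple[str, ...]] = {i: (labels[i],) for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    Z = np.zeros((n - 1, 4))
    children: dict[int, tuple[int, int]] = {}
    next_id = n
    for step in range(n - 1):
        best = min(
            d.items(),
            key=lambda kv: (kv[1], min(keys[kv[0][0]], keys[kv[0][1]]),
                            max(keys[kv[0][0]], keys[kv[0][1]])),
        )
        (a, b), h = best
        na, nb = len(active[a]), len(active[b])
        Z[step] = (a, b, h, na + nb)
        children[next_id] = (a, b) if keys[a] <= keys[b] else (b, a)
        # average-linkage update
        for c in list(active):
            if c in (a, b):
                continue
            key_a = (min(a, c), max(a, c))
            key_b = (min(b, c), max(b, c))
            d[(min(next_id, c), max(next_id, c))] = (
                na * d.pop(key_a) + nb * d.pop(key_b)
            ) / (na + nb)
        d.pop((min(a, b), max(a, b)))
        active[next_id] = active.pop(a) + active.pop(b)
        keys[next_id] = min(keys[a], keys[b])
        next_id += 1

    def _leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        l, r = children[node]
        return _leaves(l) + _leaves(r)

    return Z, _leaves(next_id - 1)


@dataclass
class HeatmapClustering:
    matrix: pd.DataFrame              # mean-centered, rows/cols reordered
    linkage: np.ndarray               # SciPy-convention merge tree
    leaf_order: list[str]
    dropped: list[str] = field(default_factory=list)


def cluster_heatmap(summaries: list[ConditionSummary], which: str = "conditions") -> HeatmapClustering:
    """Cluster condition profiles (or features) by rank correlation.

    The condition x feature matrix of 11 shape means is mean-centered per
    feature; items (rows for ``which='conditions'``, columns for
    ``which='features'``) are clustered with distance 1 - Spearman rho and
    average linkage. Constant items make Spearman undefined and are dropped
    with a warning.
    """
    if which not in {"conditions", "features"}:
        raise ValueError("which must be 'conditions' or 'features'")
    M = pd.DataFrame(
        {s.condition: s.mean_features for s in summaries}
    ).T[list(FEATURE_NAMES)]
    if len(summaries) != len(M):
        raise ValueError("duplicate condition names in summaries")
    M = M - M.mean(axis=0)  # mean-center each feature across conditions
    items = M if which == "conditions" else M.T
    if len(items) < 3:
        raise ValueError("need at least 3 items to cluster")
    dropped = []
    keep = []
    for name, row in items.iterrows():
        if np.ptp(rankdata(row.to_numpy())) == 0:
            dropped.append(str(name))
        else:
            keep.append(name)
    if dropped:
        warnings.warn(f"constant profiles dropped (Spearman undefined): {dropped}")
    items = items.loc[keep]
    labels = [str(i) for i in items.index]
    dist = _spearman_distance_matrix(items.to_numpy(float))
    Z, order = _average_linkage(dist, labels)
    leaf_order = [labels[i] for i in order]
    reordered = items.loc[leaf_order]
    matrix = reordered if which == "conditions" else reordered.T
    return HeatmapClustering(matrix=matrix, linkage=Z, leaf_order=leaf_order, dropped=dropped)


# ---------------------------------------------------------------------------
# kNN graph + layout hook, PCA


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def knn_graph(features: pd.DataFrame, k: int, layout: str = "spring") -> EmbeddingResult:
    """Euclidean kNN graph in standardized feature space plus 2D layout.

    ``features`` holds one row per cell with the 11 feature columns.
    Duplicate points yield zero-length edges, which are permitted. The layout
    (networkx spring with a fixed seed, or ``'spectral'``) is a deterministic
    visualization hook, not a quantitative output.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = features[list(FEATURE_NAMES)].to_numpy(float)
    n = len(X)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(_standardize(X))
    _, idx = nn.kneighbors()
    edges = [(i, int(j)) for i in range(n) for j in idx[i, :k]]

    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(edges)
    if layout == "spring":
        pos = nx.spring_layout(G, seed=0)
    elif layout == "spectral":
        pos = nx.spectral_layout(G)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    coords = np.array([pos[i] for i in range(n)])
    return EmbeddingResult(coordinates=coords, edges=edges, k=k)


def pca(features: pd.DataFrame, n_components: int):
    """PCA on standardized features.

    Returns ``(scores, loadings, variance_fractions)``; fractions are
    non-increasing and sum to <= 1.
    """
    cols = [c for c in FEATURE_NAMES if c in features.columns]
    X = features[cols].to_numpy(float)
    if n_components > len(cols):
        raise ValueError(f"n_components={n_components} exceeds {len(cols)} features")
    if len(X) < n_components:
        raise ValueError("fewer cells than components")
    from sklearn.decomposition import PCA

    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(_standardize(X))
    return scores, model.components_, model.explained_variance_ratio_
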