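"""Activation network from cross-replica correlation of per-residue divergences.

Residues whose divergence from the dark state co-varies across replicas are
considered part of a common activation process.  The per-replica (normalized)
KLD profiles form a replica x residue matrix; Pearson correlation between
residue columns yields a residue x residue matrix that, binarized at a
threshold (default 0.86, keeping only the strong correlations), defines an
undirected graph on which components, communities, centralities and pathways
between named residue sets are computed with NetworkX.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .errors import SelectionError, ShapeError
from .divergence import KLDProfile
from .trajectory_io import RegionSet

__all__ = [
    "kld_matrix",
    "residue_correlation",
    "region_reference_map",
    "threshold_adjacency",
    "edge_count_curve",
    "ActivationNetwork",
    "build_network",
    "NetworkMetrics",
    "graph_metrics",
]

DEFAULT_THRESHOLD = 0.86


def kld_matrix(profiles: list[KLDProfile], normalized: bool = True) -> np.ndarray:
    """Stack replica profiles into a (n_replicas, n_residues) matrix.

    With ``normalized`` each profile is scaled by its own maximum, putting
    replicas on a comparable scale before correlation.
    """
    if not profiles:
        raise ShapeError("no profiles")
    rows = [p.normalized() if normalized else p.values for p in profiles]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ShapeError("profiles have differing lengths")
    return np.stack(rows)


def residue_correlation(kld: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Correlation between residue columns across replicas.

    Residues with zero variance across replicas have undefined correlations;
    their rows/columns are returned as NaN and treated as non-edges downstream.
    """
    kld = np.asarray(kld, dtype=float)
    if kld.ndim != 2:
        raise ShapeError("KLD matrix must be 2-D (replicas x residues)")
    n_rep, n_res = kld.shape
    if n_rep < 3:
        raise ShapeError(f"correlation needs >= 3 replicas, got {n_rep}")
    if np.any(kld < 0):
        raise ShapeError("KLD values must be non-negative")
    if method == "spearman":
        from scipy.stats import rankdata
        kld = rankdata(kld, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    centered = kld - kld.mean(axis=0)
    std = centered.std(axis=0)
    valid = std > 0
    corr = np.full((n_res, n_res), np.nan)
    if valid.any():
        sub = centered[:, valid] / std[valid]
        c = (sub.T @ sub) / n_rep
        np.clip(c, -1.0, 1.0, out=c)
        np.fill_diagonal(c, 1.0)
        ix = np.where(valid)[0]
        corr[np.ix_(ix, ix)] = c
    return corr


def region_reference_map(corr: np.ndarray, region: str | tuple[int, int],
                         regions: RegionSet) -> np.ndarray:
    """Mean correlation of every residue to the members of one region.

    Self-pairs are excluded, so a region member's value is its mean correlation
    to the *other* members.
    """
    residues = regions.residues(region)
    if residues.size == 0:
        raise SelectionError(f"region {region!r} is empty")
    n_res = corr.shape[0]
    cols = residues - 1
    out = np.empty(n_res)
    for i in range(n_res):
        others = cols[cols != i]
        if others.size == 0:
            out[i] = np.nan
        else:
            out[i] = np.nanmean(corr[i, others])
    return out


def threshold_adjacency(corr: np.ndarray, theta: float = DEFAULT_THRESHOLD,
                        mode: str = "signed") -> np.ndarray:
    """Binarize the correlation matrix: edge iff r_ij >= theta (i != j).

    ``mode='signed'`` keeps only strong positive correlations (default);
    ``mode='absolute'`` thresholds |r|.  NaN (undefined) entries never form
    edges.
    """
    if not (0.0 < theta < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {theta}")
    corr = np.asarray(corr, dtype=float)
    vals = np.abs(corr) if mode == "absolute" else corr
    with np.errstate(invalid="ignore"):
        adj = vals >= theta
    adj &= ~np.isnan(corr)
    np.fill_diagonal(adj, False)
    if not np.array_equal(adj, adj.T):
        adj &= adj.T  # enforce symmetry against asymmetric NaN patterns
    return adj


def edge_count_curve(corr: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Number of edges at each threshold (audit of the threshold choice)."""
    return np.array([int(threshold_adjacency(corr, th).sum() // 2)
                     for th in np.asarray(thetas)])


@dataclass
class ActivationNetwork:
    """Correlation matrix, thresholded adjacency and node metadata."""

    corr: np.ndarray
    theta: float
    adjacency: np.ndarray
    node_regions: list[str] = field(default_factory=list)
    tetrad_flags: np.ndarray | None = None

    @property
    def n_residues(self) -> int:
        return self.corr.shape[0]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_residues):
            attrs = {"residue": i + 1}
            if self.node_regions:
                attrs["region"] = self.node_regions[i]
            if self.tetrad_flags is not None:
                attrs["tetrad"] = bool(self.tetrad_flags[i])
            g.add_node(i + 1, **attrs)
        for i, j in zip(*np.where(np.triu(self.adjacency, k=1))):
            g.add_edge(int(i) + 1, int(j) + 1, weight=float(self.corr[i, j]))
        return g


def build_network(corr: np.ndarray, theta: float = DEFAULT_THRESHOLD,
                  regions: RegionSet | None = None,
                  mode: str = "signed") -> ActivationNetwork:
    adj = threshold_adjacency(corr, theta, mode=mode)
    n_res = corr.shape[0]
    node_regions, tetrad_flags = [], np.zeros(n_res, dtype=bool)
    if regions is not None:
        node_regions = [regions.label_of(i + 1) for i in range(n_res)]
        tetrad = regions.residue_sets.get("tetrad", {})
        for r in tetrad.values():
            tetrad_flags[r - 1] = True
    return ActivationNetwork(corr=corr, theta=theta, adjacency=adj,
                             node_regions=node_regions, tetrad_flags=tetrad_flags)


@dataclass
class NetworkMetrics:
    """Graph structure of the activation network."""

    components: list[set[int]]
    communities: list[set[int]]
    degree: dict[int, int]
    betweenness: dict[int, float]
    paths: dict[str, dict]
    layout: dict[int, tuple[float, float]]


def _set_to_set_path(g: nx.Graph, sources: set[int], targets: set[int]) -> dict:
    """Shortest path between two node sets: existence, length, intermediates."""
    best = None
    for s in sources:
        if s not in g:
            continue
        lengths, paths = nx.single_source_dijkstra(g, s, weight=None)
        for t in targets:
            if t in lengths and (best is None or lengths[t] < best[0]):
                best = (lengths[t], paths[t])
    if best is None:
        return {"exists": False, "length": None, "path": []}
    return {"exists": True, "length": int(best[0]), "path": [int(n) for n in best[1]]}


def graph_metrics(
    net: ActivationNetwork,
    regions: RegionSet | None = None,
    path_queries: dict[str, tuple[str, str]] | None = None,
    seed: int = 0,
) -> NetworkMetrics:
    """Components, greedy-modularity communities, centralities, pathways, layout.

    ``path_queries`` maps a label to a (source region, target region) pair;
    defaults to tetrad -> CT / EEE / PBL when a registry is given.  An empty
    graph yields empty collections rather than an exception.  Isolated nodes
    are kept in the graph but excluded from community detection.
    """
    g = net.graph()
    non_isolated = g.subgraph([n for n, d in g.degree() if d > 0])
    components = [set(c) for c in nx.connected_components(non_isolated)]
    if non_isolated.number_of_nodes():
        communities = [set(c) for c in
                       nx.community.greedy_modularity_communities(non_isolated)]
        betweenness = nx.betweenness_centrality(non_isolated)
    else:
        communities, betweenness = [], {}
    degree = {n: d for n, d in g.degree()}

    paths: dict[str, dict] = {}
    if path_queries is None and regions is not None:
        path_queries = {f"tetrad->{t}": ("tetrad", t) for t in ("CT", "EEE", "PBL")}
    if path_queries and regions is not None:
        for label, (src, dst) in path_queries.items():
            s = set(int(r) for r in regions.residues(src))
            t = set(int(r) for r in regions.residues(dst))
            paths[label] = _set_to_set_path(non_isolated, s, t)

    layout = nx.spring_layout(g, seed=seed)
    layout = {int(n): (float(p[0]), float(p[1])) for n, p in layout.items()}
    return NetworkMetrics(components=components, communities=communities,
                          degree=degree, betweenness=betweenness,
                          paths=paths, layout=layout)
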