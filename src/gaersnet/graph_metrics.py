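"""Density thresholding and graph metrics with random-network normalization.

A connectivity matrix is thresholded to a stated average density k (exactly
floor(R*k/2) strongest edges, e.g. 360 edges at k = 10 for 72 regions).  On
the resulting network, clustering and characteristic path length are
computed on the binarized graph (strength is the only weighted metric) and
normalized against the mean of matched uniform random graphs with the same
number of nodes and edges: gamma = C/C_rand, lambda = L/L_rand, and the
small-world index sigma = gamma/lambda.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "ThresholdedNetwork",
    "GlobalMetrics",
    "threshold_to_density",
    "count_components",
    "global_metrics",
    "node_metrics",
    "hub_scores",
]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Undirected weighted graph at a stated average density k.

    ``edges``: tuple of (i, j, weight) with i < j, weights > 0, no
    self-loops; ``k``: target mean degree; ``m``: realized edge count.
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[int, int, float], ...]
    k: float
    m: int

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        edges = tuple((int(i), int(j), float(w)) for i, j, w in self.edges)
        R = len(labels)
        seen = set()
        for i, j, w in edges:
            if i == j:
                raise ValueError("self-loops are not allowed")
            if not (0 <= i < j < R):
                raise ValueError("edge endpoints must be ordered node indices")
            if w <= 0:
                raise ValueError("edge weights must be positive")
            seen.add((i, j))
        if len(seen) != len(edges):
            raise ValueError("duplicate edges")
        if self.m != len(edges):
            raise ValueError("m must equal the number of edges")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "edges", edges)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def adjacency(self, weighted: bool = False) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes))
        for i, j, w in self.edges:
            a[i, j] = a[j, i] = w if weighted else 1.0
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for i, j, w in self.edges:
            g.add_edge(self.labels[i], self.labels[j], weight=w)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, k: Optional[float] = None) -> "ThresholdedNetwork":
        labels = tuple(str(n) for n in g.nodes())
        index = {n: i for i, n in enumerate(g.nodes())}
        edges = []
        for u, v, data in g.edges(data=True):
            i, j = sorted((index[u], index[v]))
            edges.append((i, j, float(data.get("weight", 1.0))))
        edges.sort()
        m = len(edges)
        kk = k if k is not None else 2.0 * m / max(len(labels), 1)
        return cls(labels=labels, edges=tuple(edges), k=kk, m=m)


def threshold_to_density(matrix: ConnectivityMatrix, k: float) -> ThresholdedNetwork:
    """Keep exactly floor(R*k/2) strongest positive edges.

    Ties at the cutoff weight are broken deterministically by lexicographic
    (i, j) node order.  Raises if the matrix has too few positive edges,
    reporting the maximum achievable mean degree.
    """
    R = matrix.n_regions
    m_target = int(np.floor(R * k / 2.0))
    iu, ju = np.triu_indices(R, k=1)
    w = matrix.weights[iu, ju]
    pos = w > 0
    n_pos = int(pos.sum())
    if m_target > n_pos:
        raise ValueError(
            f"only {n_pos} positive edges available; maximum achievable mean "
            f"degree is {2.0 * n_pos / R:.3f} (requested k={k})"
        )
    order = np.lexsort((ju[pos], iu[pos], -w[pos]))
    keep = order[:m_target]
    edges = tuple(
        (int(iu[pos][idx]), int(ju[pos][idx]), float(w[pos][idx])) for idx in keep
    )
    edges = tuple(sorted(edges))
    return ThresholdedNetwork(labels=matrix.labels, edges=edges, k=k, m=m_target)


def count_components(net: ThresholdedNetwork) -> int:
    """Number of connected components (isolated nodes count)."""
    a = csr_matrix(net.adjacency())
    n, _ = connected_components(a, directed=False)
    return int(n)


def _binary_clustering(a: np.ndarray) -> float:
    """Mean binary local clustering coefficient (0 for degree < 2 nodes)."""
    deg = a.sum(axis=1)
    tri = np.diag(a @ a @ a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c.mean())


def _hop_path_length(a: np.ndarray) -> tuple[float, bool]:
    """Mean shortest hop count over ordered reachable pairs.

    Returns (L, connected).  For disconnected graphs, L is computed on the
    largest connected component.
    """
    sp = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    finite = np.isfinite(sp)
    np.fill_diagonal(finite, False)
    connected = bool(finite.sum() == a.shape[0] * (a.shape[0] - 1))
    if connected:
        off = ~np.eye(a.shape[0], dtype=bool)
        return float(sp[off].mean()), True
    n_comp, lab = connected_components(csr_matrix(a), directed=False)
    sizes = np.bincount(lab)
    big = lab == sizes.argmax()
    sub = sp[np.ix_(big, big)]
    off = ~np.eye(int(big.sum()), dtype=bool)
    return float(sub[off].mean()), False


@dataclass(frozen=True)
class GlobalMetrics:
    """Global network parameters with random-null normalization.

    ``gamma = C / C_rand``, ``lam = L / L_rand``, ``sigma = gamma / lam``;
    nulls are uniform random graphs with identical node and edge counts
    (disconnected draws resampled and counted).
    """

    clustering: float
    path_length: float
    clustering_rand: float
    path_length_rand: float
    gamma: float
    lam: float
    sigma: float
    n_components: int
    n_null: int
    n_resampled: int
    connected: bool


def _random_gnm_adjacency(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    pairs = n * (n - 1) // 2
    chosen = rng.choice(pairs, size=m, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    a = np.zeros((n, n))
    a[iu[chosen], ju[chosen]] = 1.0
    return a + a.T


def global_metrics(
    net: ThresholdedNetwork, n_null: int = 1000, seed: int = 0,
    max_resample: int = 100_000,
) -> GlobalMetrics:
    """Clustering, path length, and small-world index vs matched nulls.

    C is the mean binary local clustering coefficient; L the mean shortest
    hop count over ordered node pairs (largest component, with a flag, if
    the input is disconnected).  The null model is Erdos-Renyi G(n, m) with
    the same node and edge counts; disconnected nulls are resampled.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    a = net.adjacency()
    c_obs = _binary_clustering(a)
    l_obs, connected = _hop_path_length(a)
    if not connected:
        warnings.warn(
            "network is disconnected; path length computed on the largest component"
        )
    rng = np.random.default_rng(seed)
    n, m = net.n_nodes, net.m
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    n_resampled = 0
    for i in range(n_null):
        while True:
            ar = _random_gnm_adjacency(n, m, rng)
            nc, _ = connected_components(csr_matrix(ar), directed=False)
            if nc == 1:
                break
            n_resampled += 1
            if n_resampled > max_resample:
                raise RuntimeError("too many disconnected null draws; density too low")
        c_null[i] = _binary_clustering(ar)
        l_null[i], _ = _hop_path_length(ar)
    c_rand = float(c_null.mean())
    l_rand = float(l_null.mean())
    gamma = c_obs / c_rand if c_rand > 0 else np.inf
    lam = l_obs / l_rand if l_rand > 0 else np.inf
    return GlobalMetrics(
        clustering=c_obs,
        path_length=l_obs,
        clustering_rand=c_rand,
        path_length_rand=l_rand,
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        n_components=count_components(net),
        n_null=n_null,
        n_resampled=n_resampled,
        connected=connected,
    )


def node_metrics(net: ThresholdedNetwork) -> pd.DataFrame:
    """Per-node table: degree, strength, clustering, path length, betweenness.

    Degree, clustering, average shortest (hop) path length to reachable
    nodes, and normalized shortest-path betweenness are binary; strength is
    the sum of incident edge weights.
    """
    g = net.to_networkx()
    a = net.adjacency()
    deg = dict(g.degree())
    strength = dict(g.degree(weight="weight"))
    clustering = nx.clustering(g)  # binary (no weight argument)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    sp = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    np.fill_diagonal(sp, np.inf)
    apl = []
    for i in range(net.n_nodes):
        row = sp[i]
        reach = np.isfinite(row)
        apl.append(float(row[reach].mean()) if reach.any() else np.inf)
    labels = list(net.labels)
    df = pd.DataFrame(
        {
            "degree": [deg.get(lab, 0) for lab in labels],
            "strength": [strength.get(lab, 0.0) for lab in labels],
            "clustering": [clustering.get(lab, 0.0) for lab in labels],
            "path_length": apl,
            "betweenness": [betweenness.get(lab, 0.0) for lab in labels],
        },
        index=pd.Index(labels, name="region"),
    )
    return df


_HUB_FORMULA = (
    "hub_score = mean(zscore(degree), zscore(betweenness), zscore(-path_length)); "
    "zscore uses the within-network mean and population SD; a zero-variance "
    "metric contributes 0"
)


def hub_scores(table: pd.DataFrame) -> pd.Series:
    """Composite hub score per node.

    Flags nodes that combine many connections (degree), high shortest-path
    betweenness centrality, and short average path length.  Each metric is
    standardized within the network and the three standard scores averaged
    (path length with negative sign).  The exact formula is recorded in the
    result's ``attrs["formula"]``.
    """
    required = {"degree", "betweenness", "path_length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"node metrics table lacks columns: {sorted(missing)}")
    comps = []
    for col, sign in (("degree", 1.0), ("betweenness", 1.0), ("path_length", -1.0)):
        x = sign * table[col].to_numpy(dtype=float)
        sd = x.std()
        # guard against floating-point jitter on symmetric graphs
        if sd <= 1e-9 * max(1.0, float(np.abs(x).max())):
            warnings.warn(f"zero variance in {col}; component contributes 0")
            comps.append(np.zeros_like(x))
        else:
            comps.append((x - x.mean()) / sd)
    score = pd.Series(np.mean(comps, axis=0), index=table.index, name="hub_score")
    score.attrs["formula"] = _HUB_FORMULA
    return score
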