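"""Comparator centralities: degree, closeness, k-shell, betweenness,
eigenvector and a simplified undamped PageRank iteration.

Standard algorithms delegate to networkx; this module fixes the conventions
used throughout the package (union-neighbor degree, total-degree k-shell on
directed graphs, reachable-only closeness on disconnected graphs) and the
simplified PageRank update, which differs from networkx's damped variant.

Weighted graphs interpret edge weight as *length* for the shortest-path
centralities (closeness, betweenness); since many networks carry affinity
weights (larger = closer), an inverse-weight option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .graph_core import Network, neighbors

__all__ = [
    "CentralityVector",
    "degree_centrality",
    "closeness_centrality",
    "k_shell",
    "betweenness_centrality",
    "eigenvector_centrality",
    "pagerank_simple",
    "BASELINE_METHODS",
    "compute_baseline",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge within the iteration budget."""


@dataclass(frozen=True)
class CentralityVector:
    """A named per-node score map, one finite score per node."""

    method: str
    scores: dict[str, float]

    def __post_init__(self):
        bad = [v for v, s in self.scores.items() if not np.isfinite(s)]
        if bad:
            raise ValueError(f"non-finite score for nodes {bad[:5]}")


def _length_graph(net: Network, invert_weights: bool):
    g = net.to_networkx()
    if net.weighted and invert_weights:
        for u, v, d in g.edges(data=True):
            d["weight"] = 1.0 / d["weight"]
    return g


def degree_centrality(net: Network) -> CentralityVector:
    """Neighbor count per node (union of in/out neighbors when directed)."""
    return CentralityVector(
        "degree", {v: float(len(neighbors(net, v))) for v in net.nodes}
    )


def in_degree_centrality(net: Network) -> CentralityVector:
    g = net.to_networkx()
    deg = g.in_degree() if net.directed else g.degree()
    return CentralityVector("in_degree", {v: float(d) for v, d in deg})


def out_degree_centrality(net: Network) -> CentralityVector:
    g = net.to_networkx()
    deg = g.out_degree() if net.directed else g.degree()
    return CentralityVector("out_degree", {v: float(d) for v, d in deg})


def closeness_centrality(
    net: Network, invert_weights: bool = False
) -> CentralityVector:
    """Reciprocal farness: 1 / Σ_y d(x, y) over nodes *reachable from* x,
    0 when x reaches nothing.  Weighted graphs use weighted shortest paths
    with weight read as length (see ``invert_weights``)."""
    g = _length_graph(net, invert_weights)
    weight = "weight" if net.weighted else None
    out = {}
    for v in net.nodes:
        dists = nx.single_source_dijkstra_path_length(g, v, weight=weight)
        total = sum(d for u, d in dists.items() if u != v)
        out[v] = 1.0 / total if total > 0 else 0.0
    return CentralityVector("closeness", out)


def k_shell(net: Network) -> CentralityVector:
    """Shell index per node by iterative minimum-degree pruning.
    Directed networks use total (in+out) degree."""
    g = net.to_networkx()
    if net.directed:
        g = nx.Graph(g.to_undirected())  # core_number uses total degree anyway
    cores = nx.core_number(g)
    return CentralityVector("k_shell", {v: float(c) for v, c in cores.items()})


def betweenness_centrality(
    net: Network, normalized: bool = True, invert_weights: bool = False
) -> CentralityVector:
    """Fraction of shortest paths through each node; normalization divides
    by (n−1)(n−2) for directed and (n−1)(n−2)/2 for undirected graphs."""
    g = _length_graph(net, invert_weights)
    weight = "weight" if net.weighted else None
    bc = nx.betweenness_centrality(g, normalized=normalized, weight=weight)
    return CentralityVector("betweenness", {v: float(s) for v, s in bc.items()})


def eigenvector_centrality(
    net: Network, max_iter: int = 1000, tol: float = 1e-10
) -> CentralityVector:
    """Dominant-eigenvector scores by power iteration on the (symmetrised
    view for undirected) adjacency matrix, normalized to unit sum.

    Convergence: successive iterates differ by < tol in max-norm.

    Raises
    ------
    ConvergenceError
        If the iteration budget is exhausted (reports the residual).
    ValueError
        If the network has no edges.
    """
    if net.n_edges == 0:
        raise ValueError("eigenvector centrality needs at least one edge")
    order = sorted(net.nodes)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for (u, v), w in net.edges.items():
        a[idx[u], idx[v]] = w
        if not net.directed:
            a[idx[v], idx[u]] = w
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        # x_v ∝ Σ_u A[u,v] x_u (left eigenvector: score flows along edges)
        y = a.T @ x
        norm = y.sum()
        if norm == 0:
            # no mass flows (e.g. pure sink structure); fall back to A x
            y = a @ x
            norm = y.sum()
            if norm == 0:
                raise ConvergenceError("adjacency iteration collapsed to zero")
        y /= norm
        resid = float(np.max(np.abs(y - x)))
        x = y
        if resid < tol:
            return CentralityVector(
                "eigenvector", {v: float(x[idx[v]]) for v in order}
            )
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} steps "
        f"(residual {resid:.3e})"
    )


def pagerank_simple(
    net: Network, iterations: int = 100, damping: float | None = None
) -> CentralityVector:
    """Simplified PageRank: uniform start summing to 1, then repeated
    multiplication by the column-normalized transition matrix,
    ``PR ← Tᵀ·PR``.  Dangling nodes redistribute their mass uniformly so
    Σ PR = 1 at every iteration.  ``damping`` is off by default; pass e.g.
    0.85 for the classical damped update."""
    order = sorted(net.nodes)
    n = len(order)
    if n == 0:
        return CentralityVector("pagerank", {})
    idx = {v: i for i, v in enumerate(order)}
    t = np.zeros((n, n))  # t[u, v] = probability of stepping u -> v
    for (u, v), w in net.edges.items():
        t[idx[u], idx[v]] = w
        if not net.directed:
            t[idx[v], idx[u]] = w
    out_sum = t.sum(axis=1)
    dangling = out_sum == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(out_sum[:, None] > 0, t / out_sum[:, None], 0.0)
    pr = np.full(n, 1.0 / n)
    for _ in range(iterations):
        new = t.T @ pr + pr[dangling].sum() / n
        if damping is not None:
            new = (1 - damping) / n + damping * new
        pr = new / new.sum()  # guard drift; analytically sum is already 1
    return CentralityVector("pagerank", {v: float(pr[idx[v]]) for v in order})


BASELINE_METHODS = {
    "degree": degree_centrality,
    "closeness": closeness_centrality,
    "k_shell": k_shell,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
    "pagerank": pagerank_simple,
}


def compute_baseline(net: Network, method: str) -> CentralityVector:
    """Dispatch a baseline centrality by name.

    Externally computed score files (for centralities this package does not
    reimplement) can be registered via :func:`load_score_file` instead.
    """
    try:
        fn = BASELINE_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; available: {sorted(BASELINE_METHODS)}"
        ) from None
    return fn(net)


def load_score_file(path, method: str) -> CentralityVector:
    """Register an externally computed centrality from a 2-column TSV
    (node, score) as a named method."""
    scores = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("%", "#")):
                continue
            node, score = line.split()[:2]
            scores[node] = float(score)
    return CentralityVector(method, scores)
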