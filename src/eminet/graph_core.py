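"""Graph data model, neighbor semantics and edge-list IO.

The central object is :class:`Network`, a light container for a directed or
undirected, weighted or unweighted graph.  Network type is always *declared*
(via the ``directed`` / ``weighted`` flags), never inferred from file
contents: which entropy components enter a node's importance score depends on
these flags, so silent misdetection would silently change results.

Neighborhood semantics: for directed graphs the neighbor set of ``v`` is the
union of its in- and out-neighbors.  Two nodes are neighbors whenever an edge
connects them in either direction; all entropy and mutual-power computations
rest on this convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

log = logging.getLogger(__name__)

__all__ = [
    "Network",
    "DegreeRecord",
    "load_edge_list",
    "write_edge_list",
    "neighbors",
    "degree_record",
    "secondary_neighbors",
    "toy_network",
    "describe",
    "EdgeListParseError",
    "UnknownNodeError",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class UnknownNodeError(KeyError):
    """Raised when an operation references a node absent from the network."""


@dataclass
class Network:
    """A directed or undirected, weighted or unweighted network.

    Invariants maintained by the constructors in this module:

    * no self-loops;
    * each ordered node pair appears at most once (parallel edges merged by
      weight summation);
    * if ``weighted`` is ``False`` every stored weight is 1;
    * ``nodes`` contains every edge endpoint (plus any isolated nodes).

    For undirected networks an edge is stored once under a canonical
    orientation; :meth:`edge_weight` looks up both orientations.
    """

    directed: bool = True
    weighted: bool = True
    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], float] = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_node(self, v: str) -> None:
        self.nodes.add(v)

    def add_edge(self, u: str, v: str, w: float = 1.0) -> None:
        """Add edge ``u -> v`` (or ``u -- v``), merging parallels by weight sum.

        Self-loops are dropped with a warning: every score here is defined
        over neighbor sets that exclude the node itself.
        """
        if u == v:
            log.warning("dropping self-loop at node %r", u)
            self.nodes.add(u)
            return
        if not self.weighted:
            w = 1.0
        key = (u, v)
        if not self.directed and (v, u) in self.edges:
            key = (v, u)
        if key in self.edges:
            if self.weighted:
                self.edges[key] += w
            # unweighted: duplicate collapses to the single unit edge
        else:
            self.edges[key] = w
        self.nodes.add(u)
        self.nodes.add(v)

    # -- queries ------------------------------------------------------

    def __contains__(self, v: str) -> bool:
        return v in self.nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_weight(self, u: str, v: str) -> float | None:
        """Weight of edge u->v (directed) or u--v (undirected); None if absent."""
        w = self.edges.get((u, v))
        if w is None and not self.directed:
            w = self.edges.get((v, u))
        return w

    def max_weight(self) -> float:
        if not self.edges:
            raise ValueError("network has no edges")
        return max(self.edges.values())

    def out_neighbors(self, v: str) -> set[str]:
        self._check_node(v)
        if self.directed:
            return {t for (s, t) in self.edges if s == v}
        return neighbors(self, v)

    def in_neighbors(self, v: str) -> set[str]:
        self._check_node(v)
        if self.directed:
            return {s for (s, t) in self.edges if t == v}
        return neighbors(self, v)

    def _check_node(self, v: str) -> None:
        if v not in self.nodes:
            raise UnknownNodeError(f"node {v!r} not in network")

    def to_networkx(self):
        """Export to a networkx (Di)Graph with ``weight`` edge attributes."""
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for (u, v), w in self.edges.items():
            g.add_edge(u, v, weight=w)
        return g


@dataclass(frozen=True)
class DegreeRecord:
    """In/out degree counts and in/out weight sums (strengths) of one node.

    For undirected networks ``d_in == d_out`` (the plain degree) and
    ``w_in == w_out`` (the strength); for unweighted networks the weight
    sums equal the degree counts.
    """

    node: str
    d_in: int
    d_out: int
    w_in: float
    w_out: float


def load_edge_list(
    path,
    directed: bool,
    weighted: bool,
    shift_nonpositive_weights: bool = True,
) -> Network:
    """Read a whitespace-separated edge list into a :class:`Network`.

    Accepts 2 or 3 columns (``source target [weight]``); lines starting with
    ``%`` or ``#`` are comments (KONECT ``out.*`` headers parse as-is).
    A missing weight column yields weight 1.  Duplicate ordered pairs have
    their weights summed; self-loops are dropped with a warning.

    If any weight is ≤ 0 and ``shift_nonpositive_weights`` is on, all
    weights are shifted by ``w' = w − w_min + 1`` so they form a valid
    probability mass when normalised (signed affinity scales such as the
    −1…+3 friendship ratings some social networks use become 1…5).

    Raises
    ------
    EdgeListParseError
        On a malformed line (names the line number), or when a 3-column
        file is loaded with ``weighted=False`` (refusing silent truncation).
    """
    raw: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("%", "#")):
                continue
            parts = line.split()
            if len(parts) == 2:
                u, v = parts
                w = 1.0
            elif len(parts) == 3:
                if not weighted:
                    raise EdgeListParseError(
                        f"line {lineno}: file has a weight column but "
                        "weighted=False; refusing to discard weights"
                    )
                u, v = parts[0], parts[1]
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise EdgeListParseError(
                        f"line {lineno}: bad weight {parts[2]!r}"
                    ) from exc
            else:
                raise EdgeListParseError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            raw.append((u, v, w))

    if weighted and raw and shift_nonpositive_weights:
        w_min = min(w for _, _, w in raw)
        if w_min <= 0:
            log.warning(
                "non-positive weights present (min %g); shifting all weights "
                "by %g so the smallest becomes 1",
                w_min,
                1 - w_min,
            )
            raw = [(u, v, w - w_min + 1) for u, v, w in raw]

    net = Network(directed=directed, weighted=weighted)
    for u, v, w in raw:
        net.add_edge(u, v, w)
    return net


def write_edge_list(net: Network, path) -> None:
    """Write a network as a TSV edge list (weight column only if weighted)."""
    with open(path, "w") as fh:
        fh.write(
            "%% eminet edge list; directed=%s weighted=%s\n"
            % (net.directed, net.weighted)
        )
        for (u, v), w in sorted(net.edges.items()):
            if net.weighted:
                fh.write(f"{u}\t{v}\t{w:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def neighbors(net: Network, v: str) -> set[str]:
    """Neighbor set of ``v``: all nodes connected to it by an edge in either
    direction (union of in- and out-neighbors for directed networks)."""
    net._check_node(v)
    out = set()
    for s, t in net.edges:
        if s == v:
            out.add(t)
        elif t == v:
            out.add(s)
    return out


def degree_record(net: Network, v: str) -> DegreeRecord:
    """Per-node degree counts and weight sums (see :class:`DegreeRecord`)."""
    net._check_node(v)
    d_in = d_out = 0
    w_in = w_out = 0.0
    for (s, t), w in net.edges.items():
        if net.directed:
            if s == v:
                d_out += 1
                w_out += w
            if t == v:
                d_in += 1
                w_in += w
        else:
            if s == v or t == v:
                d_in += 1
                d_out += 1
                w_in += w
                w_out += w
    return DegreeRecord(node=v, d_in=d_in, d_out=d_out, w_in=w_in, w_out=w_out)


def secondary_neighbors(net: Network, v: str) -> set[str]:
    """Nodes adjacent to a neighbor of ``v`` but not to ``v`` itself
    (and not ``v``) — the distance-two shell."""
    first = neighbors(net, v)
    second: set[str] = set()
    for u in first:
        second |= neighbors(net, u)
    return second - first - {v}


def toy_network() -> Network:
    """The four-node directed, weighted worked-example network.

    Edges: a→b (w=1), a→d (w=4), b→c (w=2), c→a (w=3).  This is the unique
    edge set consistent with the published neighbor-degree/weight sums
    (EXD/EXW table) for all four nodes.
    """
    net = Network(directed=True, weighted=True)
    net.add_edge("a", "b", 1)
    net.add_edge("a", "d", 4)
    net.add_edge("b", "c", 2)
    net.add_edge("c", "a", 3)
    return net


def describe(net: Network) -> dict:
    """Summary statistics: n, e, average/max degree, clustering, assortativity.

    Clustering and assortativity follow their standard (undirected-view)
    definitions; both are ``nan`` where undefined (e.g. empty graph).
    """
    import networkx as nx

    n = net.n_nodes
    e = net.n_edges
    if n == 0:
        return {
            "n": 0,
            "e": 0,
            "average_degree": 0.0,
            "max_degree": 0,
            "clustering": math.nan,
            "assortativity": math.nan,
        }
    degs = {v: len(neighbors(net, v)) for v in net.nodes}
    g = net.to_networkx().to_undirected()
    try:
        assort = nx.degree_assortativity_coefficient(g) if e > 1 else math.nan
    except (ValueError, ZeroDivisionError):
        assort = math.nan
    return {
        "n": n,
        "e": e,
        "average_degree": 2 * e / n if not net.directed else sum(degs.values()) / n,
        "max_degree": max(degs.values()),
        "clustering": nx.average_clustering(g) if e else math.nan,
        "assortativity": assort,
    }
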