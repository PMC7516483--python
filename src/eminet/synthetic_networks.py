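"""Network generators for property tests and scaled experiments.

Three tiers:

* analytic families (star, path, cycle, complete) whose centrality values
  have closed forms;
* Erdős–Rényi-style random graphs, optionally directed and weighted, fully
  reproducible from an explicit seed;
* the two-hub *overlap pair* family — two connected hubs sharing a tunable
  number of common leaf neighbors — the canonical scenario in which plain
  degree-style scores overvalue both hubs and the mutual-power penalty
  should bite, monotonically in the overlap.

All generators take explicit seeds; none touch global RNG state.  Weights
default to integers (count-style weights, e.g. flights on a route); a
continuous option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import Network

__all__ = [
    "GeneratorSpec",
    "analytic_family",
    "random_network",
    "overlap_pair_network",
]

_FAMILIES = ("star", "path", "cycle", "complete")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a random network draw.

    weight_range: inclusive integer bounds for uniform integer weights, or
    None for a constant weight of 1 (unweighted).
    """

    n: int
    p: float
    directed: bool = False
    weight_range: tuple[int, int] | None = None
    continuous_weights: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.weight_range is not None:
            lo, hi = self.weight_range
            if lo <= 0 or hi < lo:
                raise ValueError("weight range must be positive and ordered")


def _node(i: int) -> str:
    return f"n{i}"


def analytic_family(kind: str, n: int) -> Network:
    """One of the closed-form families, unweighted and undirected.

    star(n): node n0 is the center with n−1 leaves; path(n): n0–…–n(n−1);
    cycle(n): a ring (n ≥ 3); complete(n): all pairs connected.
    """
    if kind not in _FAMILIES:
        raise ValueError(f"unknown family {kind!r}; one of {_FAMILIES}")
    if n < 2 or (kind == "cycle" and n < 3):
        raise ValueError(f"{kind} needs n >= {3 if kind == 'cycle' else 2}")
    net = Network(directed=False, weighted=False)
    if kind == "star":
        for i in range(1, n):
            net.add_edge(_node(0), _node(i))
    elif kind == "path":
        for i in range(n - 1):
            net.add_edge(_node(i), _node(i + 1))
    elif kind == "cycle":
        for i in range(n):
            net.add_edge(_node(i), _node((i + 1) % n))
    else:  # complete
        for i in range(n):
            for j in range(i + 1, n):
                net.add_edge(_node(i), _node(j))
    return net


def random_network(spec: GeneratorSpec) -> Network:
    """Erdős–Rényi G(n, p) edge sampling, optionally directed/weighted."""
    rng = np.random.default_rng(spec.seed)
    weighted = spec.weight_range is not None
    net = Network(directed=spec.directed, weighted=weighted)
    for i in range(spec.n):
        net.add_node(_node(i))
    pairs = (
        [(i, j) for i in range(spec.n) for j in range(spec.n) if i != j]
        if spec.directed
        else [(i, j) for i in range(spec.n) for j in range(i + 1, spec.n)]
    )
    for i, j in pairs:
        if rng.random() < spec.p:
            if weighted:
                lo, hi = spec.weight_range
                w = (
                    float(rng.uniform(lo, hi))
                    if spec.continuous_weights
                    else float(rng.integers(lo, hi + 1))
                )
            else:
                w = 1.0
            net.add_edge(_node(i), _node(j), w)
    return net


def overlap_pair_network(
    shared: int, private_a: int, private_b: int
) -> Network:
    """Two connected hubs ``hub_a``–``hub_b`` with ``shared`` common leaf
    neighbors and the given private leaf counts (undirected, unweighted).

    Holding each hub's degree fixed while raising ``shared`` increases the
    redundancy between the hubs' neighborhoods; the mutual-power penalty of
    each hub grows (more negative) strictly with ``shared``.
    """
    if shared < 0 or private_a < 0 or private_b < 0:
        raise ValueError("leaf counts must be non-negative")
    net = Network(directed=False, weighted=False)
    net.add_edge("hub_a", "hub_b")
    for i in range(shared):
        net.add_edge("hub_a", f"s{i}")
        net.add_edge("hub_b", f"s{i}")
    for i in range(private_a):
        net.add_edge("hub_a", f"pa{i}")
    for i in range(private_b):
        net.add_edge("hub_b", f"pb{i}")
    return net
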