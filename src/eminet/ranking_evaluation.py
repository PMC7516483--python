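"""Discriminability metrics over ranking lists.

A ranking partitions the node set into ordered tie groups.  Two summary
views quantify how finely a centrality separates nodes:

* monotonicity ``M(R) = (1 − Σ_r n_r(n_r−1) / (n(n−1)))²`` with ``n`` the
  number of nodes and ``n_r`` the size of tie group ``r`` — 1 when every
  node gets a unique rank, 0 when all nodes are tied;
* the complementary cumulative distribution of rank occupancy,
  ``CCDF(r) = (|V| − Σ_{i≤r} n_i) / |V|`` — flat tails mean finely
  resolved rankings.

Tie detection is rounding-based: scores are rounded to
``−log10(tolerance)`` decimals and equal rounded values share a group.
This is deterministic and order-independent, unlike pairwise tolerance
chaining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .baseline_centralities import CentralityVector
from .entropy_centrality import EmiScore

__all__ = [
    "RankingList",
    "make_ranking",
    "monotonicity",
    "ccdf",
    "top_k_overlap",
    "UndefinedMetricError",
]

DEFAULT_TIE_TOL = 1e-10


class UndefinedMetricError(ValueError):
    """Metric requested on an input where it is undefined."""


@dataclass(frozen=True)
class RankingList:
    """Ordered tie groups (descending score); groups partition the node set."""

    groups: tuple[frozenset[str], ...]

    @property
    def n_nodes(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def group_sizes(self) -> list[int]:
        return [len(g) for g in self.groups]

    def top_k(self, k: int) -> list[str]:
        """Flatten tie groups (identifier-ascending within a group) and
        return the first ``k`` nodes."""
        if k > self.n_nodes:
            raise ValueError(f"k={k} exceeds node count {self.n_nodes}")
        flat: list[str] = []
        for g in self.groups:
            flat.extend(sorted(g))
            if len(flat) >= k:
                break
        return flat[:k]


def _as_score_map(scores) -> dict[str, float]:
    if isinstance(scores, CentralityVector):
        return dict(scores.scores)
    if isinstance(scores, dict):
        return dict(scores)
    # list of EmiScore records
    return {r.node: r.K for r in scores}


def make_ranking(scores, tol: float = DEFAULT_TIE_TOL) -> RankingList:
    """Group scores into an ordered :class:`RankingList`.

    ``scores`` may be a :class:`CentralityVector`, a plain ``{node: score}``
    dict, or a list of :class:`EmiScore` records (ranked by K).

    Raises on non-finite scores (naming the node) and on empty input.
    """
    if tol < 0:
        raise ValueError("tie tolerance must be >= 0")
    m = _as_score_map(scores)
    if not m:
        raise ValueError("cannot rank an empty score set")
    for node, s in m.items():
        if not math.isfinite(s):
            raise ValueError(f"non-finite score for node {node!r}")
    decimals = max(0, round(-math.log10(tol))) if tol > 0 else None
    keyed: dict[float, set[str]] = {}
    for node, s in m.items():
        key = round(s, decimals) if decimals is not None else s
        keyed.setdefault(key, set()).add(node)
    groups = tuple(
        frozenset(keyed[key]) for key in sorted(keyed, reverse=True)
    )
    return RankingList(groups=groups)


def monotonicity(r: RankingList) -> float:
    """Monotonicity M(R) ∈ [0, 1] of a ranking; needs ≥ 2 nodes."""
    n = r.n_nodes
    if n < 2:
        raise UndefinedMetricError("monotonicity needs at least 2 nodes")
    tied = sum(nr * (nr - 1) for nr in r.group_sizes)
    return (1.0 - tied / (n * (n - 1))) ** 2


def ccdf(r: RankingList) -> list[tuple[int, float]]:
    """Rank-occupancy CCDF: (rank index, fraction of nodes strictly below
    that rank).  Non-increasing; the final value is 0."""
    n = r.n_nodes
    if n == 0:
        raise ValueError("empty ranking")
    out = []
    cum = 0
    for i, size in enumerate(r.group_sizes, start=1):
        cum += size
        out.append((i, (n - cum) / n))
    return out


def top_k_overlap(
    a: RankingList, b: RankingList, k: int
) -> tuple[int, set[str]]:
    """Size and identity of the intersection of two rankings' top-k sets."""
    sa = set(a.top_k(k))
    sb = set(b.top_k(k))
    common = sa & sb
    return len(common), common
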