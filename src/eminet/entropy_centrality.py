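"""The EMI node-importance score: entropy of neighbor degrees/strengths plus
a mutual-information redundancy penalty.

A node is influential when its neighbors' connectivity is both large and
evenly spread; Shannon entropy of the neighbor degree (and, for weighted
networks, strength) multiset captures exactly that.  But adjacent nodes that
share many neighbors largely duplicate each other's reach, so a non-positive
*mutual power* term, built from the shared-neighbor overlap, discounts that
redundancy.  The overall importance of node ``i`` is

    K_i = S_i + I_i + MI_i      (weighted networks)
    K_i = S_i + MI_i            (unweighted networks)

where

* ``S_i`` — *structural entropy*: for a directed network the sum of the
  entropy of the in-degrees of i's neighbors and the entropy of their
  out-degrees; for an undirected network a single entropy over the neighbor
  degrees.
* ``I_i`` — *interactive entropy*: the same construction over the neighbors'
  inbound/outbound weight sums (strengths); only defined for weighted
  networks.
* ``MI_i`` — *mutual power*: for each neighbor ``j``, with ``N_i``, ``N_j``
  the neighbor sets, ``N_ij`` their intersection and ``F`` the size
  function,

      MI_i = Σ_j  F(N_ij)/(F(N_i)+F(N_j))
              · log[ (F(N_i)+F(N_j)−F(N_ij)) / (F(N_i)+F(N_j)) ]

  Each term is ≤ 0 and vanishes when i and j share no neighbors, so
  MI_i ≤ 0 with equality iff i shares no neighbor with any of its
  neighbors.

All logarithms default to base 10.  Zero entries in an entropy multiset
contribute nothing (the 0·log 0 := 0 convention); that convention is
load-bearing — a neighbor with out-degree 0 must contribute a zero term,
not poison the sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .graph_core import Network, degree_record, neighbors

log = logging.getLogger(__name__)

__all__ = [
    "EmiConfig",
    "EmiScore",
    "multiset_entropy",
    "structural_entropy",
    "interactive_entropy",
    "mutual_power",
    "emi_score",
    "write_ranking_tsv",
    "UndefinedEntropyError",
    "NotApplicableError",
]


class UndefinedEntropyError(ValueError):
    """Entropy requested for an all-zero multiset."""


class NotApplicableError(ValueError):
    """Interactive entropy requested on an unweighted network."""


@dataclass(frozen=True)
class EmiConfig:
    """Tunable knobs of the EMI computation.

    Parameters
    ----------
    log_base:
        Base of every logarithm (> 1).  Default 10.
    compat_single_neighbor:
        When a node has exactly one neighbor, strict evaluation of the
        entropy formulas gives 0 (a one-element multiset carries no
        uncertainty).  With this flag the node's *own* degrees/weight sums
        join the multiset alongside its single neighbor's, which reproduces
        the published worked-example row for the degree-one node.  Off by
        default.
    weight_shift:
        Shift non-positive edge weights at load time (handled by the IO
        layer; recorded here so a config fully describes a run).
    mi_pair_multiplicity:
        Expert option: weight each neighbor-pair term of the mutual power
        by the common-neighbor count F(N_ij) (a "repeated events" reading
        of the double sum).  The two readings coincide whenever
        F(N_ij) ≤ 1, which covers the worked example; default off, keeping
        the per-pair joint mass a probability.
    """

    log_base: float = 10.0
    compat_single_neighbor: bool = False
    weight_shift: bool = True
    mi_pair_multiplicity: bool = False

    def __post_init__(self):
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")


@dataclass(frozen=True)
class EmiScore:
    """Per-node EMI components.  ``S_in``/``S_out`` (and ``I_in``/``I_out``)
    are ``None`` for undirected networks, where a single entropy is used;
    ``I`` components are ``None`` for unweighted networks."""

    node: str
    S_in: float | None
    S_out: float | None
    S: float
    I_in: float | None
    I_out: float | None
    I: float | None
    MI: float
    K: float


def multiset_entropy(values: Iterable[float], base: float = 10.0) -> float:
    """Shannon entropy of the distribution induced by a non-negative multiset.

    Each value ``v_i`` receives probability ``p_i = v_i / Σ v_k``;
    ``H = −Σ p_i log_base p_i`` with zero values contributing 0.

    Raises
    ------
    UndefinedEntropyError
        If every value is zero (no distribution can be formed).
    ValueError
        If any value is negative.
    """
    vals = [float(v) for v in values]
    if any(v < 0 for v in vals):
        raise ValueError("entropy multiset must be non-negative")
    total = sum(vals)
    if total == 0:
        raise UndefinedEntropyError("all-zero multiset has no entropy")
    h = 0.0
    for v in vals:
        if v > 0:
            p = v / total
            if p > 0.0:  # guard subnormal underflow of v/total
                h -= p * math.log(p, base)
    return h


def _entropy_or_zero(values: Sequence[float], base: float) -> float:
    """Entropy of a multiset, 0 when the multiset is empty or all-zero."""
    if not values or all(v == 0 for v in values):
        return 0.0
    return multiset_entropy(values, base)


def _neighbor_multisets(net: Network, v: str, cfg: EmiConfig):
    """Degree and weight multisets over v's neighbors, with the
    single-neighbor compat augmentation when enabled."""
    nb = sorted(neighbors(net, v))
    recs = [degree_record(net, u) for u in nb]
    if cfg.compat_single_neighbor and len(nb) == 1:
        recs.append(degree_record(net, v))
    return nb, recs


def structural_entropy(
    net: Network, v: str, cfg: EmiConfig | None = None
) -> tuple[float | None, float | None, float]:
    """Structural entropy ``(S_in, S_out, S)`` of node ``v``.

    Directed: ``S_in`` is the entropy of the in-degrees of v's neighbors,
    ``S_out`` the entropy of their out-degrees, ``S = S_in + S_out``.
    Undirected: a single entropy over the neighbor degrees is returned as
    ``S`` with ``S_in = S_out = None``.

    An isolated node scores 0 (with a warning) so whole-network ranking
    never aborts.
    """
    cfg = cfg or EmiConfig()
    nb, recs = _neighbor_multisets(net, v, cfg)
    if not nb:
        log.warning("node %r is isolated; structural entropy set to 0", v)
        return (0.0, 0.0, 0.0) if net.directed else (None, None, 0.0)
    if net.directed:
        s_in = _entropy_or_zero([r.d_in for r in recs], cfg.log_base)
        s_out = _entropy_or_zero([r.d_out for r in recs], cfg.log_base)
        return s_in, s_out, s_in + s_out
    s = _entropy_or_zero([r.d_in for r in recs], cfg.log_base)
    return None, None, s


def interactive_entropy(
    net: Network, v: str, cfg: EmiConfig | None = None
) -> tuple[float | None, float | None, float]:
    """Interactive entropy ``(I_in, I_out, I)`` of node ``v`` — the
    structural construction applied to neighbors' inbound/outbound weight
    sums (strengths) instead of degree counts.

    Raises
    ------
    NotApplicableError
        On unweighted networks (the score's weighted branch only).
    """
    cfg = cfg or EmiConfig()
    if not net.weighted:
        raise NotApplicableError(
            "interactive entropy is defined for weighted networks only"
        )
    nb, recs = _neighbor_multisets(net, v, cfg)
    if not nb:
        log.warning("node %r is isolated; interactive entropy set to 0", v)
        return (0.0, 0.0, 0.0) if net.directed else (None, None, 0.0)
    if net.directed:
        i_in = _entropy_or_zero([r.w_in for r in recs], cfg.log_base)
        i_out = _entropy_or_zero([r.w_out for r in recs], cfg.log_base)
        return i_in, i_out, i_in + i_out
    i = _entropy_or_zero([r.w_in for r in recs], cfg.log_base)
    return None, None, i


def mutual_power(net: Network, v: str, cfg: EmiConfig | None = None) -> float:
    """Mutual power ``MI_v ≤ 0``: the shared-neighbor redundancy penalty.

    Sums, over every neighbor ``j`` of ``v``, the term

        F(N_vj)/(F(N_v)+F(N_j)) · log[(F(N_v)+F(N_j)−F(N_vj))/(F(N_v)+F(N_j))]

    where ``N_vj`` is the common-neighbor set.  Pairs with no common
    neighbor contribute 0; an isolated node scores 0.
    """
    cfg = cfg or EmiConfig()
    n_v = neighbors(net, v)
    if not n_v:
        return 0.0
    mi = 0.0
    for j in sorted(n_v):
        n_j = neighbors(net, j)
        common = len(n_v & n_j)
        if common == 0:
            continue
        joint = len(n_v) + len(n_j)
        term = (common / joint) * math.log((joint - common) / joint, cfg.log_base)
        if cfg.mi_pair_multiplicity:
            term *= common
        mi += term
    return mi


def emi_score(net: Network, cfg: EmiConfig | None = None) -> list[EmiScore]:
    """Score and rank every node of a network by overall importance K.

    K = S + I + MI on weighted networks, K = S + MI on unweighted ones
    (where for directed-unweighted networks S is still the in+out split).
    Output is sorted by K descending, ties broken by node identifier
    ascending, for deterministic files.
    """
    cfg = cfg or EmiConfig()
    scores = []
    for v in sorted(net.nodes):
        s_in, s_out, s = structural_entropy(net, v, cfg)
        if net.weighted:
            i_in, i_out, i = interactive_entropy(net, v, cfg)
        else:
            i_in = i_out = i = None
        mi = mutual_power(net, v, cfg)
        k = s + (i or 0.0) + mi
        scores.append(
            EmiScore(
                node=v,
                S_in=s_in,
                S_out=s_out,
                S=s,
                I_in=i_in,
                I_out=i_out,
                I=i,
                MI=mi,
                K=k,
            )
        )
    scores.sort(key=lambda r: (-r.K, r.node))
    return scores


def write_ranking_tsv(scores: list[EmiScore], path_or_file) -> None:
    """Write the fixed-schema ranking TSV:
    node, S_in, S_out, S, I_in, I_out, I, MI, K, rank (6-decimal floats).

    Accepts a path or an open text file object."""

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.6f}"

    if hasattr(path_or_file, "write"):
        _write_ranking(scores, path_or_file, fmt)
    else:
        with open(path_or_file, "w") as fh:
            _write_ranking(scores, fh, fmt)


def _write_ranking(scores, fh, fmt) -> None:
    fh.write("node\tS_in\tS_out\tS\tI_in\tI_out\tI\tMI\tK\trank\n")
    for rank, r in enumerate(scores, start=1):
        cols = [r.node, fmt(r.S_in), fmt(r.S_out), fmt(r.S), fmt(r.I_in),
                fmt(r.I_out), fmt(r.I), fmt(r.MI), fmt(r.K), str(rank)]
        fh.write("\t".join(cols) + "\n")
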