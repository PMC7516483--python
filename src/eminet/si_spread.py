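"""Monte-Carlo susceptible-infected (SI) spreading.

The SI process scores a seed set by how far infection starting from it
reaches.  There is no recovery: once infected, always infected, so the
infected set grows monotonically and the final count measures spreading
influence.

Dynamics are synchronous discrete-time: at each step, every infected node
attempts each currently susceptible out-neighbor once.  On unweighted
networks each attempt succeeds with probability β.  On weighted networks
the per-edge probability follows the edge weight:

    λ_ij = (w_ij / w_max) ** α

for susceptible ``i`` infected through neighbor ``j`` (``w_max`` the global
maximum weight, ``α > 0`` a shape constant, default 1).  Infection travels
along out-edges of infected nodes; undirected edges carry it both ways.

Runs terminate at the step cap or as soon as no susceptible node is
adjacent to an infected one, whichever comes first.  Each Monte-Carlo run
draws from an independent RNG substream derived from the configured seed,
so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_core import Network
from .ranking_evaluation import RankingList

__all__ = ["SIConfig", "SpreadResult", "infection_probability", "si_run",
           "seed_set_experiment"]


@dataclass(frozen=True)
class SIConfig:
    """SI simulation parameters.

    beta:  infection probability per contact on unweighted networks, in [0,1].
    alpha: positive exponent of the weighted infection probability (default 1).
    steps: maximum number of synchronous timesteps.
    runs:  Monte-Carlo repetitions (default 100).
    seed:  RNG seed; every run uses an independent substream spawned from it.
    """

    beta: float = 0.1
    alpha: float = 1.0
    steps: int = 50
    runs: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass(frozen=True)
class SpreadResult:
    """Outcome of Monte-Carlo SI runs for one seed set."""

    seeds: frozenset[str]
    mean_infected: float
    final_counts: tuple[int, ...]
    trajectory: tuple[float, ...]  # per-step mean infected count

    @property
    def std_error(self) -> float:
        c = np.asarray(self.final_counts, dtype=float)
        return float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0


def infection_probability(net: Network, i: str, j: str, cfg: SIConfig) -> float:
    """Probability that susceptible ``i`` is infected through infected
    neighbor ``j`` in one contact.  Requires the edge j→i (directed) or
    j–i (undirected) to exist."""
    w = net.edge_weight(j, i)
    if w is None:
        raise ValueError(f"no edge from {j!r} to {i!r}")
    if not net.weighted:
        return cfg.beta
    return (w / net.max_weight()) ** cfg.alpha


def _transmission_lists(net: Network, cfg: SIConfig):
    """Per-node list of (target, probability) contacts infection can use."""
    contacts: dict[str, list[tuple[str, float]]] = {v: [] for v in net.nodes}
    w_max = net.max_weight() if (net.weighted and net.edges) else 1.0
    for (u, v), w in net.edges.items():
        p = (w / w_max) ** cfg.alpha if net.weighted else cfg.beta
        contacts[u].append((v, p))
        if not net.directed:
            contacts[v].append((u, p))
    return contacts


def _single_run(
    contacts: dict[str, list[tuple[str, float]]],
    seeds: frozenset[str],
    steps: int,
    rng: np.random.Generator,
) -> list[int]:
    infected = set(seeds)
    frontier = set(seeds)  # nodes that may still have susceptible contacts
    counts = []
    for _ in range(steps):
        newly: set[str] = set()
        exhausted: set[str] = set()
        for u in sorted(frontier):
            live = [(v, p) for v, p in contacts[u] if v not in infected]
            if not live:
                exhausted.add(u)
                continue
            for v, p in live:
                if v in newly:
                    continue
                if rng.random() < p:
                    newly.add(v)
        infected |= newly
        frontier |= newly
        frontier -= exhausted
        counts.append(len(infected))
        if not newly and all(
            all(v in infected for v, _ in contacts[u]) for u in frontier
        ):
            break
    return counts or [len(infected)]


def si_run(net: Network, seeds, cfg: SIConfig) -> SpreadResult:
    """Run the SI process ``cfg.runs`` times from a seed set and average.

    Returns mean final infected count, per-run finals and a per-step mean
    trajectory (runs that terminate early hold their final value).
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    missing = seeds - net.nodes
    if missing:
        raise ValueError(f"seed nodes not in network: {sorted(missing)[:5]}")
    contacts = _transmission_lists(net, cfg)
    ss = np.random.SeedSequence(cfg.seed)
    streams = ss.spawn(cfg.runs)
    finals = []
    trajs = []
    for child in streams:
        rng = np.random.default_rng(child)
        counts = _single_run(contacts, seeds, cfg.steps, rng)
        # pad early-terminated runs with their final plateau value
        counts = counts + [counts[-1]] * (cfg.steps - len(counts))
        finals.append(counts[-1])
        trajs.append(counts)
    traj_mean = tuple(float(x) for x in np.asarray(trajs, dtype=float).mean(axis=0))
    return SpreadResult(
        seeds=seeds,
        mean_infected=float(np.mean(finals)),
        final_counts=tuple(finals),
        trajectory=traj_mean,
    )


def seed_set_experiment(
    net: Network,
    rankings: dict[str, RankingList],
    ks: list[int],
    cfg: SIConfig,
) -> list[dict]:
    """Compare ranking methods by the spread their top-k seed sets achieve.

    For every method × k, runs :func:`si_run` seeded from that method's
    top-k nodes.  All methods share the same RNG substream per (k, run)
    pair, so comparisons are variance-paired.

    Returns a list of row dicts: method, k, mean_infected, std_error, runs.
    """
    if ks and max(ks) > net.n_nodes:
        raise ValueError(f"k={max(ks)} exceeds network size {net.n_nodes}")
    rows = []
    for ki, k in enumerate(ks):
        # same seed for every method at this k -> paired Monte-Carlo streams
        k_cfg = SIConfig(
            beta=cfg.beta,
            alpha=cfg.alpha,
            steps=cfg.steps,
            runs=cfg.runs,
            seed=cfg.seed + ki,
        )
        for method, ranking in rankings.items():
            res = si_run(net, ranking.top_k(k), k_cfg)
            rows.append(
                {
                    "method": method,
                    "k": k,
                    "mean_infected": res.mean_infected,
                    "std_error": res.std_error,
                    "runs": cfg.runs,
                }
            )
    return rows
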