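"""Comparator ranking schemes: hypergeometric test, raw occurrence, and the
two random controls (random ranks, degree-preserving rewiring).

The hypergeometric test asks, for a pair observed N_ij times, how likely
that many co-occurrences are when protein i's N_i endpoint slots are drawn
at random from the 2N slots of the whole record list, N_j of which belong
to protein j:

    p_ij = sum_{n=N_ij}^{min(N_i, N_j)}
           C(N_j, n) C(2N - N_j, N_i - n) / C(2N, N_i)

This background admits self-pairs, which is the conceptual difference from
the shuffle null model: for frequently studied proteins the hypergeometric
background "wastes" probability mass on impossible self-pairs and therefore
overstates the significance of their observed partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import networkx as nx
import numpy as np

from ._hyper import hypergeom_tail
from .core import fractional_rank
from .records import AggregatedNetwork, Pair, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ComparatorScore",
    "hypergeometric_pvalue",
    "hypergeometric_rank",
    "occurrence_rank",
    "random_rank",
    "rewire",
]

Method = Literal["hypergeometric", "occurrence", "random_rank", "rewired"]


@dataclass(frozen=True)
class ComparatorScore:
    pair: Pair
    method: str
    score: float
    rank: float


def hypergeometric_pvalue(n_ij: int, n_i: int, n_j: int, n_total: int) -> float:
    """Upper-tail probability of observing >= n_ij co-occurrences of two
    proteins with endpoint counts n_i and n_j among n_total records."""
    if not 1 <= n_ij <= min(n_i, n_j):
        raise ValueError(f"n_ij={n_ij} outside [1, min(n_i, n_j)]")
    if max(n_i, n_j) > n_total:
        raise ValueError("per-protein count exceeds the total record count")
    return hypergeom_tail(n_ij, n_success=n_j, n_draws=n_i, n_pop=2 * n_total)


def _sorted_scores(
    network: AggregatedNetwork, scores: np.ndarray, ranks: np.ndarray, method: str
) -> list[ComparatorScore]:
    pairs = network.pairs
    order = sorted(range(len(pairs)), key=lambda i: (ranks[i], pairs[i]))
    return [
        ComparatorScore(pairs[i], method, float(scores[i]), float(ranks[i]))
        for i in order
    ]


def hypergeometric_rank(network: AggregatedNetwork) -> list[ComparatorScore]:
    """Rank all pairs by the hypergeometric upper-tail probability
    (smaller is better)."""
    n = network.total_records
    occ = network.protein_occurrence
    pairs = network.pairs
    p = np.array(
        [
            hypergeometric_pvalue(network.pair_occurrence[(a, b)], occ[a], occ[b], n)
            for a, b in pairs
        ]
    )
    ranks = fractional_rank(p, better="smaller")
    return _sorted_scores(network, p, ranks, "hypergeometric")


def occurrence_rank(network: AggregatedNetwork) -> list[ComparatorScore]:
    """Rank pairs by raw occurrence O_ij (larger is better).

    Occurrence is integer-valued, so large tie groups are the norm: in
    literature-aggregated data most pairs are singletons sharing one rank.
    """
    pairs = network.pairs
    o = np.array([network.pair_occurrence[p] for p in pairs], dtype=float)
    ranks = fractional_rank(o, better="larger")
    return _sorted_scores(network, o, ranks, "occurrence")


def random_rank(pairs: Iterable[Pair], seed: int) -> list[ComparatorScore]:
    """Assign ranks 1..n uniformly at random (the no-information control)."""
    pair_list = sorted(canonical_pair(*p) for p in set(pairs))
    rng = np.random.default_rng(seed)
    ranks = rng.permutation(len(pair_list)) + 1
    order = sorted(range(len(pair_list)), key=lambda i: ranks[i])
    return [
        ComparatorScore(pair_list[i], "random_rank", float(ranks[i]), float(ranks[i]))
        for i in order
    ]


def rewire(pairs: Iterable[Pair], n_swaps: int, seed: int) -> set[Pair]:
    """Degree-preserving randomization of the unique-pair graph by double
    edge swaps; self-pairs and duplicate pairs are never introduced.

    Swap-chain controls randomize *which* pairs exist while keeping each
    protein's partner count; occurrence multiplicities are not modeled.
    """
    graph = nx.Graph()
    graph.add_edges_from(canonical_pair(*p) for p in set(pairs))
    if graph.number_of_edges() < 2:
        return {canonical_pair(*e) for e in graph.edges()}
    try:
        nx.double_edge_swap(
            graph, nswap=n_swaps, max_tries=max(100 * n_swaps, 1000), seed=seed
        )
    except nx.NetworkXAlgorithmError:
        # swap chain exhausted (e.g., near-complete graphs); keep current state
        logger.warning("rewire: swap chain exhausted before %d swaps", n_swaps)
    return {canonical_pair(*e) for e in graph.edges()}
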