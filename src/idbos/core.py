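"""IDBOS scoring: occurrence-preserving randomization, Z-scores, empirical
p-values, fractional ranking and average-rank combination.

The null model holds each protein's total report count N_i fixed and
forbids self-pairs; M randomized realizations of the record list yield, for
every observed pair (i, j), the ensemble mean <R_ij> and standard deviation
sigma_R of its random occurrence, giving

    Z_ij = (O_ij - <R_ij>) / sigma_R

and the empirical tail estimate

    p_ij ~ (1/M) * #{realizations with R_ij >= O_ij}.

Both metrics are converted to fractional ranks (Z: larger is better, p:
smaller is better) and averaged; the average rank is the IDBOS confidence
ordering.  Pairs sharing an average rank form an equivalence group and are
meant to be analyzed together.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from . import _engine
from .records import AggregatedNetwork, Pair, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "InfeasibleNetworkError",
    "RandomizationSummary",
    "ScoredPair",
    "shuffle_once",
    "randomize",
    "z_score",
    "p_value",
    "empirical_pdfs",
    "matching_pdf_oracle",
    "oracle_mean",
    "oracle_tail",
    "fractional_rank",
    "idbos_score",
]

#: mixing sweeps per realization (Metropolis double-swap moves = sweeps * N)
DEFAULT_SWEEPS = 10

_ORACLE_MAX_STUBS = 14


class InfeasibleNetworkError(ValueError):
    """No self-pair-free matching exists (some N_i exceeds N)."""


class OracleSizeError(ValueError):
    """Network too large for exhaustive matching enumeration."""


# ---------------------------------------------------------------------------
# index mapping between the string-keyed network and integer stub arrays
# ---------------------------------------------------------------------------


@dataclass
class _Indexed:
    proteins: list[str]
    index: dict[str, int]
    stubs: np.ndarray  # 2N protein indices
    pairs: list[Pair]  # observed pairs, lexicographic
    keys: np.ndarray  # ia * n_prot + ib per observed pair, ascending
    occ: np.ndarray  # O_ij aligned with pairs


def _index_network(network: AggregatedNetwork) -> _Indexed:
    if network.n_pairs == 0:
        raise ValueError("empty network")
    proteins = network.proteins
    index = {p: i for i, p in enumerate(proteins)}
    n_records = network.total_records
    worst = max(network.protein_occurrence.items(), key=lambda kv: kv[1])
    if worst[1] > n_records:
        raise InfeasibleNetworkError(
            f"protein {worst[0]!r} occupies {worst[1]} of {2 * n_records} "
            "endpoint slots; a self-pair-free pairing is impossible"
        )
    stubs = np.empty(2 * n_records, dtype=np.int64)
    pos = 0
    for p in proteins:
        k = network.protein_occurrence[p]
        stubs[pos : pos + k] = index[p]
        pos += k
    pairs = network.pairs
    n_prot = len(proteins)
    keys = np.array([index[a] * n_prot + index[b] for a, b in pairs], dtype=np.int64)
    occ = np.array([network.pair_occurrence[p] for p in pairs], dtype=np.int64)
    return _Indexed(proteins, index, stubs, pairs, keys, occ)


def _as_seed(seed: int | np.random.Generator) -> int:
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(0, 2**31 - 1))
    return int(seed) % (2**31 - 1)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def shuffle_once(
    network: AggregatedNetwork,
    rng: int | np.random.Generator,
    sweeps: int = DEFAULT_SWEEPS,
) -> Counter[Pair]:
    """One randomized realization as a multiset of unordered pairs.

    The output has exactly N pairs, preserves every protein's endpoint
    count N_i, and contains no self-pairs; duplicate pairs carry their
    multiplicity.
    """
    ix = _index_network(network)
    x, y = _engine.single_matching(ix.stubs, sweeps, _as_seed(rng))
    out: Counter[Pair] = Counter()
    for a, b in zip(x, y):
        pa, pb = ix.proteins[int(a)], ix.proteins[int(b)]
        out[(pa, pb) if pa < pb else (pb, pa)] += 1
    return out


@dataclass
class RandomizationSummary:
    """Per-pair ensemble statistics over M shuffled realizations."""

    pairs: list[Pair]
    occurrence: np.ndarray  # O_ij
    mean_r: np.ndarray  # <R_ij>
    sd_r: np.ndarray  # sigma_R, sample (n-1) normalization
    exceed_count: np.ndarray  # #{n : R_ij(n) >= O_ij}
    m: int
    seed: int

    def __post_init__(self) -> None:
        self._pos = {p: i for i, p in enumerate(self.pairs)}

    def for_pair(self, pair: Pair) -> tuple[float, float, int]:
        """(mean_R, sd_R, exceed_count) for one observed pair."""
        i = self._pos[canonical_pair(*pair)]
        return float(self.mean_r[i]), float(self.sd_r[i]), int(self.exceed_count[i])


def randomize(
    network: AggregatedNetwork,
    m: int,
    seed: int,
    sweeps: int = DEFAULT_SWEEPS,
) -> RandomizationSummary:
    """Stream M randomized realizations and summarize each observed pair.

    Mean and standard deviation use a numerically stable one-pass update,
    so M = 1e6 realizations never need to be stored.  Deterministic given
    (network, m, seed).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    ix = _index_network(network)
    mean, m2, exceed = _engine.ensemble_stats(
        ix.stubs, ix.keys, ix.occ, len(ix.proteins), m, sweeps, _as_seed(seed)
    )
    sd = np.sqrt(m2 / (m - 1)) if m > 1 else np.zeros_like(mean)
    return RandomizationSummary(ix.pairs, ix.occ, mean, sd, exceed, m, int(seed))


def empirical_pdfs(
    network: AggregatedNetwork,
    m: int,
    seed: int,
    sweeps: int = DEFAULT_SWEEPS,
) -> dict[Pair, np.ndarray]:
    """Per observed pair, the empirical PDF of its random occurrence R_ij
    over M realizations (index r holds P(R_ij = r))."""
    if m < 1:
        raise ValueError("m must be >= 1")
    ix = _index_network(network)
    max_r = network.total_records
    hist = _engine.ensemble_hist(
        ix.stubs, ix.keys, len(ix.proteins), m, sweeps, _as_seed(seed), max_r
    )
    return {pair: hist[i] / m for i, pair in enumerate(ix.pairs)}


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle (tiny networks)
# ---------------------------------------------------------------------------


def _enumerate_valid(stubs: list[int]):
    """Yield every self-pair-free perfect matching of the labeled stubs,
    each exactly once, as a list of canonical (lo, hi) index pairs."""
    if not stubs:
        yield []
        return
    first = stubs[0]
    rest = stubs[1:]
    for k, partner in enumerate(rest):
        if partner == first:
            continue
        sub = rest[:k] + rest[k + 1 :]
        lo, hi = (first, partner) if first <= partner else (partner, first)
        for tail in _enumerate_valid(sub):
            yield [(lo, hi)] + tail


def _oracle_pdfs(network: AggregatedNetwork) -> dict[Pair, dict[int, float]]:
    ix = _index_network(network)
    if ix.stubs.shape[0] > _ORACLE_MAX_STUBS:
        raise OracleSizeError(
            f"{ix.stubs.shape[0]} stubs exceed the enumeration limit of "
            f"{_ORACLE_MAX_STUBS}"
        )
    stubs = [int(s) for s in ix.stubs]
    observed = {(ix.index[a], ix.index[b]): (a, b) for a, b in ix.pairs}
    tallies: dict[Pair, Counter[int]] = {p: Counter() for p in ix.pairs}
    total = 0
    for matching in _enumerate_valid(stubs):
        total += 1
        counts = Counter(matching)
        for key, pair in observed.items():
            tallies[pair][counts.get(key, 0)] += 1
    if total == 0:
        raise InfeasibleNetworkError("no self-pair-free matching exists")
    return {
        pair: {r: c / total for r, c in sorted(tally.items())}
        for pair, tally in tallies.items()
    }


def matching_pdf_oracle(network: AggregatedNetwork, pair: Pair) -> dict[int, float]:
    """Exact PDF of the random occurrence of ``pair`` under the null model,
    by brute-force enumeration of all self-pair-free stub matchings.

    Only tractable for networks with 2N <= 14 stubs; larger networks raise
    :class:`OracleSizeError`.
    """
    return _oracle_pdfs(network)[canonical_pair(*pair)]


def oracle_mean(network: AggregatedNetwork, pair: Pair) -> float:
    pdf = matching_pdf_oracle(network, pair)
    return sum(r * p for r, p in pdf.items())


def oracle_tail(network: AggregatedNetwork, pair: Pair, threshold: int) -> float:
    """Exact P(R_ij >= threshold) from the enumeration oracle."""
    pdf = matching_pdf_oracle(network, pair)
    return sum(p for r, p in pdf.items() if r >= threshold)


# ---------------------------------------------------------------------------
# scores and ranks
# ---------------------------------------------------------------------------


def z_score(o: float, mean_r: float, sd_r: float) -> float:
    """(O - <R>) / sigma_R.

    Degenerate ensembles (sigma_R = 0) return 0 when O equals the mean and
    a signed infinity otherwise; :func:`idbos_score` replaces the infinities
    by (largest finite |Z| in the run + 1) so such pairs sort beyond every
    finite-Z pair without inventing a magnitude.
    """
    if sd_r < 0:
        raise ValueError("sd_r must be >= 0")
    if sd_r == 0:
        if o == mean_r:
            return 0.0
        return math.inf if o > mean_r else -math.inf
    return (o - mean_r) / sd_r


def p_value(exceed_count: int, m: int, pseudo_count: bool = False) -> float:
    """Empirical tail estimate exceed_count / M.

    With ``pseudo_count`` the (k+1)/(M+1) estimator is used instead, which
    never returns an exact zero at finite M.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= exceed_count <= m:
        raise ValueError("exceed_count outside [0, m]")
    if pseudo_count:
        return (exceed_count + 1) / (m + 1)
    return exceed_count / m


def fractional_rank(
    values: Sequence[float] | np.ndarray,
    better: Literal["larger", "smaller"] = "larger",
) -> np.ndarray:
    """Fractional (mean-of-ordinal) ranks, best value ranked 1.

    Tied values share the mean of the ordinal positions they span, so the
    ranks of n items always sum to n(n+1)/2.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty value list")
    if np.isnan(arr).any():
        raise ValueError("NaN value in ranking input")
    if better == "larger":
        arr = -arr
    elif better != "smaller":
        raise ValueError(f"unknown direction {better!r}")
    return rankdata(arr, method="average")


@dataclass(frozen=True)
class ScoredPair:
    """One pair with its IDBOS scores and ranks."""

    pair: Pair
    occurrence: int
    z: float
    p: float
    z_rank: float
    p_rank: float
    avg_rank: float
    tie_group: int  # pairs sharing an avg_rank share a group id

    @property
    def rank(self) -> float:
        return self.avg_rank


def idbos_score(
    network: AggregatedNetwork,
    m: int,
    seed: int,
    sweeps: int = DEFAULT_SWEEPS,
    pseudo_count: bool = False,
) -> list[ScoredPair]:
    """Score every observed pair and sort by average rank (best first).

    Z-ranks use larger-is-better, p-ranks smaller-is-better; the average of
    the two fractional ranks is the final ordering.  Pairs with identical
    average rank form a tie group (``tie_group``) and are emitted in
    lexicographic pair order within the group.
    """
    summary = randomize(network, m, seed, sweeps)
    o = summary.occurrence.astype(float)
    with np.errstate(invalid="ignore"):
        z = np.where(
            summary.sd_r > 0,
            (o - summary.mean_r) / np.where(summary.sd_r > 0, summary.sd_r, 1.0),
            np.sign(o - summary.mean_r) * np.inf,
        )
    z[np.isnan(z)] = 0.0  # sd_R = 0 with O == <R>
    infinite = ~np.isfinite(z)
    if infinite.any():
        finite_max = float(np.abs(z[~infinite]).max()) if (~infinite).any() else 0.0
        z = np.where(infinite, np.sign(z) * (finite_max + 1.0), z)
        logger.warning(
            "%d pair(s) had sigma_R = 0; Z set beyond the largest finite |Z|",
            int(infinite.sum()),
        )
    p = np.array([p_value(int(e), m, pseudo_count) for e in summary.exceed_count])
    z_ranks = fractional_rank(z, better="larger")
    p_ranks = fractional_rank(p, better="smaller")
    avg = (z_ranks + p_ranks) / 2.0
    order = sorted(range(len(summary.pairs)), key=lambda i: (avg[i], summary.pairs[i]))
    out: list[ScoredPair] = []
    group = -1
    last_avg: float | None = None
    for i in order:
        if last_avg is None or avg[i] != last_avg:
            group += 1
            last_avg = float(avg[i])
        out.append(
            ScoredPair(
                pair=summary.pairs[i],
                occurrence=int(summary.occurrence[i]),
                z=float(z[i]),
                p=float(p[i]),
                z_rank=float(z_ranks[i]),
                p_rank=float(p_ranks[i]),
                avg_rank=float(avg[i]),
                tie_group=group,
            )
        )
    return out
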