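"""Shared log-space hypergeometric upper-tail kernel.

Used both for the interaction-occurrence test (endpoint slots drawn from 2N
stubs) and for the annotation-overlap score (terms drawn from a vocabulary
of T terms).  Direct factorials overflow around N ~ 1e5, so binomials are
evaluated through ``lgamma`` and the tail is accumulated with logsumexp.
"""

from __future__ import annotations

from math import exp, lgamma

from scipy.special import logsumexp

__all__ = ["log_comb", "hypergeom_tail"]


def log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return float("-inf")
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_tail(k: int, n_success: int, n_draws: int, n_pop: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population n_pop, successes
    n_success, draws n_draws).

    Equals sum_{i=k}^{min(n_draws, n_success)}
    C(n_success, i) * C(n_pop - n_success, n_draws - i) / C(n_pop, n_draws).
    """
    if not (0 <= n_success <= n_pop and 0 <= n_draws <= n_pop):
        raise ValueError(
            f"invalid hypergeometric arguments: successes={n_success}, "
            f"draws={n_draws}, population={n_pop}"
        )
    lo = max(0, n_draws + n_success - n_pop)  # support lower bound
    hi = min(n_draws, n_success)
    if k > hi:
        raise ValueError(f"k={k} above the support maximum {hi}")
    if k <= lo:
        return 1.0
    denom = log_comb(n_pop, n_draws)
    terms = [
        log_comb(n_success, i) + log_comb(n_pop - n_success, n_draws - i) - denom
        for i in range(k, hi + 1)
    ]
    return min(1.0, float(exp(logsumexp(terms))))
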