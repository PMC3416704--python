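"""Benchmarking harness for ranked interaction sets.

A reference set supplies a protein universe and a list of "true" pairs.  A
scored pair is *judgeable* when both proteins belong to the universe, and
*true* when it appears among the reference pairs.  Sweeping a rank
threshold over the judgeable sublist yields an accuracy-coverage curve
(coverage = number of true pairs above the threshold, accuracy = fraction
true among judgeable above it); tied ranks enter a threshold together.

Summary statistics:

* average accuracy  <A> = (1/N) sum_r accuracy(r) * n(r), where n(r) counts
  the true pairs whose rank equals r and N is the total true count -- the
  mean accuracy-at-inclusion over true pairs;
* gain = (<A> - <A_R>) / <A_R> * 100, the percent improvement over the
  random-ranking expectation <A_R> (analytically, the overall true
  fraction among judgeable pairs).

Also provided: top-k ranking overlap and enrichment of known domain-domain
interactions (DDIs) among the domain pairs of top-ranked interactions.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import Pair, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceSet",
    "LabeledPair",
    "AccuracyCurve",
    "as_ranked",
    "judgeable",
    "accuracy_coverage_curve",
    "average_accuracy",
    "expected_random_accuracy",
    "sampled_random_accuracy",
    "gain",
    "top_overlap",
    "ddi_enrichment",
    "evaluate_schemes",
]

Ranked = Sequence[tuple[Pair, float]]


@dataclass
class ReferenceSet:
    """A protein universe plus the set of pairs held to be true."""

    universe: set[str]
    true_pairs: set[Pair]

    def __post_init__(self) -> None:
        self.true_pairs = {canonical_pair(*p) for p in self.true_pairs}
        for a, b in self.true_pairs:
            if a not in self.universe or b not in self.universe:
                raise ValueError(f"true pair ({a}, {b}) outside the universe")

    @classmethod
    def from_files(cls, pairs_path: str | Path, universe_path: str | Path) -> "ReferenceSet":
        """Read a two-column pair TSV and a one-column universe file."""
        universe: set[str] = set()
        with open(universe_path) as fh:
            for line in fh:
                name = line.strip().split("\t")[0]
                if name and not name.startswith("#"):
                    universe.add(name)
        true_pairs: set[Pair] = set()
        with open(pairs_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = line.rstrip("\n").split("\t")[:2]
                true_pairs.add(canonical_pair(a, b))
        return cls(universe, true_pairs)


@dataclass(frozen=True)
class LabeledPair:
    pair: Pair
    rank: float
    is_true: bool


def as_ranked(items: Iterable) -> list[tuple[Pair, float]]:
    """Normalize scored/comparator/tuple items into (pair, rank) tuples."""
    out: list[tuple[Pair, float]] = []
    for item in items:
        if hasattr(item, "avg_rank"):
            out.append((item.pair, float(item.avg_rank)))
        elif hasattr(item, "rank") and hasattr(item, "pair"):
            out.append((item.pair, float(item.rank)))
        else:
            pair, rank = item
            out.append((canonical_pair(*pair), float(rank)))
    return out


def judgeable(ranked: Iterable, refset: ReferenceSet) -> list[LabeledPair]:
    """Keep pairs with both proteins in the universe, labeling each true or
    false; input order is preserved."""
    out: list[LabeledPair] = []
    for pair, rank in as_ranked(ranked):
        a, b = pair
        if a in refset.universe and b in refset.universe:
            out.append(LabeledPair(pair, rank, pair in refset.true_pairs))
    return out


@dataclass(frozen=True)
class CurvePoint:
    rank: float
    coverage: int
    judgeable_count: int
    accuracy: float


@dataclass
class AccuracyCurve:
    points: list[CurvePoint]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["#rank", "coverage", "judgeable", "accuracy"])
            for pt in self.points:
                writer.writerow([pt.rank, pt.coverage, pt.judgeable_count, pt.accuracy])


def accuracy_coverage_curve(labeled: Sequence[LabeledPair]) -> AccuracyCurve:
    """One curve point per distinct rank value, best ranks first; pairs
    sharing a rank enter the threshold as one atomic group."""
    ordered = sorted(labeled, key=lambda lp: lp.rank)
    points: list[CurvePoint] = []
    cov = 0
    judg = 0
    for rank, group in groupby(ordered, key=lambda lp: lp.rank):
        members = list(group)
        judg += len(members)
        cov += sum(lp.is_true for lp in members)
        points.append(CurvePoint(rank, cov, judg, cov / judg))
    return AccuracyCurve(points)


def average_accuracy(curve: AccuracyCurve | Sequence[LabeledPair]) -> float:
    """True-pair-weighted mean accuracy over rank thresholds.

    <A> = (1/N) sum_r accuracy(r) * n(r) with n(r) the number of true pairs
    first included at threshold r.  Undefined (ValueError) without any true
    pair.
    """
    if not isinstance(curve, AccuracyCurve):
        curve = accuracy_coverage_curve(curve)
    total = curve.points[-1].coverage if curve.points else 0
    if total == 0:
        raise ValueError("no true pairs: average accuracy undefined")
    acc = 0.0
    prev_cov = 0
    for pt in curve.points:
        n_r = pt.coverage - prev_cov
        acc += pt.accuracy * n_r
        prev_cov = pt.coverage
    return acc / total


def expected_random_accuracy(labeled: Sequence[LabeledPair]) -> float:
    """Analytic expectation of <A> under uniformly random ranking: the
    overall fraction of true pairs among judgeable ones."""
    if not labeled:
        raise ValueError("no judgeable pairs")
    return sum(lp.is_true for lp in labeled) / len(labeled)


def sampled_random_accuracy(
    labeled: Sequence[LabeledPair], seed: int, n_samples: int = 1
) -> float:
    """<A> of the labeled list under sampled random rankings (mean over
    ``n_samples`` independent permutations)."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_samples):
        ranks = rng.permutation(len(labeled)) + 1
        shuffled = [
            LabeledPair(lp.pair, float(r), lp.is_true)
            for lp, r in zip(labeled, ranks)
        ]
        vals.append(average_accuracy(shuffled))
    return float(np.mean(vals))


def gain(a: float, a_random: float) -> float:
    """Percent improvement of <A> over the random expectation <A_R>."""
    if a_random <= 0:
        raise ValueError("random-ranking accuracy must be > 0")
    return (a - a_random) / a_random * 100.0


def _top_set(ranking: Ranked, k: int) -> set[Pair]:
    ordered = sorted(ranking, key=lambda pr: (pr[1], pr[0]))
    if k > len(ordered):
        raise ValueError(f"k={k} exceeds ranking size {len(ordered)}")
    cutoff = ordered[k - 1][1]
    return {pair for pair, rank in ordered if rank <= cutoff}


def top_overlap(ranking_a: Iterable, ranking_b: Iterable, k: int) -> float:
    """Fraction of shared pairs among the top-k of two rankings over the
    same pair set.

    A tie group straddling position k is included whole; the denominator is
    then the larger of the two expanded top-set sizes (equal to k whenever
    ranks are distinct)."""
    ra, rb = as_ranked(ranking_a), as_ranked(ranking_b)
    if {p for p, _ in ra} != {p for p, _ in rb}:
        raise ValueError("rankings cover different pair sets")
    top_a = _top_set(ra, k)
    top_b = _top_set(rb, k)
    return len(top_a & top_b) / max(len(top_a), len(top_b))


def ddi_enrichment(
    ranked: Iterable,
    domain_annotation: Mapping[str, Iterable[str]],
    known_ddis: Iterable[tuple[str, str]],
    rank_threshold: float,
) -> float:
    """Fraction of known domain-domain interactions among the candidate
    domain pairs of top-ranked interactions.

    Only judgeable pairs count: both proteins must be annotated and every
    one of their domains must appear in the known-DDI domain universe.  For
    each retained interaction, the candidate set is the full unordered
    cross-product of the two proteins' domain sets (a domain may pair with
    itself); enrichment is the fraction of candidates present in the known
    set, counted with multiplicity across interactions.
    """
    ddis = {tuple(sorted(d)) for d in known_ddis}
    domain_universe = {d for pair in ddis for d in pair}
    annotation = {p: set(ds) for p, ds in domain_annotation.items()}
    n_candidates = 0
    n_known = 0
    n_excluded = 0
    for pair, rank in as_ranked(ranked):
        if rank > rank_threshold:
            continue
        a, b = pair
        dom_a = annotation.get(a)
        dom_b = annotation.get(b)
        if not dom_a or not dom_b:
            n_excluded += 1
            continue
        if not (dom_a <= domain_universe and dom_b <= domain_universe):
            n_excluded += 1
            continue
        seen: set[tuple[str, str]] = set()
        for da in dom_a:
            for db in dom_b:
                seen.add(tuple(sorted((da, db))))
        n_candidates += len(seen)
        n_known += sum(d in ddis for d in seen)
    if n_excluded:
        logger.info("ddi_enrichment: excluded %d non-judgeable pair(s)", n_excluded)
    if n_candidates == 0:
        raise ValueError("no judgeable candidate domain pairs at this threshold")
    return n_known / n_candidates


def evaluate_schemes(
    rankings: Mapping[str, Iterable],
    refsets: Mapping[str, ReferenceSet],
    sampled_control: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Benchmark-summary table: one row per (scheme, reference set) with
    <A>, <A_R> and the percent gain.

    A reference set without any judgeable true pair for a scheme yields a
    flagged row (NaN accuracies) instead of an error.  With
    ``sampled_control`` the random baseline is a sampled permutation rather
    than the analytic expectation.
    """
    rows = []
    for scheme, ranking in rankings.items():
        ranked = as_ranked(ranking)
        for name, refset in refsets.items():
            labeled = judgeable(ranked, refset)
            n_true = sum(lp.is_true for lp in labeled)
            if not labeled or n_true == 0:
                rows.append(
                    dict(
                        scheme=scheme,
                        refset=name,
                        n_judgeable=len(labeled),
                        n_true=n_true,
                        avg_accuracy=np.nan,
                        random_accuracy=np.nan,
                        gain_percent=np.nan,
                        flag="no_judgeable_true_pairs",
                    )
                )
                continue
            a = average_accuracy(labeled)
            if sampled_control:
                a_r = sampled_random_accuracy(labeled, seed=seed)
            else:
                a_r = expected_random_accuracy(labeled)
            rows.append(
                dict(
                    scheme=scheme,
                    refset=name,
                    n_judgeable=len(labeled),
                    n_true=n_true,
                    avg_accuracy=a,
                    random_accuracy=a_r,
                    gain_percent=gain(a, a_r),
                    flag="",
                )
            )
    return pd.DataFrame(rows)
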