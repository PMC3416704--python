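"""Benchmark harness: judgeable logic, accuracy curves, <A>, gain, overlap
and domain-interaction enrichment."""

import numpy as np
import pytest

from idbos import (
    LabeledPair,
    ReferenceSet,
    accuracy_coverage_curve,
    average_accuracy,
    ddi_enrichment,
    evaluate_schemes,
    expected_random_accuracy,
    gain,
    judgeable,
    sampled_random_accuracy,
    top_overlap,
)


def labeled(spec):
    """Build LabeledPairs from (rank, is_true) tuples with synthetic names."""
    return [
        LabeledPair((f"a{i}", f"b{i}"), float(rank), bool(t))
        for i, (rank, t) in enumerate(spec)
    ]


def brute_force_average_accuracy(items):
    """Independent pass: mean accuracy-at-inclusion over true pairs."""
    accs = []
    for lp in items:
        if lp.is_true:
            at_or_above = [x for x in items if x.rank <= lp.rank]
            accs.append(sum(x.is_true for x in at_or_above) / len(at_or_above))
    return sum(accs) / len(accs)


class TestJudgeable:
    def test_filters_and_labels(self):
        refset = ReferenceSet({"A", "B", "C"}, {("A", "B")})
        ranked = [(("A", "B"), 1.0), (("A", "D"), 2.0), (("B", "C"), 3.0)]
        out = judgeable(ranked, refset)
        assert [(lp.pair, lp.is_true) for lp in out] == [
            (("A", "B"), True),
            (("B", "C"), False),
        ]

    def test_empty_universe(self):
        refset = ReferenceSet(set(), set())
        assert judgeable([(("A", "B"), 1.0)], refset) == []

    def test_true_pair_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ReferenceSet({"A"}, {("A", "B")})

    def test_from_files(self, tmp_path):
        (tmp_path / "pairs.tsv").write_text("B\tA\nC\tA\n")
        (tmp_path / "universe.txt").write_text("A\nB\nC\nD\n")
        rs = ReferenceSet.from_files(tmp_path / "pairs.tsv", tmp_path / "universe.txt")
        assert rs.true_pairs == {("A", "B"), ("A", "C")}
        assert rs.universe == {"A", "B", "C", "D"}


class TestAccuracyCurve:
    def test_distinct_rank_points(self):
        curve = accuracy_coverage_curve(labeled([(1, True), (2, False), (3, True)]))
        got = [(p.rank, p.coverage, p.judgeable_count, p.accuracy) for p in curve.points]
        assert got == [
            (1.0, 1, 1, 1.0),
            (2.0, 1, 2, 0.5),
            (3.0, 2, 3, pytest.approx(2 / 3)),
        ]

    def test_tied_ranks_enter_together(self):
        curve = accuracy_coverage_curve(labeled([(1, True), (1, False)]))
        assert len(curve.points) == 1
        pt = curve.points[0]
        assert (pt.coverage, pt.judgeable_count, pt.accuracy) == (1, 2, 0.5)

    def test_all_false(self):
        curve = accuracy_coverage_curve(labeled([(1, False), (2, False)]))
        assert all(p.accuracy == 0 for p in curve.points)


class TestAverageAccuracy:
    def test_hand_example(self):
        items = labeled([(1, True), (2, False), (3, True)])
        assert average_accuracy(items) == pytest.approx((1.0 + 2 / 3) / 2)

    def test_all_true_and_single_late_truth(self):
        assert average_accuracy(labeled([(1, True), (2, True)])) == 1.0
        k = 5
        items = labeled([(r, r == k) for r in range(1, k + 1)])
        assert average_accuracy(items) == pytest.approx(1 / k)

    def test_no_true_pairs_is_undefined(self):
        with pytest.raises(ValueError):
            average_accuracy(labeled([(1, False)]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        ranks = rng.choice(np.arange(1, 15), size=n)  # many ties
        truths = rng.random(n) < 0.3
        if not truths.any():
            truths[0] = True
        items = [
            LabeledPair((f"x{i}", f"y{i}"), float(r), bool(t))
            for i, (r, t) in enumerate(zip(ranks, truths))
        ]
        assert average_accuracy(items) == pytest.approx(
            brute_force_average_accuracy(items), rel=1e-12
        )


class TestRandomBaselineAndGain:
    def test_expected_random_accuracy(self):
        assert expected_random_accuracy(labeled([(1, True), (2, False), (3, False)])) == pytest.approx(1 / 3)
        assert expected_random_accuracy(labeled([(1, True), (2, True)])) == 1.0

    def test_monte_carlo_mean_matches_exact_permutation_expectation(self):
        # Exact E[<A>] under a random permutation: a true pair's position r
        # is uniform and the accuracy there is (1 + (r-1)(t-1)/(n-1))/r,
        # giving E[<A>] = f + (1 - f) H_n / n with f = (t-1)/(n-1).  This
        # exceeds the true fraction t/n by a finite-size term ~(1-p) H_n/n
        # that vanishes for large judgeable sets.
        n, t = 12, 4
        items = labeled([(r, r <= t) for r in range(1, n + 1)])
        h_n = sum(1 / r for r in range(1, n + 1))
        f = (t - 1) / (n - 1)
        exact = f + (1 - f) * h_n / n
        draws = [sampled_random_accuracy(items, seed=s) for s in range(1000)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - exact) < 3 * se
        # the analytic large-n baseline sits within the finite-size term
        assert abs(exact - expected_random_accuracy(items)) < (1 - t / n) * h_n / n + 1e-9

    def test_gain(self):
        assert gain(0.3, 0.3) == 0.0
        assert gain(0.6, 0.2) == pytest.approx(200.0)
        with pytest.raises(ValueError):
            gain(0.5, 0.0)

    def test_loosest_threshold_accuracy_equals_random_expectation(self):
        # with all pairs included, ranking carries no information
        items = labeled([(r, r % 4 == 1) for r in range(1, 21)])
        curve = accuracy_coverage_curve(items)
        assert curve.points[-1].accuracy == pytest.approx(expected_random_accuracy(items))


class TestTopOverlap:
    def test_identical_and_reversed(self):
        a = [((f"x{i}", f"y{i}"), float(i)) for i in range(1, 11)]
        b = [(p, 11.0 - r) for p, r in a]
        for k in (1, 3, 5, 10):
            assert top_overlap(a, a, k) == 1.0
        assert top_overlap(a, b, 3) == 0.0
        assert top_overlap(a, b, 10) == 1.0

    def test_tie_group_expansion(self):
        a = [(("p", "q"), 1.0), (("r", "s"), 2.0), (("t", "u"), 2.0), (("v", "w"), 4.0)]
        b = [(("p", "q"), 1.0), (("r", "s"), 2.0), (("t", "u"), 3.0), (("v", "w"), 4.0)]
        # k=2 expands a's tie group to 3 entries; denominator follows
        assert top_overlap(a, b, 2) == pytest.approx(2 / 3)

    def test_random_rankings_overlap_near_k_over_n(self):
        n, k = 200, 20
        pairs = [(f"x{i}", f"y{i}") for i in range(n)]
        rng = np.random.default_rng(5)
        overlaps = []
        for _ in range(100):
            ra = [(p, float(r)) for p, r in zip(pairs, rng.permutation(n) + 1)]
            rb = [(p, float(r)) for p, r in zip(pairs, rng.permutation(n) + 1)]
            overlaps.append(top_overlap(ra, rb, k))
        assert np.mean(overlaps) == pytest.approx(k / n, abs=0.03)

    def test_mismatched_pair_sets_rejected(self):
        with pytest.raises(ValueError):
            top_overlap([(("a", "b"), 1.0)], [(("c", "d"), 1.0)], 1)


class TestDDIEnrichment:
    DOMAINS = {"A": {"d1"}, "B": {"d2"}, "C": {"d1", "d3"}}

    def test_single_known_pair(self):
        assert ddi_enrichment([(("A", "B"), 1.0)], self.DOMAINS, {("d1", "d2")}, 1.0) == 1.0

    def test_unknown_candidate(self):
        # d2 is in the DDI universe but (d1, d2) is not a known DDI
        known = {("d1", "d3"), ("d2", "d4")}
        assert ddi_enrichment([(("A", "B"), 1.0)], self.DOMAINS, known, 1.0) == 0.0

    def test_unannotated_protein_excluded(self):
        ranked = [(("A", "Z"), 1.0), (("A", "B"), 2.0)]
        assert ddi_enrichment(ranked, self.DOMAINS, {("d1", "d2")}, 2.0) == 1.0
        with pytest.raises(ValueError):  # nothing judgeable at all
            ddi_enrichment([(("A", "Z"), 1.0)], self.DOMAINS, {("d1", "d2")}, 1.0)

    def test_planted_ddi_signal_rises_with_stricter_threshold(self):
        rng = np.random.default_rng(11)
        domains = {f"P{i}": {f"d{rng.integers(0, 12)}"} for i in range(120)}
        known = {tuple(sorted((f"d{i}", f"d{(i + 1) % 12}"))) for i in range(12)}
        ranked = []
        rank = 0
        for i in range(0, 120, 2):
            rank += 1
            a, b = f"P{i}", f"P{i + 1}"
            if rank <= 30:  # top ranks: force a known DDI behind the pair
                da = next(iter(domains[a]))
                match = [d for d in known if da in d]
                if match:
                    other = match[0][0] if match[0][1] == da else match[0][1]
                    domains[b] = {other}
            ranked.append(((a, b), float(rank)))
        loose = ddi_enrichment(ranked, domains, known, rank_threshold=60)
        strict = ddi_enrichment(ranked, domains, known, rank_threshold=20)
        assert strict > loose


class TestEvaluateSchemes:
    def test_perfect_and_flagged_rows(self):
        refset = ReferenceSet({"A", "B", "C", "D"}, {("A", "B")})
        empty_ref = ReferenceSet({"X", "Y"}, set())
        perfect = [(("A", "B"), 1.0), (("C", "D"), 2.0)]
        table = evaluate_schemes({"perfect": perfect}, {"main": refset, "empty": empty_ref})
        main = table[table.refset == "main"].iloc[0]
        assert main.avg_accuracy == 1.0
        assert main.gain_percent == pytest.approx(gain(1.0, 0.5))
        empty = table[table.refset == "empty"].iloc[0]
        assert empty.flag == "no_judgeable_true_pairs"
        assert np.isnan(empty.avg_accuracy)
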