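# Methods

## Data model

One *record* is a publication-level report of a physical interaction
between two proteins.  Pairs are unordered and canonicalized
lexicographically; self-reports are dropped at load (counted and logged)
because the null model forbids self-pairs.  Records lacking a publication
identifier are rejected at parse rather than silently merged or counted —
the record key is (canonical pair, publication id), and cross-database
mirror copies of the same publication are removed by that key, ignoring
the source database.  Aggregation yields O_ij (records per pair), N_i
(reports per protein, with multiplicity — its "occurrence", distinct from
its degree) and N = Σ O_ij.  Identifiers are opaque strings; no
gene-symbol mapping or aliasing is attempted.

## The shuffle null model

A network with N records is a list of 2N endpoint slots ("stubs"),
protein i contributing N_i stubs.  The null distribution of each pair's
occurrence is that of a uniformly random perfect matching of the stubs
*conditioned on containing no self-pair*.  Feasibility requires
max_i N_i ≤ N; violating networks raise an explicit error.

Exact sampling by rejection is hopeless for realistic data (a corpus with
hub proteins carrying thousands of reports has hundreds of expected
self-pairs per unconditioned matching), so each realization is drawn as:

1. Fisher–Yates shuffle of the stub list, pairing consecutive stubs
   (uniform over all matchings);
2. repair: while self-pairs remain, swap one endpoint of a self-pair with
   a random endpoint elsewhere, accepting only swaps that create no new
   self-pair (terminates with probability 1 under feasibility);
3. mixing: `sweeps × N` symmetric Metropolis double-swap moves — pick two
   pair slots and one of the two endpoint exchanges, reject any move that
   would create a self-pair.

Step 3 is essential, not cosmetic.  The bare shuffle-plus-repair sampler
is measurably biased: on the four-protein network with report counts
{A:2, B:2, C:1, D:1} the exact conditional probability of the outcome
{AB, AB, CD} is 1/5, while shuffle-plus-repair yields 1/6 (worked out by
enumerating the repair chain's transitions) — a 0.033 absolute error, far
above Monte-Carlo noise at the ensemble sizes used here.  The double-swap
proposal is symmetric and the target uniform, so the chain's stationary
distribution is uniform over self-pair-free matchings; with a fresh
shuffle + repair start each realization, the sweeps erase the repair bias
and successive realizations are independent.  The default of 10 sweeps is
far beyond the mixing needed on the tiny networks where exactness is
verifiable (state spaces of ≤ a few dozen matchings) and is validated
end-to-end against the enumeration oracle (below).  Chain connectivity
over the constrained matching space is assumed for feasible networks;
no counterexample arose in any enumeration check.

Per-pair ensemble statistics (⟨R_ij⟩, σ_R, and the count of realizations
with R_ij ≥ O_ij) are streamed with Welford's one-pass update, so M = 10^6
realizations need no storage.  σ_R uses the sample (n−1) normalization;
with the M values used in practice the difference from the population
convention is far below other Monte-Carlo uncertainty.  All kernels are
numba-compiled; a run is bit-reproducible given (network, M, seed).
M is configurable: 10^4 is comfortable for desk-scale corpora, 10^6
matches the precision of the published full-corpus analysis.

## Scores, degenerate cases, ranks

Z_ij = (O_ij − ⟨R_ij⟩)/σ_R; p_ij = exceed_count/M (the plain empirical
tail — an optional (k+1)/(M+1) pseudo-count estimator is available behind
a flag but is not the default, preserving the published estimator).  When
σ_R = 0 (forced matchings), Z is 0 if O equals the null mean and
otherwise sign(O − ⟨R⟩) × (largest finite |Z| in the run + 1), so
degenerate pairs sort beyond all finite-Z pairs without inventing a
magnitude; occurrences are logged.  p = 0 at finite M is kept as-is; the
resulting p-rank tie group is resolved by the Z-rank through averaging.

Fractional ranking assigns tied values the mean of the ordinal positions
they span (ranks of n items always sum to n(n+1)/2); Z ranks
larger-is-better, p smaller-is-better, and the final ordering is the mean
of the two ranks.  Pairs sharing an average rank form an explicit tie
group; output order within a group is lexicographic, making files
deterministic.

## Enumeration oracle

For networks with at most 14 stubs, all perfect matchings are enumerated
recursively (first unmatched stub paired with every later stub), invalid
matchings discarded, and each pair's exact conditional occurrence PDF
tallied.  The oracle is the independent ground truth for the sampler: on
a fixed family of twelve tiny networks spanning forced matchings, hubs,
stars, disjoint edges, triangles and multi-edges, every empirical mass
point at M = 2×10^5 must sit within 4 Monte-Carlo standard errors of the
exact mass.  The family is a designed test set, not an exhaustive
enumeration of all networks of that size (whose shape count is unbounded
once pair multisets are distinguished).

## Comparator schemes

*Hypergeometric test.*  The upper tail
p = Σ_{n=N_ij}^{min(N_i,N_j)} C(N_j, n)·C(2N−N_j, N_i−n) / C(2N, N_i):
protein i's N_i endpoint slots drawn from the 2N total, N_j of which
belong to protein j.  This formulation is the standard reading of the
co-occurrence test (valid in the limit N ≫ N_i·N_j) and is evaluated in
log space via lgamma + logsumexp, since direct factorials overflow at
corpus scale.  The same kernel backs the annotation-overlap score.  Its
conceptual difference from the shuffle model is the treatment of
self-pairs: the hypergeometric background gives A–A pairings finite
probability, which for popular proteins redistributes mass away from real
partners and overstates their significance — on the minimal two-stub
network {A:1, B:1} the shuffle tail for the pair (A, B) is exactly 1
(the pairing is forced) while the hypergeometric tail is 0.5.

*Occurrence.*  Fractional ranks on O_ij, larger-is-better; large tie
groups are expected since most pairs are singletons.

*Random controls.*  Random ranks (pairs kept, ranks permuted) and a
degree-preserving rewire of the unique-pair graph.  Rewiring uses
networkx double edge swaps with rejection of degenerate swaps; it
preserves unique-pair degrees, not occurrence multiplicities (the
multiplicity-preserving variant would be the shuffle engine itself).  A
swap chain that exhausts its try budget returns its current state with a
warning rather than failing.

## Evaluation harness

A pair is *judgeable* under a reference set when both proteins belong to
the reference universe, and *true* when listed.  The accuracy–coverage
curve has one point per distinct rank; tie groups are atomic at
thresholds.  Average accuracy is
⟨A⟩ = (1/N) Σ_r accuracy(r)·n(r), with n(r) the number of true pairs
whose rank is r — the mean accuracy-at-inclusion over true pairs — and
gain = (⟨A⟩ − ⟨A_R⟩)/⟨A_R⟩ × 100.

The default ⟨A_R⟩ is the analytic large-n baseline: the overall true
fraction among judgeable pairs (the flat accuracy profile a random
ranking approaches).  The exact permutation expectation is *larger* at
small n: conditioning on a true pair occupying threshold position r
biases accuracy upward by ~(1−p)·H_n/n, and the exact value is
E[⟨A⟩] = f + (1−f)·H_n/n with f = (t−1)/(n−1).  The test suite pins the
sampled estimator to this closed form; a `sampled_control` option uses a
sampled permutation instead of the analytic baseline.  Consequently, on
small benchmarks a random ranking shows a small positive gain against the
analytic baseline — a finite-size artifact, not information.

Top-k overlap expands tie groups straddling position k wholly on both
sides and divides the intersection by the larger expanded top-set size
(equal to k whenever ranks are distinct).  Domain-interaction enrichment
restricts to pairs whose proteins are annotated and whose domains all
appear in the known-DDI domain universe, enumerates the unordered
cross-product of the two proteins' domain sets per interaction
(self-domain pairs allowed), and reports the fraction of candidates that
are known, with multiplicity across interactions.

## Reference-set statistics

Annotation sets are closed under child→parent DAG traversal before
scoring (ontology input is a plain edge list, not OBO — a documented
simplification that keeps the statistic testable without an ontology
parser); cycles are rejected naming a member.  The overlap score is the
hypergeometric upper tail of n_gh among (N_g, N_h) terms from the T
observed distinct terms, reported as −log p (natural log).  T is the
observed term universe of the supplied table.

Tissue specificity standardizes a gene's abundance in tissue k against a
uniform-allocation model: with tissue shares q_k = E_k/Σ_m E_m (summing
to 1 by construction),
Z_k(g) = (e_k(g) − E(g)·q_k)/√(E(g)·q_k·(1−q_k)).  Genes or tissues with
zero totals are excluded (the statistic is undefined there), not imputed.
Co-expression is the dot product of two Z-profiles.  Top-percent
selection cuts at the k-th best score, k = max(1, ⌊n·percent/100⌋), and
includes all ties at the cut — deterministic and threshold-monotone.

## Synthetic generator

The generator's defaults (300 proteins, 600 planted true pairs, 3000
records, false rate 0.4, popularity exponent 1.5, 32 tissues) are the
package's standard study conditions.  Popularity weights w_i ∝ i^−1.5
over the protein index give a heavy-tailed study-intensity profile whose
hub accumulates on the order of a thousand report endpoints — the regime
where occurrence counting is most confounded.  True records sample
planted pairs ∝ w_i·w_j; false records sample popularity-weighted
non-true pairs, modeling popularity-driven spurious reports.  Every
record carries a unique synthetic publication id, and truth labels are
carried out of band so the scoring pipeline cannot see them.  The
expression generator boosts both genes of each planted pair in a shared
random tissue subset over gamma background noise.

What passing tests show — and what they do not: on this generator the
shuffle ranking beats occurrence ranking, and both beat the random
baseline, in ≥9/10 seeds; that demonstrates the popularity-bias
correction.  The generator does *not* reproduce other features of real
literature corpora — the empirical degree distribution, study-level
correlations between reports, or the specific hub regime in which the
shuffle model clearly outperforms the hypergeometric test on real data;
here the two probabilistic schemes perform comparably.  No fit of the
generator to real aggregated data is attempted.

## Problem sizes and numerical choices

The standard verification runs use M = 2×10^5 realizations for
oracle-equivalence on tiny networks, M = 10^4 for the ten-seed recovery
benchmark at the default study conditions, and M in the low thousands
for smoke-level checks — sizes chosen to keep the whole suite a
few-minute desk run while leaving Monte-Carlo tolerances (quoted per
check in standard-error units) meaningful.  Binomials are never formed
directly (lgamma/logsumexp only); rank arithmetic is exact on halves;
all random streams derive from explicit integer seeds, with the engine
seeded below 2^31.

## Known limitations

* Chain connectivity of the double-swap walk on self-pair-free matchings
  is assumed, not proven, for arbitrary feasible networks.
* The rewire control accepts swap-chain semantics (adequate mixing, not
  exact uniformity over fixed-degree graphs).
* The hypergeometric formulation is an interpretation of a test whose
  printed form in secondary sources is typographically inconsistent; the
  implemented tail is stated explicitly above.
* Ontology handling is generic DAG closure over a supplied edge list; no
  OBO parsing, relationship typing, or term namespaces.
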