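"""Benchmark ranking schemes on synthetic popularity-biased data.

Generates a record stream over a planted true interactome (40% spurious,
popularity-weighted reports), scores it with the shuffle null model, the
hypergeometric test and raw occurrence, and evaluates each ranking against
the planted truth with average accuracy <A> and the percent gain over a
random ranking.  A smaller corpus than the package defaults keeps the
example quick.
"""

from idbos import (
    SyntheticConfig,
    aggregate,
    deduplicate,
    evaluate_schemes,
    generate_records,
    generate_truth,
    hypergeometric_rank,
    idbos_score,
    occurrence_rank,
    random_rank,
)

config = SyntheticConfig(
    n_proteins=120, n_true_pairs=250, n_records=1200, false_rate=0.4, seed=11
)
truth = generate_truth(config)
sample = generate_records(config, truth)
network = aggregate(deduplicate(sample.records))
print(
    f"{network.total_records} records -> {network.n_pairs} unique pairs over "
    f"{network.n_proteins} proteins (hub N_max = {max(network.protein_occurrence.values())})"
)

rankings = {
    "idbos": idbos_score(network, m=5000, seed=1),
    "hypergeometric": hypergeometric_rank(network),
    "occurrence": occurrence_rank(network),
    "random": random_rank(network.pairs, seed=2),
}
table = evaluate_schemes(rankings, {"planted_truth": truth})
print()
print(table[["scheme", "n_judgeable", "n_true", "avg_accuracy", "random_accuracy", "gain_percent"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))

print(
    "\n<A> is the mean accuracy at the rank where each true pair enters; "
    "gain compares it\nto the no-ranking baseline (the true fraction among "
    "judgeable pairs).  The shuffle\nnull model separates planted truth "
    "from popularity-driven noise far better than\noccurrence counting; "
    "random ranks hover near zero gain."
)
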