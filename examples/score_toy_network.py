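"""Score a small hand-built record list with the shuffle null model.

Builds a 14-record corpus in which one heavily studied hub (HUB1)
accumulates reports with many partners, while two quiet protein pairs are
each reported twice.  The shuffle null model (protein report counts
preserved, no self-pairs) recognizes that two joint reports of two rare
proteins are far less likely by chance than repeated sightings of the hub,
and ranks the rare repeated pairs first.
"""

from idbos import InteractionRecord, aggregate, deduplicate, idbos_score

RAW = [
    # hub protein reported with many partners (popularity, not specificity)
    ("HUB1", "X1", "PMID:1"), ("HUB1", "X2", "PMID:2"), ("HUB1", "X3", "PMID:3"),
    ("HUB1", "X4", "PMID:4"), ("HUB1", "X5", "PMID:5"), ("HUB1", "X1", "PMID:6"),
    ("HUB1", "X2", "PMID:7"), ("HUB1", "X3", "PMID:8"),
    # two quiet pairs, each independently reported twice
    ("ENZA", "ENZB", "PMID:9"), ("ENZA", "ENZB", "PMID:10"),
    ("RCPT", "LGND", "PMID:11"), ("RCPT", "LGND", "PMID:12"),
    # background singletons
    ("X4", "X5", "PMID:13"), ("ENZA", "X1", "PMID:14"),
]

records = deduplicate([InteractionRecord(a, b, pub) for a, b, pub in RAW])
network = aggregate(records)
print(f"{network.total_records} records, {network.n_pairs} pairs, "
      f"{network.n_proteins} proteins; HUB1 occurrence "
      f"N={network.protein_occurrence['HUB1']}, degree={network.degree('HUB1')}")

scored = idbos_score(network, m=20_000, seed=42)
print(f"\n{'pair':<14}{'O':>3}{'Z':>8}{'p':>9}{'avg_rank':>10}")
for sp in scored:
    name = f"{sp.pair[0]}-{sp.pair[1]}"
    print(f"{name:<14}{sp.occurrence:>3}{sp.z:>8.2f}{sp.p:>9.4f}{sp.avg_rank:>10.1f}")

print(
    "\nThe twice-reported quiet pairs (ENZA-ENZB, RCPT-LGND) outrank every "
    "hub pair:\ntheir observed occurrence is many null standard deviations "
    "above the shuffled\nexpectation (large Z, tiny p), while the hub's "
    "repeated reports are largely\nexplained by its popularity alone."
)
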