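"""TSV writers/readers for scored and comparator-ranked pair lists."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .core import ScoredPair
from .ranking import ComparatorScore
from .records import Pair, canonical_pair

__all__ = [
    "write_scored_tsv",
    "write_comparator_tsv",
    "read_ranking_tsv",
    "write_pairs_tsv",
]


def write_scored_tsv(scored: Sequence[ScoredPair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["#protein_a", "protein_b", "occurrence", "z", "p", "z_rank", "p_rank", "avg_rank"]
        )
        for sp in scored:
            writer.writerow(
                [
                    sp.pair[0],
                    sp.pair[1],
                    sp.occurrence,
                    f"{sp.z:.6g}",
                    f"{sp.p:.6g}",
                    sp.z_rank,
                    sp.p_rank,
                    sp.avg_rank,
                ]
            )


def write_comparator_tsv(scores: Sequence[ComparatorScore], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["#protein_a", "protein_b", "method", "score", "rank"])
        for cs in scores:
            writer.writerow([cs.pair[0], cs.pair[1], cs.method, f"{cs.score:.6g}", cs.rank])


def read_ranking_tsv(path: str | Path) -> list[tuple[Pair, float]]:
    """Read any scored TSV back as (pair, rank) tuples; the rank column is
    ``avg_rank`` when present, else ``rank``."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        header[0] = header[0].lstrip("#")
        cols = {name: i for i, name in enumerate(header)}
        rank_col = cols.get("avg_rank", cols.get("rank"))
        if rank_col is None:
            raise ValueError(f"{path}: no avg_rank or rank column")
        out = []
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            out.append((canonical_pair(row[0], row[1]), float(row[rank_col])))
    return out


def write_pairs_tsv(pairs: Iterable[Pair], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a, b in sorted(pairs):
            writer.writerow([a, b])
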