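"""Data model and I/O for literature-reported protein-protein interactions.

A *record* is one report of a physical interaction between two proteins in
one publication.  The same biological interaction may be reported many times
(different publications) and stored redundantly (the same publication
mirrored across several source databases).  This module loads record files,
removes cross-database redundancy, and aggregates the surviving records into
an occurrence-weighted network:

* ``O_ij`` -- number of distinct publication-level records for pair (i, j);
* ``N_i``  -- total number of reported interactions involving protein i,
  counting multiplicity (its "occurrence", a popularity readout);
* degree   -- number of *distinct* partners of i, always <= ``N_i``.

Pairs are unordered and stored canonically with ``protein_a < protein_b``
under lexicographic order.  Self-reports (A interacting with A) are dropped
at load time because the downstream randomization model forbids self-pairs.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "LoadResult",
    "AggregatedNetwork",
    "ParseError",
    "canonical_pair",
    "load_records",
    "deduplicate",
    "aggregate",
    "degree",
    "degree_distribution",
]

Pair = tuple[str, str]


class ParseError(ValueError):
    """A record file violated the expected tab-delimited shape."""


def canonical_pair(a: str, b: str) -> Pair:
    """Return the unordered pair (a, b) in canonical lexicographic order.

    Raises ``ValueError`` for a self-pair: no interaction is admitted
    between two copies of the same identifier.
    """
    a = a.strip()
    b = b.strip()
    if not a or not b:
        raise ValueError("empty protein identifier")
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One publication-level report of a physical interaction.

    The pair is canonicalized on construction (``protein_a < protein_b``);
    constructing a self-report raises ``ValueError``.
    """

    protein_a: str
    protein_b: str
    publication_id: str
    source_db: str = ""

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        object.__setattr__(self, "publication_id", self.publication_id.strip())
        if not self.publication_id:
            raise ValueError("record without a publication identifier")

    @property
    def pair(self) -> Pair:
        return (self.protein_a, self.protein_b)


@dataclass
class LoadResult:
    """Records parsed from a file plus the count of dropped self-reports."""

    records: list[InteractionRecord]
    n_self_dropped: int = 0

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_records(path: str | Path, format: str = "tsv") -> LoadResult:
    """Load interaction records from a tab-delimited file.

    Expected columns: protein_a, protein_b, publication_id and an optional
    source database.  Lines starting with ``#`` are ignored.  Rows pairing a
    protein with itself are dropped (logged, counted in the result); a row
    with fewer than three columns or a blank publication identifier is a
    :class:`ParseError` naming the offending line.
    """
    if format != "tsv":
        raise ValueError(f"unknown record format {format!r}")
    path = Path(path)
    records: list[InteractionRecord] = []
    n_self = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if len(row) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(row)}"
                )
            a, b, pub = row[0], row[1], row[2]
            src = row[3].strip() if len(row) > 3 else ""
            if a.strip() == b.strip():
                n_self += 1
                logger.warning("%s:%d: dropping self-report %r", path, lineno, a.strip())
                continue
            try:
                records.append(InteractionRecord(a, b, pub, src))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if not records and n_self == 0:
        raise ParseError(f"{path}: no records found")
    if n_self:
        logger.warning("%s: dropped %d self-report(s)", path, n_self)
    return LoadResult(records, n_self)


def deduplicate(records: Iterable[InteractionRecord]) -> list[InteractionRecord]:
    """Collapse redundant copies of the same (pair, publication) report.

    Aggregated collections mirror the same publication across several source
    databases; only the first copy of each (canonical pair, publication_id)
    key is kept, in order of first appearance.  The source database is
    deliberately ignored by the key.
    """
    seen: set[tuple[Pair, str]] = set()
    out: list[InteractionRecord] = []
    for rec in records:
        key = (rec.pair, rec.publication_id)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


@dataclass
class AggregatedNetwork:
    """Unique unordered pairs with occurrence counts.

    Attributes
    ----------
    pair_occurrence
        Canonical pair (i, j) -> O_ij, the number of distinct records.
    protein_occurrence
        Protein -> N_i, total reports involving that protein (with
        multiplicity).  Satisfies sum_i N_i = 2 N.
    total_records
        N, the number of deduplicated records; equals sum_ij O_ij.
    """

    pair_occurrence: dict[Pair, int]
    protein_occurrence: dict[str, int] = field(default_factory=dict)
    total_records: int = 0

    def __post_init__(self) -> None:
        if not self.protein_occurrence:
            occ: Counter[str] = Counter()
            for (a, b), o in self.pair_occurrence.items():
                occ[a] += o
                occ[b] += o
            self.protein_occurrence = dict(occ)
        if not self.total_records:
            self.total_records = sum(self.pair_occurrence.values())
        self._partners: dict[str, int] | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[InteractionRecord]) -> "AggregatedNetwork":
        pair_occ: Counter[Pair] = Counter(rec.pair for rec in records)
        return cls(dict(pair_occ))

    # -- basic views ------------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return sorted(self.protein_occurrence)

    @property
    def pairs(self) -> list[Pair]:
        return sorted(self.pair_occurrence)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_occurrence)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_occurrence)

    def occurrence(self, pair: Pair) -> int:
        return self.pair_occurrence[canonical_pair(*pair)]

    def degree(self, protein: str) -> int:
        """Number of distinct interaction partners (<= N_protein)."""
        if protein not in self.protein_occurrence:
            raise KeyError(f"unknown protein {protein!r}")
        if self._partners is None:
            partners: Counter[str] = Counter()
            for a, b in self.pair_occurrence:
                partners[a] += 1
                partners[b] += 1
            self._partners = dict(partners)
        return self._partners[protein]

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write [protein_a, protein_b, occurrence] rows, sorted by pair."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["#protein_a", "protein_b", "occurrence"])
            for a, b in self.pairs:
                writer.writerow([a, b, self.pair_occurrence[(a, b)]])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AggregatedNetwork":
        path = Path(path)
        pair_occ: dict[Pair, int] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=1):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 columns")
                pair = canonical_pair(row[0], row[1])
                o = int(row[2])
                if o < 1:
                    raise ParseError(f"{path}:{lineno}: occurrence must be >= 1")
                pair_occ[pair] = pair_occ.get(pair, 0) + o
        if not pair_occ:
            raise ParseError(f"{path}: no pairs found")
        return cls(pair_occ)


def aggregate(records: Iterable[InteractionRecord]) -> AggregatedNetwork:
    """Aggregate deduplicated records into an occurrence-weighted network."""
    return AggregatedNetwork.from_records(records)


def degree(network: AggregatedNetwork, protein: str) -> int:
    """Distinct-partner count of ``protein`` in ``network``."""
    return network.degree(protein)


def degree_distribution(pairs: Iterable[Pair]) -> dict[int, int]:
    """Map degree -> number of proteins with that degree.

    Satisfies the handshake identity
    ``sum(degree * count) == 2 * n_pairs`` for any simple pair set.
    """
    partners: Counter[str] = Counter()
    for a, b in set(canonical_pair(a, b) for a, b in pairs):
        partners[a] += 1
        partners[b] += 1
    return dict(Counter(partners.values()))
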