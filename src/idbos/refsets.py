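"""Reference-set construction statistics.

These are the scores used to build indirect reference sets from annotation
and expression data:

* ontology ancestor closure -- each gene's term set expanded with every
  ancestor in a child->parent DAG, so genes annotated at different depths
  become comparable;
* co-annotation significance -- hypergeometric upper tail of the overlap
  n_gh between two genes' (closed) term sets drawn from T distinct terms,
  scored as -log(p);
* tissue specificity -- for a gene g with total expression E(g) spread over
  tissues with expression shares q_k, the standardized deviation
  Z_k(g) = (e_k(g) - E(g) q_k) / sqrt(E(g) q_k (1 - q_k)) of its observed
  abundance in tissue k from a uniform-allocation ("darts") model;
* co-expression score C_gh = sum_k Z_k(g) Z_k(h), the dot product of two
  genes' specificity profiles;
* top-percent selection of scored pairs (ties at the cut included whole).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._hyper import hypergeom_tail
from .records import Pair, canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationTable",
    "ancestor_closure",
    "coannotation_pvalue",
    "coannotation_score",
    "tissue_specificity",
    "coexpression_score",
    "coexpression_matrix",
    "top_percent_pairs",
]


@dataclass
class AnnotationTable:
    """Gene -> closed term set, plus the distinct-term count T."""

    annotations: dict[str, set[str]]

    @property
    def total_terms(self) -> int:
        return len({t for terms in self.annotations.values() for t in terms})

    def n_terms(self, gene: str) -> int:
        return len(self.annotations[gene])

    def overlap(self, g: str, h: str) -> int:
        return len(self.annotations[g] & self.annotations[h])


def ancestor_closure(
    annotations: Mapping[str, Iterable[str]],
    dag_edges: Iterable[tuple[str, str]],
) -> AnnotationTable:
    """Close each gene's term set under child -> parent traversal.

    ``dag_edges`` lists (child, parent) relations; a cycle raises
    ``ValueError`` naming one of its members.
    """
    dag = nx.DiGraph()
    dag.add_edges_from(dag_edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology edges contain a cycle through {cycle[0][0]!r}")
    closure_cache: dict[str, set[str]] = {}

    def ancestors(term: str) -> set[str]:
        if term not in closure_cache:
            closure_cache[term] = (
                nx.descendants(dag, term) if term in dag else set()
            )
        return closure_cache[term]

    closed = {
        gene: set(terms) | {a for t in terms for a in ancestors(t)}
        for gene, terms in annotations.items()
    }
    return AnnotationTable(closed)


def coannotation_pvalue(n_gh: int, n_g: int, n_h: int, t: int) -> float:
    """Probability of an annotation overlap >= n_gh by chance when two
    genes carry n_g and n_h terms from a vocabulary of t distinct terms."""
    if not 0 <= n_gh <= min(n_g, n_h) <= t:
        raise ValueError(
            f"invalid overlap arguments: n_gh={n_gh}, n_g={n_g}, n_h={n_h}, t={t}"
        )
    if n_gh == 0:
        return 1.0
    return hypergeom_tail(n_gh, n_success=n_h, n_draws=n_g, n_pop=t)


def coannotation_score(n_gh: int, n_g: int, n_h: int, t: int) -> float:
    """-log(p_gh), the co-annotation significance score (natural log)."""
    return -math.log(coannotation_pvalue(n_gh, n_g, n_h, t))


def tissue_specificity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardized tissue-specificity profile Z_k(g) for every gene.

    ``matrix`` is genes x tissues with non-negative abundances.  Tissues
    with zero total and genes with zero total are excluded (logged): the
    statistic is undefined for them.  Tissue shares q_k = E_k / sum_m E_m
    satisfy sum_k q_k = 1 over the retained tissues.
    """
    if (matrix.values < 0).any():
        raise ValueError("expression abundances must be non-negative")
    tissue_totals = matrix.sum(axis=0)
    dead_tissues = tissue_totals[tissue_totals == 0].index
    if len(dead_tissues):
        logger.warning("excluding %d tissue(s) with zero total", len(dead_tissues))
        matrix = matrix.drop(columns=dead_tissues)
        tissue_totals = tissue_totals.drop(dead_tissues)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 tissues with signal")
    gene_totals = matrix.sum(axis=1)
    dead_genes = gene_totals[gene_totals == 0].index
    if len(dead_genes):
        logger.warning("excluding %d gene(s) with zero total", len(dead_genes))
        matrix = matrix.drop(index=dead_genes)
        gene_totals = gene_totals.drop(dead_genes)
    q = tissue_totals / tissue_totals.sum()
    expected = np.outer(gene_totals.values, q.values)
    var = expected * (1.0 - q.values)[None, :]
    z = (matrix.values - expected) / np.sqrt(var)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def coexpression_score(z_g: np.ndarray, z_h: np.ndarray) -> float:
    """Dot product of two tissue-specificity profiles."""
    z_g = np.asarray(z_g, dtype=float)
    z_h = np.asarray(z_h, dtype=float)
    if z_g.shape != z_h.shape:
        raise ValueError("specificity vectors differ in length")
    return float(z_g @ z_h)


def coexpression_matrix(z: pd.DataFrame) -> dict[Pair, float]:
    """All-pairs co-expression scores C_gh from a specificity table."""
    genes = list(z.index)
    c = z.values @ z.values.T
    out: dict[Pair, float] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            out[canonical_pair(genes[i], genes[j])] = float(c[i, j])
    return out


def top_percent_pairs(scores: Mapping[Pair, float], percent: float) -> set[Pair]:
    """Pairs scoring in the top ``percent`` of all scored pairs.

    The cut falls at the k-th best score with k = max(1,
    floor(n * percent / 100)); pairs tied with the k-th score are all
    included, so the selection is deterministic and threshold-monotone.
    """
    if not scores:
        raise ValueError("no scored pairs")
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    values = sorted(scores.values(), reverse=True)
    k = max(1, int(len(values) * percent / 100))
    threshold = values[k - 1]
    selected = {pair for pair, s in scores.items() if s >= threshold}
    n_ties = len(selected) - k
    if n_ties:
        logger.info(
            "top_percent_pairs: %d pair(s) selected (%d beyond the nominal "
            "cut due to ties)",
            len(selected),
            n_ties,
        )
    return selected
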