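"""Gene-set over-representation via the one-sided Fisher/hypergeometric test.

For a query list of n genes drawn from a universe of N genes, and a gene
set with K members inside the universe, the overlap k is scored with the
upper-tail hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n) —
the one-sided Fisher exact test for over-representation.  Probabilities
are computed in log space by scipy's hypergeometric survival function, so
enrichments at p ~ 1e-20 do not underflow.  Benjamini-Hochberg adjustment
is applied across all sets tested for one list (one family per list), and
significance is gated at q < 0.05.

:func:`enrichment_matrix` arranges -log10 p values for several lists into
a matrix and orders both axes by average-linkage hierarchical clustering
on Euclidean distances — the data behind a clustered significance
heat map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import hypergeom

from .differential import benjamini_hochberg
from .exceptions import ConfigurationError, ConsistencyError, DomainError
from .io import GeneSetCollection

__all__ = ["EnrichmentMatrix", "fisher_enrichment", "enrichment_matrix"]

ENRICHMENT_COLUMNS = ["set", "k", "K", "n", "N", "odds_ratio", "p_value", "q_value", "significant"]


def _odds_ratio(k: int, K: int, n: int, N: int) -> float:
    """Sample odds ratio of the 2x2 table; infinity when a zero cell allows it."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b * c == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)


def fisher_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score one gene list against every set in a collection.

    Set members are intersected with the universe before counting; a set
    with no members in the universe is reported with p = 1.  Returns a
    table with one row per set (name-sorted) and columns k, K, n, N,
    odds_ratio, p_value, q_value, significant.
    """
    universe = frozenset(universe)
    if not universe:
        raise DomainError("universe is empty")
    query = frozenset(gene_list)
    stray = query - universe
    if stray:
        raise ConsistencyError(
            f"{len(stray)} query gene(s) outside the universe, e.g. "
            f"{sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(query)
    rows = []
    for name in sorted(sets.names):
        members = sets[name].members & universe
        K = len(members)
        k = len(query & members)
        if K == 0:
            p = 1.0
        else:
            # survival function gives P(X > k-1) = P(X >= k)
            p = float(hypergeom.sf(k - 1, N, K, n))
            p = min(max(p, 0.0), 1.0)
        rows.append((name, k, K, n, N, _odds_ratio(k, K, n, N), p))
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:7])
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < alpha
    return table


@dataclass(frozen=True)
class EnrichmentMatrix:
    """-log10 p per (set, list), with clustering-derived display orders."""

    matrix: pd.DataFrame  # rows: sets, columns: lists, values: -log10 p
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]

    def reordered(self) -> pd.DataFrame:
        return self.matrix.loc[list(self.row_order), list(self.col_order)]


def _leaf_order(profiles: np.ndarray, labels: list[str]) -> tuple[str, ...]:
    if len(labels) < 2:
        return tuple(labels)
    lk = linkage(profiles, method="average", metric="euclidean")
    return tuple(labels[i] for i in leaves_list(lk))


def enrichment_matrix(
    lists: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    sets: GeneSetCollection,
) -> EnrichmentMatrix:
    """Cross every gene list with every set and cluster both axes.

    Matrix entries are -log10 of the one-sided Fisher p-value.  Rows
    (sets) and columns (lists) are ordered by average-linkage hierarchical
    clustering of their -log10 p profiles; inputs are label-sorted first
    so ties resolve deterministically.
    """
    if len(lists) < 2:
        raise ConfigurationError("enrichment_matrix needs at least 2 gene lists")
    col_labels = sorted(lists)
    columns = {}
    for label in col_labels:
        table = fisher_enrichment(lists[label], universe, sets)
        columns[label] = pd.Series(
            -np.log10(table["p_value"].to_numpy()), index=table["set"]
        )
    matrix = pd.DataFrame(columns)
    matrix = matrix.loc[sorted(matrix.index)]
    matrix.index.name = "set"
    row_order = _leaf_order(matrix.to_numpy(), list(matrix.index))
    col_order = _leaf_order(matrix.to_numpy().T, list(matrix.columns))
    return EnrichmentMatrix(matrix=matrix, row_order=row_order, col_order=col_order)
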