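"""Contingency, combination, enrichment, and correlation statistics.

These back the class-bias comparisons (are PTC-introducing donor classes
activated preferentially under true labels versus label-switched controls?),
the ranking of activation calls, and gene-set over-representation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


def fisher_one_sided(table: Sequence[Sequence[int]]) -> float:
    """One-sided Fisher's exact test, first row enriched in the first column.

    The p-value is the hypergeometric upper tail: the probability, over all
    2x2 tables with the observed margins, that the first cell is at least as
    large as observed.  Any zero margin gives p = 1.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise StatsError("contingency table entries must be nonnegative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def fishers_method(pvals: Sequence[float]) -> float:
    """Combine independent p-values: X^2 = -2 * sum(ln p) ~ chi-square(2k)."""
    pvals = list(pvals)
    if not pvals:
        raise StatsError("no p-values to combine")
    clamped = []
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise StatsError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            warnings.warn("p of 0 clamped to the smallest positive float", RuntimeWarning, stacklevel=2)
            p = math.ulp(0.0)
        clamped.append(p)
    x2 = -2.0 * sum(math.log(p) for p in clamped)
    return float(sps.chi2.sf(x2, df=2 * len(clamped)))


@dataclass
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def class_bias(
    calls_a_true: int, calls_a_switched: int, calls_b_true: int, calls_b_switched: int
) -> ContingencyResult:
    """Is class A activated under true labels more than class B?

    Rows are site classes, columns are activation counts under true versus
    switched labels; the one-sided test asks whether the first row is
    enriched in the first (true-label) column.
    """
    table = ((calls_a_true, calls_a_switched), (calls_b_true, calls_b_switched))
    (a, b), (c, d) = table
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return ContingencyResult(table=table, odds_ratio=odds, p_value=fisher_one_sided(table))


@dataclass
class EnrichmentRow:
    set_name: str
    collection: str
    overlap: int
    set_size: int
    universe_size: int
    query_size: int
    p_raw: float
    p_bonferroni_collection: float
    p_bonferroni_global: float


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: one gene set per line, tab-separated name, description, genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def hypergeom_enrichment(
    query_genes: Iterable[str],
    collections: Mapping[str, Mapping[str, set[str]]],
    universe_genes: Iterable[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of the query in each gene set.

    Gene sets and the query are intersected with the universe first.  The
    raw p is the inclusive upper tail P(X >= overlap).  Bonferroni
    adjustment is applied both per collection (times the number of sets in
    that collection) and globally (times the total number of sets supplied),
    capped at 1.  Rows come back sorted by raw p.
    """
    universe = set(universe_genes)
    if not universe:
        raise StatsError("empty universe")
    query = set(query_genes) & universe
    if not query:
        raise StatsError("empty query after intersecting with the universe")
    total_sets = sum(len(c) for c in collections.values())
    rows: list[EnrichmentRow] = []
    for coll_name, gene_sets in collections.items():
        n_coll = len(gene_sets)
        for set_name, genes in gene_sets.items():
            genes_u = set(genes) & universe
            overlap = len(genes_u & query)
            p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(genes_u), len(query)))
            rows.append(
                EnrichmentRow(
                    set_name=set_name,
                    collection=coll_name,
                    overlap=overlap,
                    set_size=len(genes_u),
                    universe_size=len(universe),
                    query_size=len(query),
                    p_raw=p,
                    p_bonferroni_collection=min(1.0, p * n_coll),
                    p_bonferroni_global=min(1.0, p * total_sets),
                )
            )
    rows.sort(key=lambda r: r.p_raw)
    return rows


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; t-approximation p-value.

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("vectors must have equal length")
    if len(x) < 3:
        raise StatsError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
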