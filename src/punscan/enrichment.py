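"""Gene-set over-representation analysis (ORA) and membership fractions.

The ORA statistic is a one-sided upper-tail hypergeometric p-value

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

for a query of size n drawn from a universe of size N in which K proteins
carry the term and k of the query do, followed by Benjamini-Hochberg
adjustment across all tested terms.  Both the tail probability (log-gamma
closed form) and the BH step are implemented here; only proteins present
in the scanned universe count toward N and K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GeneSetAnnotation",
    "EnrichmentResult",
    "hypergeom_pvalue",
    "bh_adjust",
    "hypergeom_enrich",
    "membership_fractions",
]


@dataclass(frozen=True)
class GeneSetAnnotation:
    term_id: str
    term_name: str
    members: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # hits in query
    K: int  # hits in universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    p_adjusted: float


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(log_terms).sum()))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def hypergeom_enrich(
    query: Iterable[str],
    annotation: Mapping[str, GeneSetAnnotation],
    universe: Iterable[str],
    min_set: int = 10,
    max_set: int = 500,
) -> list[EnrichmentResult]:
    """One-sided over-representation of each term in the query vs the universe.

    Terms are filtered to a universe-restricted set size K in
    [min_set, max_set]; results are sorted by adjusted p ascending, ties by
    term id.
    """
    universe = set(universe)
    query = set(query)
    offenders = sorted(query - universe)
    if offenders:
        raise ValueError(f"query ids absent from universe: {offenders}")
    N, n = len(universe), len(query)

    kept: list[tuple[GeneSetAnnotation, frozenset[str]]] = []
    for term in annotation.values():
        members = frozenset(term.members & universe)
        if min_set <= len(members) <= max_set:
            kept.append((term, members))
    if not kept:
        return []

    pvals = [
        hypergeom_pvalue(len(members & query), len(members), n, N)
        for _, members in kept
    ]
    adj = bh_adjust(pvals)
    results = [
        EnrichmentResult(
            term.term_id,
            term.term_name,
            k=len(members & query),
            K=len(members),
            n=n,
            N=N,
            p_value=p,
            p_adjusted=float(a),
        )
        for (term, members), p, a in zip(kept, pvals, adj)
    ]
    return sorted(results, key=lambda r: (r.p_adjusted, r.p_value, r.term_id))


def membership_fractions(
    query: Iterable[str],
    term_ids: Sequence[str],
    annotation: Mapping[str, GeneSetAnnotation],
) -> pd.DataFrame:
    """Fraction of query proteins annotated to each listed term.

    Returns a table with numerator (annotated in query), denominator
    (query size) and the fraction, one row per requested term.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    rows = []
    for tid in term_ids:
        if tid not in annotation:
            raise KeyError(f"unknown term id {tid!r}")
        term = annotation[tid]
        k = len(term.members & query)
        rows.append(
            {
                "term_id": tid,
                "term_name": term.term_name,
                "annotated": k,
                "query_size": len(query),
                "fraction": k / len(query),
            }
        )
    return pd.DataFrame(rows)
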