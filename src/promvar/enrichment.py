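"""Gene-set overlap statistics: fold enrichment and the EASE score.

Fold enrichment is the ratio of a set's proportion in the query list to
its proportion in the background.  The EASE score is a conservative
one-sided Fisher exact p-value in which the query-overlap count k is
replaced by max(k - 1, 0) before taking the hypergeometric upper tail;
it is therefore always at least as large as the unmodified Fisher p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .io_formats import GeneSetCollection

__all__ = [
    "EnrichmentRecord",
    "fold_enrichment",
    "ease_score",
    "fisher_enrichment_p",
    "enrich_gene_list",
    "DEFAULT_COUNT_THRESHOLD",
    "DEFAULT_EASE_THRESHOLD",
    "DEFAULT_SIGNIFICANCE_LEVEL",
]

#: Reporting thresholds: minimum overlap, EASE screen, significance flag.
DEFAULT_COUNT_THRESHOLD = 2
DEFAULT_EASE_THRESHOLD = 0.1
DEFAULT_SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True, slots=True)
class EnrichmentRecord:
    """One gene set's overlap with a query list.

    k: query genes in the set; n: query size; K: background genes in the
    set; N_bg: background size.  ``passes`` applies the count and EASE
    screens; ``significant`` flags ease_p below the significance level.
    """

    set_name: str
    k: int
    n: int
    K: int
    N_bg: int
    fold_enrichment: float
    ease_p: float
    fisher_p: float
    passes: bool
    significant: bool


def fold_enrichment(k: int, n: int, K: int, N_bg: int) -> float:
    """``(k/n) / (K/N_bg)``; NaN when the set is absent from the
    background (K == 0)."""
    if n <= 0 or N_bg <= 0:
        raise ValueError("n and N_bg must be positive")
    if K == 0:
        return math.nan
    return (k / n) / (K / N_bg)


def _check_table(k: int, n: int, K: int, N_bg: int) -> None:
    if not (0 <= n <= N_bg and 0 <= K <= N_bg):
        raise ValueError("require 0 <= n, K <= N_bg")
    if k < 0 or k > n or k > K:
        raise ValueError(f"impossible contingency table: k={k}, n={n}, K={K}")
    if k < n - (N_bg - K):
        raise ValueError(
            f"impossible contingency table: k={k} < n - (N_bg - K) = {n - (N_bg - K)}"
        )


def fisher_enrichment_p(k: int, n: int, K: int, N_bg: int) -> float:
    """One-sided (enrichment-tail) Fisher exact p-value,
    P(X >= k) for X hypergeometric with n draws, K marked, N_bg total."""
    _check_table(k, n, K, N_bg)
    return float(stats.hypergeom.sf(k - 1, N_bg, K, n))


def ease_score(k: int, n: int, K: int, N_bg: int) -> float:
    """EASE score: the enrichment-tail Fisher p-value after replacing k
    with max(k - 1, 0)."""
    _check_table(k, n, K, N_bg)
    k_ease = max(k - 1, 0)
    p = float(stats.hypergeom.sf(k_ease - 1, N_bg, K, n))
    return min(p, 1.0)


def enrich_gene_list(
    query: Iterable[str],
    sets: GeneSetCollection,
    background: Iterable[str],
    *,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    ease_threshold: float = DEFAULT_EASE_THRESHOLD,
    significance_level: float = DEFAULT_SIGNIFICANCE_LEVEL,
) -> tuple[list[EnrichmentRecord], list[str]]:
    """Score every gene set against a query list.

    Symbols are uppercased and de-duplicated.  Query symbols missing
    from the background are dropped and returned as the second element.
    One record is produced per set with k >= 1, sorted by ascending
    ease_p (ties by set name).  Set membership outside the background is
    ignored so that k <= K always holds.
    """
    bg = {s.upper() for s in background}
    if not bg:
        raise ValueError("background gene list is empty")
    raw_query = {s.upper() for s in query}
    dropped = sorted(raw_query - bg)
    q = raw_query & bg
    n, N_bg = len(q), len(bg)
    records: list[EnrichmentRecord] = []
    if n == 0:
        return records, dropped
    for name in sets:
        members = sets.members(name) & bg
        K = len(members)
        k = len(q & members)
        if k < 1:
            continue
        ease_p = ease_score(k, n, K, N_bg)
        records.append(
            EnrichmentRecord(
                set_name=name,
                k=k,
                n=n,
                K=K,
                N_bg=N_bg,
                fold_enrichment=fold_enrichment(k, n, K, N_bg),
                ease_p=ease_p,
                fisher_p=fisher_enrichment_p(k, n, K, N_bg),
                passes=(k >= count_threshold and ease_p <= ease_threshold),
                significant=(ease_p < significance_level),
            )
        )
    records.sort(key=lambda r: (r.ease_p, r.set_name))
    return records, dropped
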