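"""Category over-representation tests for gene subsets.

Tests whether a functional subset (e.g. growth-annotated genes) contains
more members of a category grouping (up, down, paternalELD, maternalELD,
mid) than expected from the full gene set, via Fisher's exact test on the
2×2 table (subset vs rest) × (in grouping vs not).  One-sided
(over-representation) by default, since such claims are directional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import GROUPINGS, Category, CategoryAssignment

COMPARATORS = ("rest", "total")


@dataclass(frozen=True)
class EnrichmentResult:
    """2×2 enrichment outcome: k of n subset hits vs K of N background."""

    subset_hits: int
    subset_size: int
    background_hits: int
    background_size: int
    odds_ratio: float
    p_value: float
    grouping: str
    alternative: str = "greater"


def enrichment_test(k: int, n: int, K: int, N: int, grouping: str = "",
                    alternative: str = "greater",
                    comparator: str = "rest") -> EnrichmentResult:
    """Fisher's exact test on subset hits k/n against background K/N.

    ``comparator="rest"`` (default) uses the standard 2×2 table
    [[k, n-k], [K-k, (N-n)-(K-k)]]; ``"total"`` compares the subset column
    against the whole-set margin [[k, n-k], [K, N-n]].  The sample odds
    ratio gets a 0.5 continuity correction when any cell is zero.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid contingency: k={k}, n={n}, K={K}, N={N}")
    if comparator not in COMPARATORS:
        raise ValueError(f"comparator must be one of {COMPARATORS}")
    if comparator == "rest":
        table = np.array([[k, n - k], [K - k, (N - n) - (K - k)]])
        if (table < 0).any():
            raise ValueError(f"invalid contingency: k={k}, n={n}, K={K}, N={N}")
    else:
        table = np.array([[k, n - k], [K, N - n]])
    _, p = stats.fisher_exact(table, alternative=alternative)
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(subset_hits=k, subset_size=n, background_hits=K,
                            background_size=N, odds_ratio=float(odds),
                            p_value=float(p), grouping=grouping,
                            alternative=alternative)


def _grouping_set(grouping) -> tuple[str, frozenset[Category]]:
    if isinstance(grouping, str):
        if grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {grouping!r}; expected one of "
                             f"{sorted(GROUPINGS)}")
        return grouping, GROUPINGS[grouping]
    members = frozenset(Category(g) for g in grouping)
    if not members:
        raise ValueError("empty category grouping")
    return "+".join(sorted(c.value for c in members)), members


def category_enrichment(subset_assignments: Sequence[CategoryAssignment],
                        all_assignments: Sequence[CategoryAssignment],
                        grouping, alternative: str = "greater",
                        comparator: str = "rest") -> EnrichmentResult:
    """Enrichment of a category grouping in a subset of classified genes."""
    if not subset_assignments:
        raise ValueError("empty subset")
    name, members = _grouping_set(grouping)
    all_ids = {a.gene_id for a in all_assignments}
    stray = [a.gene_id for a in subset_assignments if a.gene_id not in all_ids]
    if stray:
        raise ValueError(f"subset gene(s) not in the full assignment set: {stray[:5]}")
    k = sum(a.category in members for a in subset_assignments)
    K = sum(a.category in members for a in all_assignments)
    return enrichment_test(k, len(subset_assignments), K, len(all_assignments),
                           grouping=name, alternative=alternative,
                           comparator=comparator)


def proportion_report(assignments: Sequence[CategoryAssignment],
                      denominator: int | None = None) -> pd.DataFrame:
    """Counts and percentages per grouping (full precision + 1-dp column).

    ``denominator`` overrides the percentage base, for gene sets whose
    unchanged members are known only by count and absent from
    ``assignments``; the remainder is reported as ``Unlisted``.
    """
    if not assignments:
        raise ValueError("empty assignment list")
    n = len(assignments)
    denom = denominator if denominator is not None else n
    if denom < n:
        raise ValueError(f"denominator {denom} smaller than assignment count {n}")
    rows = []
    counted = 0
    for name, members in GROUPINGS.items():
        count = sum(a.category in members for a in assignments)
        counted += count
        rows.append({"grouping": name, "count": count})
    for cat in (Category.NO_CHANGE, Category.AMBIGUOUS, Category.UNRESOLVED,
                Category.SILENCED, Category.NOVEL, Category.EXCLUDED):
        count = sum(a.category is cat for a in assignments)
        counted += count
        rows.append({"grouping": cat.value, "count": count})
    if denom > n:
        rows.append({"grouping": "Unlisted", "count": denom - n})
    report = pd.DataFrame(rows)
    report["percent"] = 100.0 * report["count"] / denom
    report["percent_rounded"] = report["percent"].round(1)
    return report
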