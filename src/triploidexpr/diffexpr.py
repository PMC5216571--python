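"""Two-library differential expression testing.

Two exact engines are provided for comparing one pooled count per group:

* ``binomial`` — the random-sampling model: conditional on the total
  t = c1 + c2, c1 is Binomial(t, n1/(n1+n2)) under the null of equal
  relative expression; the two-sided p-value sums the point probabilities
  of all outcomes no more likely than the observed one.
* ``fisher`` — Fisher's exact test on the 2×2 table
  [[c1, n1−c1], [c2, n2−c2]] (two-sided, point-probability method).

Replicate counts are pooled by summation before testing (no dispersion
modelling); Benjamini–Hochberg adjustment is applied across all tested
genes.  A gene is called up/down only when q < fdr_max AND |M| > lfc_min
(strict inequalities), where M is the log2 RPKM ratio of the pooled
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix
from .normalization import rpkm

ENGINES = ("binomial", "fisher")


@dataclass(frozen=True)
class DEThresholds:
    """Significance gates: q < ``fdr_max`` and |M| > ``lfc_min`` (log2)."""

    fdr_max: float = 0.001
    lfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError(f"fdr_max must be in (0, 1], got {self.fdr_max}")
        if self.lfc_min < 0:
            raise ValueError(f"lfc_min must be >= 0, got {self.lfc_min}")


@dataclass
class DifferentialResult:
    """Per-gene two-group comparison (MA coordinates, p, q, call)."""

    gene_id: str
    m_value: float  # log2 ratio (group_a / group_b); ±inf on one-sided zero
    a_value: float  # mean log2 intensity; NaN when either side is zero
    p_value: float
    q_value: float
    call: str  # "up" | "down" | "ns"
    tested: bool = True


def binomial_rs_test(c1: int, c2: int, n1: int, n2: int) -> float:
    """Exact two-sided conditional-binomial (random sampling) p-value."""
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be >= 0")
    t = c1 + c2
    if t == 0:
        return 1.0  # no information
    return stats.binomtest(int(c1), n=int(t), p=n1 / (n1 + n2),
                           alternative="two-sided").pvalue


def fisher_de_test(c1: int, c2: int, n1: int, n2: int) -> float:
    """Two-sided Fisher exact p for [[c1, n1-c1], [c2, n2-c2]]."""
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be >= 0")
    if c1 > n1 or c2 > n2:
        raise ValueError("count exceeds its library size")
    if c1 + c2 == 0:
        return 1.0
    _, p = stats.fisher_exact([[c1, n1 - c1], [c2, n2 - c2]], alternative="two-sided")
    return float(min(p, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def de_call(m_value: float, q_value: float, thresholds: DEThresholds | None = None) -> str:
    """Apply the significance gates; ``ns`` unless both are met."""
    thresholds = thresholds or DEThresholds()
    if np.isnan(m_value):
        return "ns"
    if q_value < thresholds.fdr_max:
        if m_value > thresholds.lfc_min:
            return "up"
        if m_value < -thresholds.lfc_min:
            return "down"
    return "ns"


def _ma_values(c1, c2, n1, n2, length_bp):
    """M (log2 ratio) and A (mean log2 intensity) from pooled RPKM."""
    r1 = rpkm(c1, n1, length_bp)
    r2 = rpkm(c2, n2, length_bp)
    if r1 == 0 and r2 == 0:
        return np.nan, np.nan
    if r2 == 0:
        return np.inf, np.nan
    if r1 == 0:
        return -np.inf, np.nan
    return float(np.log2(r1 / r2)), float(0.5 * (np.log2(r1) + np.log2(r2)))


def compare_groups(matrix: ExpressionMatrix, group_a: str, group_b: str,
                   engine: str = "binomial",
                   thresholds: DEThresholds | None = None,
                   adjust: bool = True) -> list[DifferentialResult]:
    """Per-gene differential expression between two group roles.

    Counts are pooled by summation across replicates within each group; M is
    the log2 ratio of pooled RPKM (group_a over group_b).  Genes with zero
    pooled counts on both sides are reported untested with call ``ns``.
    With ``adjust=False`` the raw p-values are used in place of q.
    """
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    cols_a = matrix.column_indices(group_a)
    cols_b = matrix.column_indices(group_b)
    if not cols_a or not cols_b:
        raise ValueError(f"both groups must have samples ({group_a!r}, {group_b!r})")
    ca = matrix.counts[:, cols_a].sum(axis=1)
    cb = matrix.counts[:, cols_b].sum(axis=1)
    na = int(matrix.library_size[cols_a].sum())
    nb = int(matrix.library_size[cols_b].sum())
    test = binomial_rs_test if engine == "binomial" else fisher_de_test

    lengths = matrix.lengths
    results: list[DifferentialResult] = []
    for gid, c1, c2, length in zip(matrix.gene_ids, ca, cb, lengths):
        tested = bool(c1 + c2 > 0)
        p = test(int(c1), int(c2), na, nb) if tested else 1.0
        m, a = _ma_values(int(c1), int(c2), na, nb, int(length))
        results.append(DifferentialResult(gid, m, a, p, p, "ns", tested))

    tested_idx = [i for i, r in enumerate(results) if r.tested]
    if tested_idx and adjust:
        q = bh_fdr([results[i].p_value for i in tested_idx])
        for i, qi in zip(tested_idx, q):
            results[i].q_value = float(qi)
    for i in tested_idx:
        results[i].call = de_call(results[i].m_value, results[i].q_value, thresholds)
    return results


def de_summary(results: list[DifferentialResult]) -> dict:
    """Tallies mirroring a per-contrast partitioning table."""
    up = int(sum(r.call == "up" for r in results))
    down = int(sum(r.call == "down" for r in results))
    return {
        "n_genes": len(results),
        "n_tested": int(sum(r.tested for r in results)),
        "n_up": up,
        "n_down": down,
        "n_de": up + down,
        "n_ns": len(results) - up - down,
    }
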