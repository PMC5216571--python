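"""In-silico dosage-compensation model for a triploid hybrid.

A triploid carrying two maternal and one paternal chromosome set has the
additive expectation ("predicted triploid expression level", PT-ELV)

    chi_triploid = 1/2 * chi_paternal + chi_maternal

since each diploid parent's mean RPKM represents two chromosome sets.  If
the extra maternal dose is fully compensated, expression falls to the
diploid state ("predicted diploid expression level", PD-ELV)

    chi_diploid = 1/2 * chi_paternal + 1/2 * chi_maternal

Comparing the actual triploid level (AT-ELV) against each prediction
quantifies the extent and direction of dosage compensation.  The genome
doses are parameterized (default 1 paternal : 2 maternal sets) so
reciprocal triploids can be analysed.

Predictions have no replicate structure, so the default comparison is
threshold-only (|log2 ratio| > lfc_min on mean RPKM).  A statistical mode
is available for count input: predicted counts are formed as the same
linear combination of the pooled parental counts, rounded to the nearest
integer, and treated as pseudo-observations by the chosen exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffexpr import DEThresholds, bh_fdr, binomial_rs_test, de_call, fisher_de_test
from .io import ExpressionMatrix, GroupExpression
from .normalization import rpkm

PREDICTIONS = ("PT", "PD")


def predicted_triploid_elv(chi_paternal: float, chi_maternal: float,
                           paternal_sets: int = 1, maternal_sets: int = 2) -> float:
    """Additive triploid expectation: (sets/2)-weighted sum of parent means."""
    if np.any(np.asarray(chi_paternal) < 0) or np.any(np.asarray(chi_maternal) < 0):
        raise ValueError("expression levels must be >= 0")
    return (paternal_sets / 2) * chi_paternal + (maternal_sets / 2) * chi_maternal


def predicted_diploid_elv(chi_paternal: float, chi_maternal: float) -> float:
    """Mid-parent (diploid state) expectation: half of each parent."""
    if np.any(np.asarray(chi_paternal) < 0) or np.any(np.asarray(chi_maternal) < 0):
        raise ValueError("expression levels must be >= 0")
    return 0.5 * chi_paternal + 0.5 * chi_maternal


@dataclass(frozen=True)
class DosagePrediction:
    """Predicted triploid (PT-ELV) and diploid (PD-ELV) levels for a gene."""

    gene_id: str
    pt_elv: float
    pd_elv: float


@dataclass
class DosageSummary:
    """Tallies of AT-ELV vs prediction calls (up = actual above prediction)."""

    prediction: str
    n_tested: int
    n_up: int
    n_down: int
    n_ns: int

    @property
    def fraction_up(self) -> float:
        return self.n_up / self.n_tested if self.n_tested else 0.0

    @property
    def fraction_down(self) -> float:
        return self.n_down / self.n_tested if self.n_tested else 0.0


def predict(expr: Iterable[GroupExpression], paternal_sets: int = 1,
            maternal_sets: int = 2) -> list[DosagePrediction]:
    return [
        DosagePrediction(
            gene_id=e.gene_id,
            pt_elv=predicted_triploid_elv(e.chi_paternal, e.chi_maternal,
                                          paternal_sets, maternal_sets),
            pd_elv=predicted_diploid_elv(e.chi_paternal, e.chi_maternal),
        )
        for e in expr
    ]


def dosage_comparison(expr: Sequence[GroupExpression], prediction: str = "PT",
                      lfc_min: float = 1.0, paternal_sets: int = 1,
                      maternal_sets: int = 2) -> tuple[pd.DataFrame, DosageSummary]:
    """Threshold-mode comparison of AT-ELV against PT-ELV or PD-ELV.

    Per gene, M = log2(at_elv / predicted); the call is ``up`` when
    M > lfc_min, ``down`` when M < -lfc_min, else ``ns``.  Genes where both
    the actual level and the prediction are zero are flagged untested.
    Returns the per-gene table and a :class:`DosageSummary`.
    """
    if prediction not in PREDICTIONS:
        raise ValueError(f"prediction must be one of {PREDICTIONS}, got {prediction!r}")
    if not expr:
        raise ValueError("dosage_comparison: empty expression list")
    rows = []
    for e in expr:
        if prediction == "PT":
            pred = predicted_triploid_elv(e.chi_paternal, e.chi_maternal,
                                          paternal_sets, maternal_sets)
        else:
            pred = predicted_diploid_elv(e.chi_paternal, e.chi_maternal)
        tested = not (e.at_elv == 0 and pred == 0)
        if not tested:
            m, call = np.nan, "ns"
        elif pred == 0:
            m, call = np.inf, "up"
        elif e.at_elv == 0:
            m, call = -np.inf, "down"
        else:
            m = float(np.log2(e.at_elv / pred))
            call = "up" if m > lfc_min else ("down" if m < -lfc_min else "ns")
        rows.append({"gene_id": e.gene_id, "at_elv": e.at_elv, "predicted": pred,
                     "m_value": m, "call": call, "tested": tested})
    table = pd.DataFrame(rows)
    tested_n = int(table["tested"].sum())
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    summary = DosageSummary(prediction=prediction, n_tested=tested_n, n_up=n_up,
                            n_down=n_down, n_ns=tested_n - n_up - n_down)
    return table, summary


def dosage_comparison_counts(matrix: ExpressionMatrix, prediction: str = "PT",
                             engine: str = "binomial",
                             thresholds: DEThresholds | None = None,
                             paternal_sets: int = 1, maternal_sets: int = 2
                             ) -> tuple[pd.DataFrame, DosageSummary]:
    """Statistical-mode comparison on count input.

    Predicted counts (and a matching pseudo library size) are the
    dose-weighted linear combination of the pooled parental counts, rounded
    to the nearest integer; they are pseudo-observations, so p-values are
    approximate in the same sense as the prediction itself.
    """
    if prediction not in PREDICTIONS:
        raise ValueError(f"prediction must be one of {PREDICTIONS}, got {prediction!r}")
    wp = paternal_sets / 2 if prediction == "PT" else 0.5
    wm = maternal_sets / 2 if prediction == "PT" else 0.5
    cols_p = matrix.column_indices("paternal")
    cols_m = matrix.column_indices("maternal")
    cols_h = matrix.column_indices("hybrid")
    cp = matrix.counts[:, cols_p].sum(axis=1)
    cm = matrix.counts[:, cols_m].sum(axis=1)
    ch = matrix.counts[:, cols_h].sum(axis=1)
    np_lib = int(matrix.library_size[cols_p].sum())
    nm_lib = int(matrix.library_size[cols_m].sum())
    nh_lib = int(matrix.library_size[cols_h].sum())
    pred_counts = np.rint(wp * cp + wm * cm).astype(np.int64)
    pred_lib = max(int(round(wp * np_lib + wm * nm_lib)), 1)
    test = binomial_rs_test if engine == "binomial" else fisher_de_test

    rows = []
    for gid, c_h, c_pred, length in zip(matrix.gene_ids, ch, pred_counts, matrix.lengths):
        tested = (c_h + c_pred) > 0
        p = test(int(c_h), int(c_pred), nh_lib, pred_lib) if tested else 1.0
        r_h = rpkm(int(c_h), nh_lib, int(length))
        r_p = rpkm(int(c_pred), pred_lib, int(length))
        if r_h == 0 and r_p == 0:
            m = np.nan
        elif r_p == 0:
            m = np.inf
        elif r_h == 0:
            m = -np.inf
        else:
            m = float(np.log2(r_h / r_p))
        rows.append({"gene_id": gid, "hybrid_count": int(c_h),
                     "predicted_count": int(c_pred), "m_value": m,
                     "p_value": p, "tested": tested})
    table = pd.DataFrame(rows)
    q = np.ones(len(table))
    mask = table["tested"].to_numpy()
    if mask.any():
        q[mask] = bh_fdr(table.loc[mask, "p_value"].to_numpy())
    table["q_value"] = q
    table["call"] = [
        de_call(m, qv, thresholds) if t else "ns"
        for m, qv, t in zip(table["m_value"], table["q_value"], table["tested"])
    ]
    tested_n = int(mask.sum())
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    summary = DosageSummary(prediction=prediction, n_tested=tested_n, n_up=n_up,
                            n_down=n_down, n_ns=tested_n - n_up - n_down)
    return table, summary
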