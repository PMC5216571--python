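"""Relative quantification for qPCR validation (2^-ddCt).

Each record carries the threshold cycle (Ct) of the target gene and of an
internal-control reference (the beta-actin role).  The fold change of a
test sample relative to a calibrator is

    ddCt = (Ct_target - Ct_reference)_test - (Ct_target - Ct_reference)_calibrator
    fold = 2 ** (-ddCt)

Technical triplicates are averaged on the Ct scale before the delta is
taken; fold changes are then averaged across biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    ct_target: float
    ct_reference: float
    condition: str = "test"  # "test" | "calibrator"

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.sample_id!r}: {name} must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(test: QpcrRecord, calibrator: QpcrRecord) -> float:
    """Fold change of ``test`` over ``calibrator``: 2^-(dCt_test - dCt_cal)."""
    ddct = test.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))


def average_ct(records: Sequence[QpcrRecord]) -> QpcrRecord:
    """Collapse technical replicates of one sample by mean Ct."""
    if not records:
        raise ValueError("no records to average")
    ids = {r.sample_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"technical replicates span multiple samples: {sorted(ids)}")
    conditions = {r.condition for r in records}
    if len(conditions) > 1:
        raise ValueError("technical replicates span multiple conditions")
    return QpcrRecord(
        sample_id=records[0].sample_id,
        ct_target=float(np.mean([r.ct_target for r in records])),
        ct_reference=float(np.mean([r.ct_reference for r in records])),
        condition=records[0].condition,
    )


def replicate_fold_changes(pairs: Iterable[tuple[QpcrRecord, QpcrRecord]]) -> dict:
    """Per-replicate fold changes with their mean and spread.

    Each element pairs one biological test replicate with its calibrator.
    The spread is the sample standard deviation (0 for a single replicate).
    """
    folds = [ddct_fold_change(test, cal) for test, cal in pairs]
    if not folds:
        raise ValueError("no replicate pairs supplied")
    spread = float(np.std(folds, ddof=1)) if len(folds) > 1 else 0.0
    return {"fold_changes": folds, "mean": float(np.mean(folds)), "sd": spread}


def read_qpcr_table(path) -> list[QpcrRecord]:
    """Read a TSV of (sample, condition, ct_target, ct_reference)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample", "condition", "ct_target", "ct_reference"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        QpcrRecord(sample_id=str(row.sample), ct_target=float(row.ct_target),
                   ct_reference=float(row.ct_reference), condition=str(row.condition))
        for row in frame.itertuples()
    ]


def fold_change_table(records: Sequence[QpcrRecord]) -> pd.DataFrame:
    """Fold change of every test sample against the mean calibrator.

    Calibrator records are Ct-averaged into a single baseline; each test
    sample (technical replicates Ct-averaged first) is then quantified
    against it.
    """
    calibrators = [r for r in records if r.condition == "calibrator"]
    tests = [r for r in records if r.condition == "test"]
    if not calibrators or not tests:
        raise ValueError("need at least one test and one calibrator record")
    baseline = QpcrRecord(
        sample_id="calibrator", condition="calibrator",
        ct_target=float(np.mean([r.ct_target for r in calibrators])),
        ct_reference=float(np.mean([r.ct_reference for r in calibrators])),
    )
    rows = []
    for sample in dict.fromkeys(r.sample_id for r in tests):
        merged = average_ct([r for r in tests if r.sample_id == sample])
        rows.append({"sample": sample, "delta_ct": merged.delta_ct,
                     "fold_change": ddct_fold_change(merged, baseline)})
    return pd.DataFrame(rows)
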