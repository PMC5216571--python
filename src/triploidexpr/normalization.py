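"""RPKM normalization and per-group mean expression.

RPKM (reads per kilobase of transcript per million mapped reads) for a
gene with read count C, library size N and length L bp is

    RPKM = 1e9 * C / (N * L)

Replicates are averaged on the RPKM scale (group means are the arithmetic
mean of replicate RPKM); no pseudocount is added — zero handling is the
classifier's responsibility.  Counts are only ever summed inside the
two-library statistical tests (see :mod:`triploidexpr.diffexpr`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import HYBRID, MATERNAL, PATERNAL, ExpressionMatrix, GroupExpression

SCALE = 1e9  # per-kilobase, per-million


def rpkm(count, library_size, length_bp):
    """RPKM = 1e9 * C / (N * L); accepts scalars or arrays."""
    count = np.asarray(count, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(library_size < 1):
        raise ValueError("library_size must be >= 1")
    if np.any(length_bp < 1):
        raise ValueError("length_bp must be >= 1")
    if np.any(count < 0):
        raise ValueError("count must be >= 0")
    out = SCALE * count / (library_size * length_bp)
    return float(out) if out.ndim == 0 else out


def rpkm_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene × sample RPKM values for a count matrix."""
    values = rpkm(matrix.counts, matrix.library_size[np.newaxis, :],
                  matrix.lengths[:, np.newaxis])
    return pd.DataFrame(values, index=matrix.gene_ids, columns=matrix.samples)


def group_mean_frame(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene mean RPKM per group role, as a DataFrame.

    Columns ``chi_paternal``, ``chi_maternal``, ``at_elv`` (the actual
    triploid expression level is the hybrid group's mean).
    """
    r = rpkm_matrix(matrix)
    cols = {}
    for group, name in ((PATERNAL, "chi_paternal"), (MATERNAL, "chi_maternal"),
                        (HYBRID, "at_elv")):
        samples = matrix.samples_in(group)
        if not samples:
            raise ValueError(f"group {group!r} has no samples")
        cols[name] = r[samples].mean(axis=1)
    return pd.DataFrame(cols, index=r.index)


def group_means(matrix: ExpressionMatrix) -> list[GroupExpression]:
    """Per-gene :class:`GroupExpression` records (mean replicate RPKM)."""
    frame = group_mean_frame(matrix)
    return [
        GroupExpression(gene_id=str(gene), chi_paternal=row.chi_paternal,
                        chi_maternal=row.chi_maternal, at_elv=row.at_elv)
        for gene, row in frame.iterrows()
    ]
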