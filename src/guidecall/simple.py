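"""Threshold-style assignment strategies.

Three strategies that need no model fit:

* ``umi_threshold`` -- call every (cell, guide) entry at or above a fixed
  UMI count ``t`` ("independent" family; a cell may receive many guides).
* ``maximum`` -- call the single most abundant guide per cell.
* ``ratio`` -- call the most abundant guide when its share of the cell's
  guide UMIs reaches a fraction ``r`` ("across gRNAs" family).

The latter two emit at most one call per cell, matching the low-MOI
expectation that most transduced cells carry a single gRNA.  Ties for the
per-cell maximum are never called: at low counts a tie is genuinely
ambiguous evidence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AssignmentTable, GuideCountMatrix, ParameterError

__all__ = [
    "assign_umi_threshold",
    "assign_maximum",
    "assign_ratio",
    "ratio_profile",
]


def _row_top_stats(matrix: GuideCountMatrix):
    """Per-cell total, max count, argmax column and tie count (vectorized)."""
    csr = matrix.counts
    n = csr.shape[0]
    nnz = np.diff(csr.indptr)
    total = np.zeros(n, dtype=np.int64)
    rowmax = np.zeros(n, dtype=np.int64)
    argmax = np.full(n, -1, dtype=np.int64)
    ties = np.zeros(n, dtype=np.int64)
    occupied = nnz > 0
    if not occupied.any():
        return total, rowmax, argmax, ties
    starts = csr.indptr[:-1][occupied]
    total[occupied] = np.add.reduceat(csr.data, starts)
    rowmax[occupied] = np.maximum.reduceat(csr.data, starts)
    rep = np.repeat(rowmax, nnz)
    is_max = csr.data == rep
    ties[occupied] = np.add.reduceat(is_max.astype(np.int64), starts)
    # first position achieving the row maximum
    first_hits = np.flatnonzero(is_max)
    row_of_hit = np.searchsorted(csr.indptr, first_hits, side="right") - 1
    keep = np.ones(first_hits.size, dtype=bool)
    keep[1:] = row_of_hit[1:] != row_of_hit[:-1]
    argmax[row_of_hit[keep]] = csr.indices[first_hits[keep]]
    return total, rowmax, argmax, ties


def ratio_profile(matrix: GuideCountMatrix) -> pd.DataFrame:
    """Per-cell top-guide profile.

    Columns: ``cell``, ``batch``, ``total`` (L_c), ``top_guide``,
    ``top_fraction`` (count of the top guide / L_c) and ``tie``.  Cells
    with zero guide UMIs are excluded (the fraction is undefined).
    """
    total, rowmax, argmax, ties = _row_top_stats(matrix)
    keep = total > 0
    frame = pd.DataFrame(
        {
            "cell": matrix.cell_ids[keep],
            "batch": matrix.batch_labels()[keep],
            "total": total[keep],
            "top_guide": matrix.guide_ids[argmax[keep]],
            "top_fraction": rowmax[keep] / total[keep],
            "tie": ties[keep] > 1,
        }
    )
    return frame.reset_index(drop=True)


def assign_umi_threshold(matrix: GuideCountMatrix, t: int) -> AssignmentTable:
    """Call every entry with at least ``t`` UMIs.

    The comparison is inclusive (>= t), so ``t=1`` means "any nonzero".
    """
    if not float(t).is_integer() or t < 1:
        raise ParameterError(f"threshold t must be an integer >= 1, got {t}")
    t = int(t)
    coo = matrix.counts.tocoo()
    hit = coo.data >= t
    frame = pd.DataFrame(
        {
            "cell": matrix.cell_ids[coo.row[hit]],
            "guide": matrix.guide_ids[coo.col[hit]],
        }
    )
    return AssignmentTable("umi_threshold", frame.assign(prob=np.nan), {"t": t})


def assign_maximum(matrix: GuideCountMatrix, min_count: int = 0) -> AssignmentTable:
    """Call the unique most abundant guide of each cell.

    Cells with no guide UMIs, with a tied maximum, or whose maximum is
    below ``min_count`` receive no call.
    """
    if min_count < 0:
        raise ParameterError("min_count must be >= 0")
    total, rowmax, argmax, ties = _row_top_stats(matrix)
    keep = (total > 0) & (ties == 1) & (rowmax >= min_count)
    frame = pd.DataFrame(
        {
            "cell": matrix.cell_ids[keep],
            "guide": matrix.guide_ids[argmax[keep]],
        }
    )
    return AssignmentTable(
        "maximum", frame.assign(prob=np.nan), {"min_count": int(min_count)}
    )


def assign_ratio(
    matrix: GuideCountMatrix, r: float, min_count: int = 0
) -> AssignmentTable:
    """Call the top guide when its relative frequency reaches ``r``.

    A call (c, g*) is made when g* is the unique argmax of cell c, its
    fraction of the cell's guide UMIs is >= r, and its count is
    >= ``min_count``.  At ``r=0`` this reduces to :func:`assign_maximum`.
    """
    if not 0 <= r <= 1:
        raise ParameterError(f"ratio r must lie in [0, 1], got {r}")
    if min_count < 0:
        raise ParameterError("min_count must be >= 0")
    total, rowmax, argmax, ties = _row_top_stats(matrix)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, rowmax / np.maximum(total, 1), np.nan)
    keep = (total > 0) & (ties == 1) & (frac >= r) & (rowmax >= min_count)
    frame = pd.DataFrame(
        {
            "cell": matrix.cell_ids[keep],
            "guide": matrix.guide_ids[argmax[keep]],
        }
    )
    return AssignmentTable(
        "ratio", frame.assign(prob=np.nan), {"r": float(r), "min_count": int(min_count)}
    )
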