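"""Core data containers and exceptions for guide assignment.

The canonical in-memory object is :class:`GuideCountMatrix`: a sparse
cells x gRNAs matrix of UMI counts with cell barcodes, guide identifiers,
optional per-cell batch labels and optional per-guide metadata (target gene,
targeting/non-targeting flag).  All assignment strategies consume this object
and emit an :class:`AssignmentTable` of (cell, guide) calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GuidecallError",
    "InputError",
    "ValidationError",
    "ParameterError",
    "DegenerateFitError",
    "EvaluationError",
    "GuideCountMatrix",
    "AssignmentTable",
]


class GuidecallError(Exception):
    """Base class for all guidecall errors."""


class InputError(GuidecallError):
    """A required input file or directory is missing or unreadable."""


class ValidationError(GuidecallError):
    """Input data violates an invariant of the data model."""


class ParameterError(GuidecallError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateFitError(GuidecallError):
    """The data cannot identify the model (e.g. all observations equal)."""


class EvaluationError(GuidecallError):
    """An evaluation metric cannot be computed from the given inputs."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(pd.unique(ids)):
        dup = pd.Series(ids).value_counts()
        dup = dup[dup > 1].index.tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dup}")


@dataclass
class GuideCountMatrix:
    """Sparse cells x gRNAs UMI count matrix.

    Parameters
    ----------
    counts
        Non-negative integer matrix, cells in rows, gRNAs in columns.
        Stored as CSR; dense inputs are converted.
    cell_ids, guide_ids
        Unique barcode / gRNA name strings.
    batch
        Optional per-cell batch label; a single implicit batch otherwise.
    guide_meta
        Optional frame indexed by guide id with columns ``target_gene``
        (str) and ``targeting`` (bool).
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    guide_ids: np.ndarray
    batch: np.ndarray | None = None
    guide_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        data = self.counts.data
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("counts must be integral UMI counts")
        if data.size and data.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        self.counts.eliminate_zeros()
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.guide_ids = np.asarray(self.guide_ids, dtype=object)
        n_cells, n_guides = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.guide_ids) != n_guides:
            raise ValidationError(
                f"{len(self.guide_ids)} guide ids for {n_guides} matrix columns"
            )
        _check_unique(self.cell_ids, "cell barcodes")
        _check_unique(self.guide_ids, "guide ids")
        if self.batch is not None:
            self.batch = np.asarray(self.batch, dtype=object)
            if len(self.batch) != n_cells:
                raise ValidationError("batch must have one label per cell")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_guides(self) -> int:
        return self.counts.shape[1]

    def total_counts(self) -> np.ndarray:
        """Per-cell total guide UMIs (library size L_c)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def guide_column(self, guide_id: str) -> np.ndarray:
        """Dense 1-D count vector of one guide across all cells."""
        j = int(np.flatnonzero(self.guide_ids == guide_id)[0])
        return np.asarray(self.counts[:, j].todense()).ravel()

    def batch_labels(self) -> np.ndarray:
        """Batch labels, defaulting to a single batch named 'batch0'."""
        if self.batch is None:
            return np.full(self.n_cells, "batch0", dtype=object)
        return self.batch

    def to_dense_frame(self) -> pd.DataFrame:
        """Dense cells x guides DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.counts.toarray(), index=self.cell_ids, columns=self.guide_ids
        )

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, GuideCountMatrix):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.cell_ids, other.cell_ids)
            and np.array_equal(self.guide_ids, other.guide_ids)
        )


@dataclass
class AssignmentTable:
    """Set of (cell, guide) calls produced by one assignment strategy.

    ``calls`` is a frame with columns ``cell``, ``guide`` and ``prob``
    (posterior probability of the call, NaN for hard-threshold methods).
    ``params`` records the configuration that produced the table.
    """

    method_name: str
    calls: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = ["cell", "guide", "prob"]
        if self.calls is None or len(self.calls) == 0:
            self.calls = pd.DataFrame(columns=cols)
        if "prob" not in self.calls.columns:
            self.calls = self.calls.assign(prob=np.nan)
        self.calls = self.calls[cols].reset_index(drop=True)
        self.calls["prob"] = self.calls["prob"].astype(float)
        if self.calls.duplicated(["cell", "guide"]).any():
            raise ValidationError("duplicate (cell, guide) calls")
        probs = self.calls["prob"].to_numpy()
        finite = probs[np.isfinite(probs)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("call probabilities must lie in [0, 1]")

    @classmethod
    def from_pairs(
        cls,
        method_name: str,
        pairs: Iterable[tuple[str, str]],
        probs: Iterable[float] | None = None,
        params: Mapping | None = None,
    ) -> "AssignmentTable":
        pairs = list(pairs)
        frame = pd.DataFrame(pairs, columns=["cell", "guide"])
        frame["prob"] = np.nan if probs is None else np.asarray(list(probs), float)
        return cls(method_name, frame, dict(params or {}))

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.calls["cell"], self.calls["guide"]))

    def cells(self) -> np.ndarray:
        return self.calls["cell"].to_numpy()

    def validate_against(self, matrix: GuideCountMatrix) -> None:
        """Check every call refers to a cell/guide of the source matrix."""
        bad_cells = set(self.calls["cell"]) - set(matrix.cell_ids)
        bad_guides = set(self.calls["guide"]) - set(matrix.guide_ids)
        if bad_cells or bad_guides:
            raise ValidationError(
                f"calls refer to unknown ids (cells={sorted(bad_cells)[:3]}, "
                f"guides={sorted(bad_guides)[:3]})"
            )

    def filter_prob(self, min_prob: float) -> "AssignmentTable":
        """Restrict to calls with posterior probability >= ``min_prob``."""
        kept = self.calls[self.calls["prob"] >= min_prob]
        return AssignmentTable(
            self.method_name,
            kept.copy(),
            {**self.params, "min_prob": min_prob},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssignmentTable):
            return NotImplemented
        if self.method_name != other.method_name:
            return False
        a = self.calls.sort_values(["cell", "guide"]).reset_index(drop=True)
        b = other.calls.sort_values(["cell", "guide"]).reset_index(drop=True)
        if not (a[["cell", "guide"]].equals(b[["cell", "guide"]])):
            return False
        pa, pb = a["prob"].to_numpy(), b["prob"].to_numpy()
        both_nan = np.isnan(pa) & np.isnan(pb)
        return bool(np.all(both_nan | np.isclose(pa, pb, atol=1e-9, equal_nan=False)))
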